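block,Traditional,MD,CAE
VGG,852,906,913
ResNet,1027,1044,1066
DenseNet,1187,1188,1140
MobileNet,1031,1075,1087
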