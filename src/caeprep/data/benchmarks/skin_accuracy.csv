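block,Traditional,MD,CAE
VGG,66.3,67.4,70.0
ResNet,73.7,74.7,77.9
DenseNet,75.8,75.3,80.0
MobileNet,75.2,74.2,72.0
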