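block,Traditional,MD,CAE
VGG,0.732,0.774,0.869
ResNet,0.881,0.892,0.897
DenseNet,0.905,0.903,0.926
MobileNet,0.853,0.857,0.889
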