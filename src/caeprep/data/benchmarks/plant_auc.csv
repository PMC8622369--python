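block,Traditional,MD,CAE
VGG,0.866,0.896,0.917
ResNet,0.935,0.946,0.949
DenseNet,0.953,0.954,0.956
MobileNet,0.963,0.957,0.956
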