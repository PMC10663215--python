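model,background,cane,broken_cane,top,leaf,miou,mpa
UNet,98.13,94.18,91.01,93.11,93.73,94.03,96.86
PSPNet,95.45,90.38,87.89,86.48,87.89,89.62,94.85
SegFormer-B0,95.6,82.98,72.38,81.12,79.79,82.37,89.79
DeepLabv3+,97.78,95.18,91.83,93.38,94.62,94.56,97.21
MDSC-DeepLabv3+,97.94,95.13,91.85,94.27,95.03,94.84,97.55
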