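table,model,pre,iou,dice
comparison,FCN,98.28,65.07,78.84
comparison,SegNet,98.53,70.59,82.76
comparison,UNet,98.74,73.61,84.80
comparison,DenseNet,98.79,75.86,86.27
comparison,full,99.20,83.38,90.94
ablation,baseline,89.03,73.66,84.83
ablation,scheme1,91.71,75.91,86.3
ablation,scheme2,89.01,76.85,86.91
ablation,scheme3,90.24,78.11,87.71
ablation,full,92.77,83.38,90.94
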