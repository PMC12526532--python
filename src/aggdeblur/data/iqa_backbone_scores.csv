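network,DISTS,LPIPS,VSI,MS-SSIM,FSIM,GMSD,NLPD
Test-blur,0.723,0.638,0.868,0.472,0.679,0.783,0.546
ResNet,0.848,0.740,0.961,0.817,0.891,0.847,0.673
Inception,0.854,0.729,0.956,0.802,0.881,0.836,0.654
UNet,0.853,0.740,0.959,0.812,0.885,0.843,0.665
GhostNet,0.881,0.724,0.960,0.810,0.889,0.837,0.655
MobileNet,0.884,0.729,0.961,0.809,0.891,0.838,0.654
AGG,0.911,0.766,0.971,0.863,0.914,0.860,0.697
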