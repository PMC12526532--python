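source,class_name,map50,map5095,precision,recall,f1,fnr,mconf
sharp,citrus,0.925,0.630,0.868,0.842,0.855,0.158,0.787
sharp,tree,0.995,0.868,0.982,1.000,0.987,0.000,0.928
blur,citrus,0.673,0.324,0.855,0.454,0.593,0.546,0.675
blur,tree,0.967,0.741,0.955,0.900,0.927,0.100,0.847
restore,citrus,0.898,0.604,0.861,0.803,0.831,0.197,0.767
restore,tree,0.995,0.842,0.975,1.000,0.981,0.000,0.922
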