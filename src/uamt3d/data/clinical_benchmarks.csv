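setting,method,dsc,jaccard,hd95,asd
labeled_5,mt,0.62,0.45,123.80,42.91
labeled_5,uamt,0.75,0.60,18.28,4.56
labeled_5,urpc,0.75,0.60,15.55,2.78
labeled_5,ours,0.73,0.57,20.98,1.89
labeled_10,mt,0.75,0.60,20.94,5.22
labeled_10,uamt,0.76,0.61,27.74,6.10
labeled_10,urpc,0.76,0.61,13.36,2.33
labeled_10,ours,0.82,0.70,8.93,1.49
labeled_20,mt,0.79,0.66,13.72,3.16
labeled_20,uamt,0.79,0.66,13.23,5.39
labeled_20,urpc,0.78,0.64,13.21,1.75
labeled_20,ours,0.81,0.68,8.48,1.70
ablation_10,plain_unet,0.78,0.65,13.91,3.10
ablation_10,res_unet,0.79,0.66,11.60,2.07
ablation_10,ours,0.82,0.70,8.93,1.49
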