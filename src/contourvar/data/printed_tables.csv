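site,structure,n_vt,vt_mean,vt_sd,n_via,via_mean,via_sd,n_edef,edef_mean,edef_sd,n_edef2,edef2_mean,edef2_sd,n_vio,vio_mean,vio_sd,margin_printed
head_neck,Anterior Oral Cavity,60,3.7,1.3,10,2.3,0.6,60,3.0,1.2,,,,30,5.0,1.3,5.8
head_neck,Brainstem,60,2.4,0.8,10,1.3,0.4,60,2.0,0.7,,,,30,1.7,0.5,2.6
head_neck,Cord,60,1.5,0.3,10,0.9,0.2,60,1.2,0.2,,,,30,1.5,0.3,1.9
head_neck,Left Eye,60,1.4,0.5,10,0.7,0.3,60,1.1,0.4,,,,30,1.0,0.3,1.5
head_neck,Right Eye,60,1.4,0.5,10,0.7,0.3,60,1.2,0.4,,,,30,1.0,0.3,1.5
head_neck,Larynx,58,2.3,1.1,10,1.5,0.8,58,1.8,0.8,,,,29,2.6,0.8,3.2
head_neck,Left Optic Nerve,60,1.6,0.7,10,0.4,0.2,60,1.5,0.6,,,,30,1.7,0.5,2.6
head_neck,Right Optic Nerve,60,1.6,0.8,10,0.7,0.5,60,1.4,0.6,,,,30,1.5,0.4,2.8
head_neck,Left Parotid,56,2.2,0.5,10,1.6,0.3,56,1.5,0.4,,,,28,2.2,0.6,2.6
head_neck,Right Parotid,60,2.3,0.8,10,1.4,0.3,60,1.8,0.8,,,,30,2.2,1.1,2.8
pelvis,Prostate,40,3.0,1.0,10,1.8,0.6,40,2.4,0.8,0,,,20,2.8,0.8,3.7
pelvis,Bladder,40,3.4,2.3,10,1.3,0.4,40,3.1,2.3,14,2.6,1.9,20,1.6,0.5,3.1
pelvis,Rectum,40,3.2,1.6,10,2.5,1.1,40,1.9,1.1,8,1.7,1.1,20,3.1,1.3,3.6
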