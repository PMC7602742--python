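tissue,f_ew,f_iw,f_nl,f_npl,protein_ratio,ph_iw
adipose,0.135,0.017,0.853,0.0016,0.049,7.0
bone,0.100,0.346,0.0174,0.0016,0.100,7.0
brain,0.162,0.620,0.0391,0.0015,0.048,7.0
gut,0.282,0.475,0.0487,0.0163,0.158,7.0
heart,0.320,0.456,0.0115,0.0166,0.157,7.0
kidney,0.273,0.483,0.0207,0.0162,0.130,7.0
liver,0.161,0.573,0.0348,0.0252,0.086,7.0
lung,0.336,0.446,0.0022,0.0128,0.212,7.0
muscle,0.118,0.630,0.0238,0.0072,0.064,7.0
skin,0.382,0.291,0.0284,0.0111,0.277,7.0
spleen,0.207,0.579,0.0201,0.0198,0.097,7.0
rest_of_body,0.118,0.630,0.0238,0.0072,0.064,7.0
plasma,0.945,0.0,0.0023,0.0013,1.0,7.4
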