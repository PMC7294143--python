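assay_id,direction,avg_fc_miR16,avg_fc_miR93
hsa-let-7c-5p,up,6.936,2.569
hsa-let-7d-5p,up,4.521,2.360
hsa-let-7e-5p,up,3.619,1.940
hsa-miR-144-5p,up,4.656,2.802
hsa-miR-186-5p,up,4.667,1.800
hsa-miR-20b-5p,up,69.990,12.134
hsa-miR-331-3p,up,32.978,20.656
hsa-miR-379-5p,up,127.829,49.628
hsa-miR-410-3p,up,321.130,103.873
hsa-miR-495-3p,up,24.731,41.811
hsa-miR-532-5p,up,3.466,1.727
hsa-miR-98-5p,up,5.873,2.369
hsa-miR-99b-5p,up,3.824,1.651
hsa-miR-450a-5p,down,0.516,0.347
hsa-miR-450b-5p,down,0.006,0.005
hsa-miR-505-5p,down,0.141,0.041
hsa-miR-589-5p,down,0.242,0.316
hsa-miR-603,down,0.187,0.140
hsa-miR-934,down,0.346,0.230
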