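indicator,Cy0,LinRegPCR,Standard-Cq,PCR-Miner,MAK2,LRE-E100,5PSM,DART,FPLM,LRE-Emax,FPK-PCR
bias,3,2,1,4,5,6,7,10,9,11,8
linearity,2,1,3,4,6,5,10,9,8,7,11
precision,1,2,4,6,3,5,7,8,10,9,11
resolution,1,5,2,3,4,6,8,7,9,11,10
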