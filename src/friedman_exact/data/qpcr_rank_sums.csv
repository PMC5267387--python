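method,rank_sum
Cy0,7
LinRegPCR,10
Standard-Cq,10
PCR-Miner,17
MAK2,18
LRE-E100,22
5PSM,32
DART,34
FPLM,36
LRE-Emax,38
FPK-PCR,40
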