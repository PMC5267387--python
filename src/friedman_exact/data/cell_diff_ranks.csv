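method,GDS2431,GDS2666,GDS2667,GDS2668,GDS2669,GDS2671,GDS2672,GDS586,GDS587,GDS2688
MCE-euclid-FC,1,2,1,6,6,1,1,10,8,1
PCA-FC,5,1,6,1,1.5,12,8,5.5,1,3
PLS-AREA,6.5,8,4,3,4.5,5,6,7.5,3,6
PCA-AREA,4,6.5,3,2,7,11,7,7.5,2,2
MCE-euclid-AREA,3,3.5,2,5,9,3.5,5,11,9,4
PLS-FC,9,5,8,4,1.5,3.5,12,5.5,5.5,5
SVMRank-FC,11,9,5,8,8,6,3,1,5.5,7
SVMRank-AREA,9,11,9,7,3,10,2,2,4,8
PLS-FC-time,9,3.5,11,11,4.5,8,10,3,10,9
PLS-AREA-time,6.5,6.5,12,12,12,9,4,4,7,10
Pathrecon,2,12,7,10,11,2,9,9,11,
PCA-Markers,12,10,10,9,10,7,11,12,12,
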