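sample_id,RC_healthy,VC_healthy,AC_healthy,RC_parasitoid,VC_parasitoid,AC_parasitoid
1,221,301,291,0,2,4
2,276,544,527,1,2,3
3,362,690,664,0,3,2
4,278,466,489,1,2,4
5,268,378,375,2,6,6
6,301,591,604,1,2,1
7,279,466,487,8,18,15
8,260,553,505,3,8,9
9,334,402,399,0,7,3
10,292,520,544,0,3,2
11,216,407,388,2,2,2
12,284,546,582,3,10,5
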