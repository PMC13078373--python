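parameter,strain,estimate,se
a,Hy-Line W36,0.0861,0.0030
a,Isa Brown,0.1006,0.0052
a,Dekalb White,0.1162,0.0096
a,Bovans White,0.1166,0.0100
a,Bovans Brown,0.1201,0.0131
a,Shaver,0.1116,0.0084
b,Hy-Line W36,0.0219,0.0033
b,Isa Brown,0.1342,0.0028
b,Dekalb White,0.1615,0.0048
b,Bovans White,0.1658,0.0049
b,Bovans Brown,0.1351,0.0076
b,Shaver,0.1593,0.0047
c,Hy-Line W36,2.2129,0.2001
c,Isa Brown,3.1921,0.3771
c,Dekalb White,3.9070,0.6134
c,Bovans White,3.9254,0.6343
c,Bovans Brown,2.8148,0.5592
c,Shaver,4.2621,0.6419
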