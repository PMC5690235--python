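class,label,mode,season,kmh
0,Grass,bus,dry,4.0
0,Grass,bus,wet,3.0
0,Grass,car,dry,4.0
0,Grass,car,wet,3.0
1,Forest,bus,dry,3.5
1,Forest,bus,wet,2.0
1,Forest,car,dry,3.5
1,Forest,car,wet,2.0
2,Scrub,bus,dry,3.5
2,Scrub,bus,wet,2.0
2,Scrub,car,dry,3.5
2,Scrub,car,wet,2.0
3,Rocky,bus,dry,2.5
3,Rocky,bus,wet,1.0
3,Rocky,car,dry,2.5
3,Rocky,car,wet,1.0
4,Local Road,bus,dry,4.0
4,Local Road,bus,wet,3.5
4,Local Road,car,dry,15.0
4,Local Road,car,wet,10.0
5,Provincial Road,bus,dry,10.0
5,Provincial Road,bus,wet,10.0
5,Provincial Road,car,dry,30.0
5,Provincial Road,car,wet,25.0
6,National Road,bus,dry,40.0
6,National Road,bus,wet,40.0
6,National Road,car,dry,60.0
6,National Road,car,wet,25.0
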