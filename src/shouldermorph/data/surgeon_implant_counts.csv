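rater_id,role,a_tp,r_tp,a_fn,r_fn
01,CoD,29,36,21,14
02,Con,26,36,25,13
03,Res,27,35,24,14
04,Con,24,31,27,18
05,Con,32,37,18,13
06,Reg,24,27,26,23
07,Reg,30,30,20,20
08,Con,27,32,23,18
09,Reg,19,40,31,10
10,Reg,28,40,22,10
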