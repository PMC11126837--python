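sample_id,class,conc_oue,ci_low,ci_high,predicted_class,pred_model_a,pred_model_b
1,Leachate,170,75,330,Leachate,69,107
2,Leachate,250,110,480,Leachate,240,247
3,Leachate,450,200,870,Leachate,354,328
4,Landfill Gas,317,140,610,Fresh Waste,119,142
5,Landfill Gas,610,270,1200,Landfill Gas,528,437
6,Landfill Gas,200,88,390,Landfill Gas,98,133
7,Landfill Gas,500,220,970,Landfill Gas,255,172
8,Landfill Gas,130,57,250,Landfill Gas,230,246
9,Fresh Waste,150,66,290,Fresh Waste,190,242
10,Fresh Waste,260,110,500,Fresh Waste,219,76
11,Fresh Waste,60,26,120,Fresh Waste,46,305
12,Fresh Waste,290,130,560,Fresh Waste,248,161
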