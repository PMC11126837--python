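event_no,date,duration_min,receptor_class,fenceline_class,fenceline_conc,wind_category,wind_from,wind_to
1,2020-06-29,60,Air,Landfill Gas,710,weak,WNW,ESE
2,2020-07-01,10,Air,Landfill Gas,150,weak,N,S
3,2020-07-01,20,Air,Landfill Gas,270,weak,N,S
4,2020-07-02,10,Air,Fresh Waste,50,weak,NW,SE
5,2020-07-02,20,Air,Landfill Gas,190,weak,SW,NE
6,2020-07-02,20,Air,Landfill Gas,90,weak,N,S
7,2020-07-03,60,Unknown,Air,20,weak,N,S
8,2020-07-04,10,Air,Landfill Gas,400,weak,SE,NW
9,2020-07-06,90,Landfill Gas,Landfill Gas,300,weak,N,S
10,2020-07-08,40,Air,Landfill Gas,320,weak,S,N
11,2020-07-08,25,Air,Fresh Waste,120,weak,S,N
12,2020-07-08,25,Air,Landfill Gas,520,weak,SSE,NNW
13,2020-07-08,40,Air,Fresh Waste,210,weak,S,N
14,2020-07-09,60,Landfill Gas,Landfill Gas,700,weak,N,S
15,2020-07-11,40,Air,Landfill Gas,340,strong,NE,SW
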