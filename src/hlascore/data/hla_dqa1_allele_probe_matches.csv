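allele,probe_set,p1,p2,p3,p4,p5,p6,p7,p8,p9,p10,p11
HLA-DQA1*0101.1,203290_at,0,0,0,0,0,1,0,0,0,0,0
HLA-DQA1*0102,203290_at,0,0,0,0,0,1,0,0,0,0,0
HLA-DQA1*0103,203290_at,0,0,0,0,0,1,0,0,0,0,0
HLA-DQA1*0201,203290_at,0,0,0,0,0,0,0,0,0,0,0
HLA-DQA1*0301.1,203290_at,0,0,0,0,1,0,0,0,0,0,0
HLA-DQA1*0401,203290_at,1,1,1,1,1,1,1,1,1,1,1
HLA-DQA1*0501,203290_at,1,1,1,0,0,1,1,1,1,1,1
HLA-DQA1*0101.1,213831_at,1,1,1,1,1,0,0,1,1,1,1
HLA-DQA1*0102,213831_at,1,1,1,1,1,1,1,0,0,0,1
HLA-DQA1*0103,213831_at,1,1,1,1,1,1,1,1,1,1,1
HLA-DQA1*0201,213831_at,1,0,0,0,0,0,0,0,0,0,0
HLA-DQA1*0301.1,213831_at,1,0,0,0,0,0,0,0,0,0,0
HLA-DQA1*0401,213831_at,0,0,0,0,0,0,0,0,0,0,0
HLA-DQA1*0501,213831_at,0,0,0,0,0,0,0,0,0,0,0
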