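participant_id,age,gender,aq10,wst,conscientious
p140,28,male,5,32,True
p203,36,female,7,12,True
p082,30,female,1,28,True
p130,48,female,4,29,True
p041,43,female,4,29,True
p025,57,female,3,31,True
p097,21,female,3,8,True
p166,22,female,0,23,True
p234,39,male,10,42,True
p186,57,female,3,11,True
p226,41,female,8,34,True
p098,58,female,5,16,True
p145,35,female,5,17,True
p107,55,female,5,24,True
p155,58,female,3,29,True
p168,24,female,0,34,True
p076,58,male,0,37,True
p040,42,male,0,23,True
p102,40,female,0,41,True
p029,42,female,4,25,True
p161,21,female,5,7,True
p134,56,female,1,14,True
p159,47,female,0,31,True
p173,44,female,0,34,True
p174,58,female,0,16,True
p231,44,female,9,26,True
p122,43,male,0,7,True
p110,53,female,3,12,True
p067,37,female,1,33,True
p108,46,female,0,28,True
p058,18,female,1,27,True
p185,37,male,2,15,True
p200,58,female,6,12,True
p224,21,female,10,17,True
p237,39,female,6,27,True
p183,54,female,1,14,True
p100,44,female,1,42,True
p059,29,male,0,6,True
p106,18,female,1,14,True
p089,32,female,1,41,True
p045,58,female,1,16,True
p080,60,female,5,27,True
p077,32,female,4,7,True
p061,57,female,3,41,True
p193,52,female,0,35,True
p150,31,female,4,40,True
p101,48,female,1,23,True
p170,20,female,2,39,True
p171,59,female,0,17,True
p240,53,male,10,11,True
p206,37,female,10,12,True
p054,34,female,2,19,True
p021,19,female,2,23,True
p121,33,female,2,31,True
p043,18,female,4,18,True
p210,43,female,9,29,True
p204,18,female,6,10,True
p136,59,male,2,40,True
p190,35,female,1,6,True
p177,19,female,5,25,True
p014,59,female,4,15,True
p239,18,female,7,23,True
p157,60,female,4,38,True
p044,24,female,1,28,True
p214,21,female,8,21,True
p208,24,male,8,6,True
p143,39,male,1,26,True
p132,36,male,2,27,True
p065,20,female,3,34,True
p127,23,female,3,23,True
p179,54,female,4,25,True
p163,60,female,4,12,True
p022,34,male,2,12,True
p012,24,male,3,31,True
p207,50,female,8,35,True
p178,50,female,2,19,True
p211,37,female,7,37,True
p087,51,female,2,6,True
p042,55,female,4,29,True
p164,35,female,4,22,True
p034,42,female,3,19,True
p151,56,female,2,19,True
p169,21,female,3,14,True
p055,42,female,4,13,True
p115,36,female,0,26,True
p181,54,female,2,33,True
p230,40,female,10,16,True
p175,55,female,0,22,True
p141,51,female,2,12,True
p084,29,female,2,15,True
p198,36,female,9,11,True
p062,44,male,4,15,True
p126,59,female,2,27,True
p052,35,female,2,31,True
p074,45,female,1,9,True
p228,28,female,6,27,True
p011,46,male,3,8,True
p129,31,female,1,31,True
p035,22,male,3,39,True
p201,46,female,10,23,True
p142,26,female,4,20,True
p024,31,male,0,17,True
p079,19,female,5,18,True
p091,18,female,4,10,True
p112,34,male,4,21,True
p202,31,female,9,31,True
p053,35,female,0,23,True
p219,41,female,9,35,True
p154,38,female,1,7,True
p216,37,female,8,19,True
p156,58,female,2,35,True
p056,55,female,1,7,True
p125,18,female,1,6,True
p194,19,female,0,30,True
p146,36,female,1,8,True
p189,27,female,5,25,True
p050,32,female,5,39,True
p243,23,male,8,30,True
p172,34,female,0,28,True
p242,56,female,7,26,True
p199,36,female,7,27,True
p147,51,male,5,33,True
p133,37,female,0,40,True
p096,23,female,1,12,True
p063,54,female,4,15,True
p246,42,female,9,28,True
p068,27,female,4,9,True
p229,44,male,8,22,True
p051,21,male,4,34,True
p083,50,male,4,13,True
p212,56,female,8,16,True
p165,26,female,1,42,True
p196,25,female,2,30,False
p078,41,male,3,16,True
p149,55,male,3,15,True
p180,43,female,0,9,True
p123,60,female,1,30,True
p209,45,female,9,10,True
p236,38,male,6,27,True
p027,19,female,0,11,True
p176,49,male,3,16,True
p075,55,female,1,6,True
p222,28,female,9,41,True
p046,22,female,2,23,True
p093,54,female,1,35,True
p020,37,male,0,9,True
p244,51,female,7,28,True
p038,18,female,4,6,True
p113,19,female,5,21,True
p135,41,male,1,20,True
p031,33,female,5,29,True
p162,57,male,5,6,True
p188,27,female,0,27,True
p232,58,female,7,24,True
p009,32,female,2,19,True
p167,46,male,3,35,True
p005,46,female,4,22,True
p114,36,female,3,27,True
p117,33,male,3,11,True
p085,34,female,5,30,True
p017,53,male,0,20,True
p016,47,male,5,6,True
p088,47,male,2,21,True
p158,35,female,1,6,True
p028,29,female,5,38,True
p124,20,female,3,11,True
p036,52,male,1,7,True
p000,33,female,1,38,True
p245,55,female,9,29,True
p192,56,female,4,26,True
p153,42,male,2,21,True
p138,60,female,1,36,True
p144,58,male,1,9,True
p099,26,male,3,32,True
p118,29,female,3,33,True
p241,31,female,6,29,True
p086,42,female,3,39,True
p008,56,female,1,30,True
p197,22,female,3,4,True
p111,29,female,2,10,True
p103,28,female,1,26,True
p030,46,male,2,14,True
p235,36,female,6,7,True
p019,49,female,0,39,True
p026,51,female,3,31,True
p213,60,female,8,17,True
p182,51,female,5,40,True
p069,20,female,1,28,True
p119,59,female,2,24,True
p013,19,male,5,38,True
p001,57,male,2,10,True
p205,30,female,9,37,True
p218,43,female,6,15,True
p060,54,female,5,14,True
p215,27,male,8,41,True
p195,41,female,2,22,True
p152,33,female,4,30,True
p037,56,female,2,29,True
p227,57,female,9,24,True
p191,20,male,1,8,True
p095,56,male,2,12,True
p057,33,female,2,13,True
p225,47,male,6,9,True
p233,23,male,8,6,True
p081,36,female,4,14,True
p004,50,female,3,40,True
p120,34,female,2,21,True
p007,34,female,0,6,True
p092,23,female,0,31,True
p033,37,female,1,16,True
p090,34,female,3,29,True
p018,28,female,1,10,True
p073,44,female,0,15,True
p104,40,female,4,27,True
p105,46,male,1,20,True
p015,36,female,5,42,True
p187,30,female,3,33,True
p137,59,male,3,8,True
p066,54,female,4,40,True
p049,36,female,5,12,True
p070,18,male,2,21,True
p032,24,female,0,28,True
p220,53,female,8,16,True
p116,58,female,5,22,True
p072,49,female,1,23,True
p039,45,female,4,12,True
p003,22,female,0,18,True
p023,44,female,0,18,True
p010,35,female,3,6,True
p139,20,male,5,24,True
p148,31,male,5,10,True
p006,54,female,3,22,True
p238,29,female,9,36,True
p109,37,female,4,9,True
p064,24,female,3,29,True
p223,46,male,10,29,True
p184,57,male,2,24,True
p048,46,male,4,35,True
p128,35,female,1,18,True
p131,59,female,2,22,True
p221,21,male,7,10,True
p002,40,female,3,6,True
p160,45,female,2,12,True
p094,55,male,0,7,True
p047,57,male,5,33,True
p071,34,male,2,26,True
p217,37,male,8,7,True
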