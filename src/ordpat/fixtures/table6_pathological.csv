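record_id,label,p_1,p_2,p_3,p_4,p_5,p_6
Pathological00,Pathological,0.4054,0.0838,0.0920,0.1085,0.1938,0.1161
Pathological01,Pathological,0.3260,0.0960,0.1036,0.1207,0.2244,0.1290
Pathological02,Pathological,0.4496,0.0659,0.0683,0.1163,0.1822,0.1175
Pathological03,Pathological,0.3405,0.0980,0.0926,0.1089,0.2534,0.1062
Pathological04,Pathological,0.2191,0.1271,0.1348,0.1374,0.2347,0.1465
Pathological05,Pathological,0.2736,0.0979,0.1083,0.1348,0.2407,0.1444
Pathological06,Pathological,0.3805,0.0979,0.0992,0.1204,0.1793,0.1224
Pathological07,Pathological,0.3331,0.0950,0.0950,0.1347,0.2072,0.1347
Pathological08,Pathological,0.4361,0.0711,0.0660,0.1219,0.1873,0.1174
Pathological09,Pathological,0.3103,0.1065,0.1019,0.1287,0.2283,0.1241
Pathological10,Pathological,0.4342,0.0756,0.0919,0.0968,0.1881,0.1131
Pathological11,Pathological,0.3447,0.1224,0.1155,0.1265,0.1716,0.1190
Pathological12,Pathological,0.3590,0.0972,0.1072,0.1054,0.2154,0.1154
Pathological13,Pathological,0.4056,0.0838,0.0943,0.0950,0.2154,0.1056
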