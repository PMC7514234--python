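record_id,label,p_1,p_2,p_3,p_4,p_5,p_6
Control00,Control,0.4058,0.0836,0.0941,0.1255,0.1548,0.1359
Control01,Control,0.5376,0.0899,0.0836,0.0878,0.1192,0.0815
Control02,Control,0.3849,0.0753,0.0836,0.1025,0.2426,0.1108
Control03,Control,0.3870,0.0732,0.0878,0.1129,0.2092,0.1297
Control04,Control,0.3242,0.1276,0.1255,0.1171,0.1903,0.1150
Control05,Control,0.3598,0.0962,0.0983,0.1213,0.2008,0.1234
Control06,Control,0.3912,0.0815,0.0648,0.1401,0.1987,0.1234
Control07,Control,0.3410,0.1004,0.1317,0.0815,0.2322,0.1129
Control08,Control,0.3368,0.0941,0.0983,0.1171,0.2301,0.1234
Control09,Control,0.3159,0.1171,0.1255,0.1234,0.1841,0.1338
Control10,Control,0.4560,0.0920,0.0962,0.1129,0.1276,0.1150
Control11,Control,0.3556,0.1004,0.1171,0.1213,0.1694,0.1359
Control12,Control,0.5334,0.0732,0.0753,0.0899,0.1380,0.0899
Control13,Control,0.2615,0.1066,0.1234,0.1317,0.2301,0.1464
Control14,Control,0.4058,0.0836,0.0941,0.1255,0.1548,0.1359
Control15,Control,0.4518,0.0774,0.0878,0.1276,0.1192,0.1359
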