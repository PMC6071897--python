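patient_id,home_quintile,home_block_group,moved,move_date,destination_quintile,destination_block_group,destination_address
P000000,3,BG00021,False,,,,
P000001,1,BG00023,False,,,,
P000002,5,BG00024,False,,,,
P000003,5,BG00007,False,,,,
P000004,5,BG00026,False,,,,
P000005,3,BG00017,True,2015-12-24,3.0,BG00021,2085 BG00021 ST
P000006,1,BG00027,False,,,,
P000007,2,BG00019,False,,,,
P000008,1,BG00023,False,,,,
P000009,4,BG00005,False,,,,
P000010,2,BG00019,True,2016-08-15,2.0,BG00029,7625 BG00029 ST
P000011,3,BG00014,True,2016-01-21,3.0,BG00013,6989 BG00013 ST
P000012,1,BG00028,False,,,,
P000013,3,BG00014,False,,,,
P000014,2,BG00006,True,2016-10-25,3.0,BG00014,5079 BG00014 ST
P000015,5,BG00026,False,,,,
P000016,1,BG00027,True,2016-05-18,1.0,BG00027,3962 BG00027 ST
P000017,3,BG00017,False,,,,
P000018,1,BG00018,False,,,,
P000019,2,BG00004,False,,,,
P000020,4,BG00008,False,,,,
P000021,2,BG00019,False,,,,
P000022,3,BG00017,True,2016-02-15,2.0,BG00019,7771 BG00019 ST
P000023,1,BG00025,False,,,,
P000024,2,BG00004,False,,,,
P000025,2,BG00022,False,,,,
P000026,1,BG00018,True,2016-04-02,1.0,BG00027,8881 BG00027 ST
P000027,1,BG00009,False,,,,
P000028,3,BG00014,False,,,,
P000029,5,BG00007,False,,,,
P000030,3,BG00001,True,2016-09-17,3.0,BG00000,1699 BG00000 ST
P000031,2,BG00003,False,,,,
P000032,5,BG00016,False,,,,
P000033,4,BG00012,False,,,,
P000034,2,BG00019,True,2015-09-04,5.0,BG00020,6001 BG00020 ST
P000035,4,BG00005,False,,,,
P000036,2,BG00004,True,2015-12-31,3.0,BG00014,8190 BG00014 ST
P000037,4,BG00012,True,2016-04-23,5.0,BG00024,8261 BG00024 ST
P000038,3,BG00017,False,,,,
P000039,1,BG00027,True,2015-12-24,3.0,BG00021,5894 BG00021 ST
P000040,1,BG00025,False,,,,
P000041,1,BG00027,False,,,,
P000042,1,BG00028,False,,,,
P000043,1,BG00028,False,,,,
P000044,1,BG00023,True,2016-04-08,1.0,BG00025,709 BG00025 ST
P000045,5,BG00007,False,,,,
P000046,1,BG00028,False,,,,
P000047,1,BG00009,False,,,,
P000048,4,BG00012,True,2016-01-20,3.0,BG00001,9145 BG00001 ST
P000049,4,BG00015,False,,,,
P000050,1,BG00025,False,,,,
P000051,2,BG00006,True,2015-10-31,2.0,BG00022,8844 BG00022 ST
P000052,3,BG00021,True,2016-10-28,3.0,BG00014,7504 BG00014 ST
P000053,3,BG00013,False,,,,
P000054,3,BG00000,False,,,,
P000055,5,BG00026,False,,,,
P000056,2,BG00029,False,,,,
P000057,1,BG00009,False,,,,
P000058,1,BG00009,False,,,,
P000059,2,BG00003,False,,,,
P000060,2,BG00006,False,,,,
P000061,5,BG00020,False,,,,
P000062,5,BG00026,True,2016-04-17,5.0,BG00026,5277 BG00026 ST
P000063,2,BG00006,False,,,,
P000064,2,BG00029,False,,,,
P000065,2,BG00029,True,2016-08-02,1.0,BG00025,2816 BG00025 ST
P000066,2,BG00019,True,2016-09-07,2.0,BG00004,8335 BG00004 ST
P000067,4,BG00002,True,2016-01-26,1.0,BG00028,7902 BG00028 ST
P000068,2,BG00003,False,,,,
P000069,3,BG00017,False,,,,
P000070,1,BG00023,False,,,,
P000071,4,BG00008,False,,,,
P000072,4,BG00010,False,,,,
P000073,5,BG00020,True,2016-08-26,5.0,BG00026,2302 BG00026 ST
P000074,4,BG00005,False,,,,
P000075,3,BG00017,False,,,,
P000076,2,BG00003,False,,,,
P000077,4,BG00015,False,,,,
P000078,5,BG00020,False,,,,
P000079,1,BG00027,False,,,,
P000080,5,BG00024,False,,,,
P000081,1,BG00018,True,2015-12-26,1.0,BG00009,6074 BG00009 ST
P000082,3,BG00000,False,,,,
P000083,1,BG00009,False,,,,
P000084,3,BG00017,False,,,,
P000085,2,BG00022,True,2016-08-06,1.0,BG00025,5400 BG00025 ST
P000086,3,BG00021,True,2016-01-07,3.0,BG00000,2528 BG00000 ST
P000087,3,BG00014,False,,,,
P000088,4,BG00015,False,,,,
P000089,1,BG00025,True,2016-03-23,1.0,BG00027,7257 BG00027 ST
P000090,5,BG00016,True,2016-05-24,5.0,BG00024,4857 BG00024 ST
P000091,3,BG00013,False,,,,
P000092,2,BG00019,True,2015-10-11,3.0,BG00001,6686 BG00001 ST
P000093,1,BG00018,False,,,,
P000094,5,BG00016,True,2016-01-19,2.0,BG00004,5906 BG00004 ST
P000095,3,BG00021,False,,,,
P000096,4,BG00008,False,,,,
P000097,3,BG00017,False,,,,
P000098,3,BG00017,False,,,,
P000099,1,BG00028,False,,,,
P000100,5,BG00024,False,,,,
P000101,1,BG00025,False,,,,
P000102,2,BG00006,True,2015-09-29,3.0,BG00001,5271 BG00001 ST
P000103,5,BG00011,False,,,,
P000104,3,BG00021,True,2015-11-04,3.0,BG00014,6503 BG00014 ST
P000105,5,BG00016,False,,,,
P000106,3,BG00013,False,,,,
P000107,5,BG00020,True,2016-03-06,2.0,BG00006,2498 BG00006 ST
P000108,4,BG00010,False,,,,
P000109,2,BG00022,False,,,,
P000110,3,BG00021,False,,,,
P000111,5,BG00026,False,,,,
P000112,4,BG00012,False,,,,
P000113,5,BG00026,True,2015-09-24,5.0,BG00024,3347 BG00024 ST
P000114,3,BG00013,True,2015-12-31,5.0,BG00016,5503 BG00016 ST
P000115,3,BG00014,False,,,,
P000116,1,BG00009,False,,,,
P000117,2,BG00022,False,,,,
P000118,4,BG00002,False,,,,
P000119,1,BG00009,True,2015-11-20,3.0,BG00000,2084 BG00000 ST
P000120,3,BG00013,False,,,,
P000121,1,BG00028,False,,,,
P000122,1,BG00025,False,,,,
P000123,3,BG00013,False,,,,
P000124,5,BG00011,True,2016-05-28,4.0,BG00008,2833 BG00008 ST
P000125,2,BG00019,False,,,,
P000126,3,BG00017,False,,,,
P000127,2,BG00022,True,2016-04-18,2.0,BG00022,543 BG00022 ST
P000128,2,BG00029,True,2016-08-12,1.0,BG00009,8321 BG00009 ST
P000129,2,BG00006,False,,,,
P000130,4,BG00002,False,,,,
P000131,2,BG00019,False,,,,
P000132,1,BG00018,False,,,,
P000133,4,BG00015,True,2016-01-23,2.0,BG00004,5900 BG00004 ST
P000134,2,BG00019,False,,,,
P000135,3,BG00000,True,2015-11-21,2.0,BG00029,6332 BG00029 ST
P000136,1,BG00009,False,,,,
P000137,2,BG00006,True,2015-09-15,2.0,BG00003,6978 BG00003 ST
P000138,4,BG00005,True,2016-10-18,4.0,BG00008,6505 BG00008 ST
P000139,4,BG00002,False,,,,
P000140,4,BG00015,True,2016-10-27,4.0,BG00015,5644 BG00015 ST
P000141,1,BG00027,False,,,,
P000142,2,BG00006,False,,,,
P000143,3,BG00000,False,,,,
P000144,2,BG00019,False,,,,
P000145,3,BG00000,False,,,,
P000146,4,BG00005,False,,,,
P000147,2,BG00006,False,,,,
P000148,2,BG00004,True,2016-08-22,5.0,BG00024,3418 BG00024 ST
P000149,1,BG00009,True,2016-09-05,2.0,BG00003,6508 BG00003 ST
P000150,3,BG00017,True,2016-06-29,1.0,BG00027,1433 BG00027 ST
P000151,2,BG00006,False,,,,
P000152,3,BG00014,False,,,,
P000153,2,BG00003,False,,,,
P000154,4,BG00008,False,,,,
P000155,2,BG00004,False,,,,
P000156,4,BG00008,True,2015-10-10,5.0,BG00026,4656 BG00026 ST
P000157,5,BG00020,False,,,,
P000158,1,BG00023,False,,,,
P000159,5,BG00020,True,2016-10-24,4.0,BG00015,2560 BG00015 ST
P000160,2,BG00003,False,,,,
P000161,1,BG00023,False,,,,
P000162,1,BG00028,True,2016-05-23,1.0,BG00027,3271 BG00027 ST
P000163,2,BG00004,True,2015-09-29,2.0,BG00006,7871 BG00006 ST
P000164,2,BG00006,False,,,,
P000165,2,BG00019,True,2016-08-19,4.0,BG00010,3630 BG00010 ST
P000166,1,BG00009,False,,,,
P000167,2,BG00029,False,,,,
P000168,3,BG00021,True,2016-03-19,3.0,BG00017,3933 BG00017 ST
P000169,2,BG00006,False,,,,
P000170,1,BG00018,False,,,,
P000171,1,BG00025,False,,,,
P000172,2,BG00003,True,2016-07-01,2.0,BG00006,9566 BG00006 ST
P000173,4,BG00008,False,,,,
P000174,2,BG00029,False,,,,
P000175,5,BG00020,False,,,,
P000176,1,BG00025,False,,,,
P000177,4,BG00015,False,,,,
P000178,1,BG00009,False,,,,
P000179,2,BG00006,False,,,,
P000180,4,BG00012,True,2015-10-15,3.0,BG00013,1640 BG00013 ST
P000181,2,BG00006,False,,,,
P000182,3,BG00001,False,,,,
P000183,1,BG00009,False,,,,
P000184,2,BG00004,False,,,,
P000185,3,BG00013,False,,,,
P000186,3,BG00000,True,2016-02-15,3.0,BG00000,2262 BG00000 ST
P000187,3,BG00014,False,,,,
P000188,1,BG00028,False,,,,
P000189,2,BG00006,False,,,,
P000190,3,BG00001,False,,,,
P000191,5,BG00007,True,2016-07-09,5.0,BG00026,1734 BG00026 ST
P000192,2,BG00004,False,,,,
P000193,2,BG00019,False,,,,
P000194,4,BG00008,False,,,,
P000195,5,BG00020,False,,,,
P000196,3,BG00013,False,,,,
P000197,3,BG00001,True,2016-03-21,3.0,BG00021,9839 BG00021 ST
P000198,1,BG00025,False,,,,
P000199,1,BG00028,False,,,,
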