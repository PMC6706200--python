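transmitter_id,release_site,weight_g,total_length_cm,release_date,days_detected,days_monitored,residency_index,movement_index
1001,II,356,36,2015-08-15,8,156,0.05,0.25
1002,II,185,26,2015-08-15,71,156,0.46,0.04
1003,II,361,34,2015-08-15,133,156,0.85,0.14
1004,II,225,30,2015-08-15,85,156,0.54,0.14
1006,II,210,28,2015-08-15,27,156,0.17,3.44
1007,II,240,31,2015-08-15,45,156,0.29,0.04
1010,II,209,29,2015-08-15,23,156,0.15,6.39
1011,II,400,37,2015-08-15,94,156,0.60,0.02
1012,II,381,35,2015-08-16,3,155,0.02,16.67
1013,II,264,33,2015-08-15,142,156,0.91,0.06
1014,II,120,25,2015-08-16,143,155,0.92,0.13
1015,II,232,30,2015-08-16,24,155,0.15,0.04
1016,II,422,47,2015-08-16,2,155,0.01,0.50
1017,II,241,30,2015-08-16,88,155,0.57,0.50
1019,II,330,33,2015-08-16,94,155,0.61,0.36
1020,I,136,26,2015-08-24,59,147,0.40,0.03
1021,II,35,16,2015-08-16,5,155,0.03,0.40
1022,II,156,28,2015-08-16,4,155,0.03,8.75
1023,II,150,26,2015-08-16,146,155,0.94,0.56
1024,II,116,25,2015-08-16,61,155,0.39,0.02
1025,I,172,28,2015-08-24,40,147,0.27,0.73
1026,I,228,30,2015-08-24,20,147,0.14,0.20
1027,I,117,25,2015-08-24,128,147,0.87,0.03
1028,I,135,25,2015-08-22,148,149,0.99,0.01
1029,I,194,28,2015-08-22,21,149,0.14,0.38
1030,I,438,37,2015-08-22,99,149,0.66,0.06
1031,I,162,26,2015-08-22,29,149,0.19,0.14
1033,I,249,30,2015-08-22,7,149,0.05,0.86
1034,I,197,29,2015-08-21,109,150,0.73,0.06
1035,I,231,28,2015-08-21,2,150,0.01,0.50
1036,I,569,39,2015-08-21,34,150,0.23,0.88
1038,I,173,27,2015-08-21,149,150,0.99,0.33
1040,I,127,26,2015-08-16,36,155,0.23,2.50
1041,I,205,30,2015-08-16,10,155,0.06,0.40
1042,I,413,36,2015-08-16,12,155,0.08,0.33
1043,I,155,27,2015-08-16,6,155,0.04,0.50
1044,I,266,32,2015-08-16,153,155,0.99,0.05
1045,I,131,25,2015-08-16,20,155,0.13,1.00
1046,I,186,28,2015-08-16,12,155,0.08,0.17
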