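name,pubchem_cid,chemspider_id,AZI,M1,M2,mM2,H,ReZG3,Sch,Gut,SDD,I,F,MW,EM,PSA,C,BP,EoV,FP,IoR,MR,P,ST,MV
Acetaminophen,1983,1906,74.125,50,53,2.5,4.9,248,106,496,27,11.45,124,151.16,151.0633,49.3,139,387.8,66.2,188.4,1.619,42.4,16.8,52.8,120.9
Amitriptyline,2160,2075,188.3125,108,126,4.6944,10.0333,624,252,1248,50,26.1,268,277.4,277.18,3.2,331,398.2,64.9,174,1.628,91.5,36.3,47,257.8
Amlodipine,2162,2077,240.625,136,160,6.6389,12.9667,820,320,1640,66,32.4,346,408.9,408.1452,99.9,647,527.2,80.2,272.6,1.546,105.4,41.8,44.4,333
Amoxicillin,33613,31006,209.9397,138,168,5.2639,10.8857,918,336,1836,68.25,31.5476,390,365.4,365.1045,158,590,743.2,113.7,403.3,1.702,91.5,36.3,85.3,236.2
Ativan,3958,3821,182.4531,112,133,4.5556,9.6667,682,266,1364,53,26.5,292,321.2,320.0119,61.7,443,543.6,86.5,282.6,1.694,81,32.1,56,211
Atorvastatin,60823,54810,345.5156,210,245,9.0833,18.9,1238,490,2476,101.3333,49.7,538,558.6,558.253,112,822,722.2,110.7,390.6,1.603,155.2,61.5,46,451.9
Azithromycin,447043,10482163,400.9291,274,327,11.2361,22.1095,1798,654,3596,142.25,61.3405,786,749,748.5085,180,1150,822.1,136,451,1.537,197.6,78.3,50.6,632.7
Benzonatate,7699,7413,334.7656,174,180,10.4444,20.5667,770,360,1540,87.3333,42.7833,372,603.7,603.3619,121,565,649,95.7,346.3,1.495,160.6,63.7,39.8,550.7
Brilinta,9871419,8047109,335.4062,196,238,7.9444,16.8667,1236,476,2472,89.3333,46.9333,512,522.6,522.1861,164,736,777.6,118.7,424,1.744,126.3,50.1,63.3,311.9
Buprenorphine,644073,559124,379.4833,236,319,6.8194,15.5667,1940,638,3880,103.5,54.2833,738,467.6,467.3036,62.2,869,667.4,116.5,401,1.632,131.4,52.1,58.2,368.3
Cephalexin,27447,25541,210.7656,128,155,5.25,10.9,818,310,1636,61,30.2,340,347.4,347.0941,138,600,727.4,111.5,393.7,1.7,89.4,35.4,78.5,231.3
Ciprofloxacin,2764,2662,224.625,134,164,5.1389,11.1667,860,328,1720,61,32,354,331.34,331.1332,72.9,571,581.8,91.5,305.6,1.655,83.3,33,67.4,226.8
Citalopram,2771,2669,196.5386,122,145,5.0278,10.5714,762,290,1524,58.1667,28.5952,326,324.4,324.1638,36.3,466,428.3,68.3,212.8,1.591,92.1,36.5,49.9,272.6
Clindamycin,446598,393915,218.75,136,161,6.1389,12,844,322,1688,68,31.5833,362,425,424.1799,128,502,628.1,106.5,333.6,1.574,107.9,42.8,56.2,327.2
Clonazepam,2802,2700,190.4531,116,137,4.8056,10.1667,698,274,1396,55,27.5,300,315.71,315.0411,87.3,491,524.5,79.8,271,1.701,81.2,32.2,61.8,209.9
Cyclobenzaprine,2895,21168,206.8772,126,148,5.2361,11.0524,766,296,1532,60.9167,29.5476,334,275.4,275.1674,3.2,365,405.9,65.8,177.8,1.646,91.1,36.1,48.5,251.1
Doxycycline,54671203,10482106,295.2174,184,237,6.7778,13.8905,1360,474,2720,87.5,42.5929,532,444.4,444.1533,182,956,762.6,116.5,415,1.737,109,43.2,99.2,271.1
Fentanyl,3345,3228,221.5469,124,142,5.75,12.0667,686,284,1372,57.6667,30.1167,300,336.5,336.2202,23.6,391,466.2,72.8,185.8,1.585,103.7,41.1,45.7,309.4
Gabapentin,3446,3328,86.75,56,62,2.8333,5.4,316,124,632,29.3333,12.7,150,171.24,171.1259,63.3,162,314.4,61.1,144,1.489,46.7,18.5,47.1,161.8
Hydrochlorothiazide,3639,3513,129.6561,94,111,3.4306,7.0714,618,222,1236,50.0833,20.5119,282,297.7,296.9645,135,494,577,86.4,302.7,1.632,62.7,24.9,62,175.8
Ibuprofen,3672,3544,103.6562,70,77,3.3889,6.5667,380,154,760,37.6667,15.95,180,206.28,206.1307,37.3,203,319.6,59.3,216.7,1.519,60.8,24.1,38.1,200.3
Imbruvica,24821094,26637187,310.4844,178,213,7.2778,15.8,1078,426,2156,80,43.0667,452,440.5,440.1961,99.2,678,715,104.5,386.2,1.696,126.1,50,56.5,327.5
Jardiance,11949646,10123957,273.8438,164,194,6.8333,14.4667,984,388,1968,76.6667,39.0667,422,450.9,450.1445,109,558,664.5,102.7,355.7,1.628,114.4,45.4,59.4,322.4
Lisinopril,5362119,4514933,233.8281,138,156,6.7222,13.4333,766,312,1532,68.6667,32.7167,342,405.5,405.2264,133,550,666.4,102.9,356.9,1.578,107.5,42.6,60.4,323.9
Lofexidine,30668,28460,132.2969,80,92,3.5833,7.4,458,184,916,39,18.95,202,259.13,258.0327,33.6,263,421.5,64.9,208.7,1.611,64.7,25.6,43.4,186.3
Loratadine,3957,3820,251.0938,144,172,6,12.8667,872,344,1744,65.3333,34.7667,366,382.9,382.1448,42.4,569,531.3,80.7,275.1,1.614,105.9,42,53.3,303.5
Lyrica,5486971,4589156,61.5,44,44,2.6667,4.6667,204,88,408,26.6667,9.6667,110,159.23,159.1259,63.3,123,274,56.4,119.5,1.465,44.1,17.5,37.9,159.6
Melatonin,896,872,141.5312,84,96,3.8889,7.9333,472,192,944,40.6667,19.9667,210,232.28,232.1212,54.1,270,512.8,78.4,264,1.6,67.6,26.8,46.7,197.6
Meloxicam,54677470,10442740,198.8419,126,153,4.8889,10.2381,830,306,1660,61.3333,29.1286,350,351.4,351.0347,136,628,692,103.1,392.2,1.72,86,34.1,85.3,217.7
Metformin,4091,3949,44.2656,36,36,2.1111,3.6333,174,72,348,23,7.65,94,129.16,129.1014,91.5,132,172.5,40.9,58.1,1.576,33.4,13.2,50.8,100.8
Methadone,4095,3953,194.3626,114,135,5.3194,10.5905,716,270,1432,55.5833,26.8429,300,309.4,309.2093,20.3,346,423.7,67.8,126.5,1.538,95.9,38,37.1,306.5
Methotrexate,126941,112728,259.9531,168,193,7.2222,14.8667,970,386,1940,83.6667,39.1,436,454.4,454.1713,211,704,533.2,101.1,389.7,1.738,119,47.2,96.5,295.7
Metoprolol,4171,4027,138.125,84,89,4.5,8.7667,408,178,816,44,19.7167,200,267.36,267.1834,50.7,215,398.6,68.5,194.9,1.508,77.1,30.6,37.1,258.7
Naltrexone,5360515,4514524,292.3325,176,237,5.0764,12.0262,1396,474,2792,73.5833,41.5238,526,341.4,341.1627,70,621,558.1,88.4,291.4,1.709,90.1,35.7,77.1,230.9
Naproxen,156391,137720,140.2969,86,100,3.8333,7.7667,506,200,1012,42,20.2167,222,230.26,230.0943,46.5,277,403.9,69.1,154.5,1.609,66.5,26.4,47.5,192.3
Narcan,5284596,4447644,276.3325,164,221,5.0764,11.4929,1312,442,2624,69.5833,38.5905,492,327.4,327.1471,70,594,532.8,85.1,276.1,1.691,87.3,34.6,72.1,228.1
Omeprazole,4594,4433,211.0781,126,150,5.3889,11.1,770,300,1540,59.3333,29.8833,328,345.4,345.1147,96.3,453,600,89.3,316.7,1.669,94,37.3,75.2,251.9
Otezla,11561674,9736448,267.1267,168,199,7.0417,14.2667,1048,398,2096,83.4167,38.7667,458,460.5,460.1304,127,825,741.3,108.1,402.1,1.612,115.9,45.9,60.6,333.3
Pantoprazole,4679,4517,223.6875,134,157,5.8611,12.0667,792,314,1584,63.6667,31.7833,344,383.4,383.0751,106,490,586.9,87.6,308.7,1.643,91.4,36.2,73.5,252.7
Prednisone,5865,5656,235.7242,146,185,5.2778,11.2095,1048,370,2096,67.8333,33.8405,422,358.4,358.178,91.7,764,573.7,98.7,314.8,1.604,94.1,37.3,58.6,273.6
Probuphine,3033050,559124,379.4833,236,319,6.8194,15.5667,1940,638,3880,103.5,54.2833,738,467.6,467.3036,62.2,869,583.7,99.2,323.4,1.632,131.4,52.1,58.2,368.3
Qulipta,72163100,59718640,383.681,246,302,8.9306,19.2381,1640,604,3280,116.5833,56.9786,690,603.5,603.1705,104,1110,693.9,101.7,373.5,1.624,138,54.7,63.6,390.9
Tramadol,33741,31105,156.7684,96,112,4.2917,8.6714,586,224,1172,47.4167,22.3286,256,263.37,263.1885,32.7,282,388.1,67.2,188.5,1.533,78,30.9,39.7,251.4
Trazodone,5533,5332,236.3125,138,162,5.6944,12.4333,804,324,1608,63,33.3,346,371.9,371.1513,42.4,611,528.5,80.3,273.4,1.671,104.2,41.3,55.1,278.8
Xanax,2118,2034,211.0938,122,148,4.75,10.5,760,296,1520,54.3333,29.5,314,308.8,308.0829,43.1,434,509,77.9,261.6,1.711,88.2,35,52.2,225.6
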