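pair,night,FR,NR,CC,CR,excluded,exclusion_reason,repetition_total,mb
MS_01,1,11,3,9,10,0,,,0
MS_01,2,6,16,22,135,0,,,0
MS_01,3,7,9,23,41,0,,,0
MS_02,1,3,12,6,5,0,,,0
MS_02,2,2,7,24,80,0,,,0
MS_02,3,,,,,1,opened the contact window in night 3,,0
MS_03,1,5,3,0,3,0,,7,0
MS_03,2,0,1,1,12,0,,39,0
MS_03,3,0,0,0,12,0,,21,0
MS_04,1,3,2,17,4,0,,22,0
MS_04,2,6,2,3,16,0,,39,0
MS_04,3,1,1,20,9,0,,25,0
MS_05,1,5,6,7,6,0,,19,0
MS_05,2,7,24,35,298,0,,413,0
MS_05,3,13,10,24,179,0,,166,0
MS_06,1,7,3,33,5,0,,48,0
MS_06,2,5,18,14,93,0,,173,0
MS_06,3,1,6,5,44,0,,73,0
MS_07,1,5,3,11,5,0,,,0
MS_07,2,7,5,20,85,0,,,0
MS_07,3,0,0,15,13,0,,,0
MS_07,4,0,2,23,6,0,,,1
MS_08,1,2,3,28,1,0,,,0
MS_08,2,1,2,21,48,0,,,0
MS_08,3,0,0,23,20,0,,,0
MS_08,4,2,4,20,23,0,,,0
MS_09,1,1,4,0,2,0,,,0
MS_09,2,0,0,3,10,0,,,0
MS_09,3,0,1,1,3,0,,,0
MS_09,4,0,4,4,3,0,,,0
MS_10,1,3,6,22,4,0,,39,0
MS_10,2,1,6,28,234,0,,152,0
MS_10,3,1,5,23,63,0,,107,0
MS_10,4,3,3,15,90,0,,,5
MS_11,1,1,3,16,1,0,,,0
MS_11,2,2,1,21,13,0,,,0
MS_11,3,0,0,28,1,0,,,0
MS_11,4,0,0,11,3,0,,,8
MS_12,1,1,1,28,1,0,,,0
MS_12,2,1,1,30,63,0,,,0
MS_12,3,1,0,15,23,0,,,0
MS_12,4,0,0,17,18,0,,,0
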