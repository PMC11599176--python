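patient_id,trial_id,dataset_count,LEDD,DBS_Hz,UPDRS3,BBS,PIGD,fog_flag,include_flag
1,1,2,675,130,23,47,5,-,yes
1,2,2,675,130,25,49,5,-,yes
2,3,1,799.5,145,25,54,5,-,yes
2,4,1,799.5,145,24,54,6,+,yes
3,5,1,1137.4,80,42,22,7,-,yes
4,6,2,1090,130,28,53,10,+,yes
4,7,1,1040,130,21,50,7,+,yes
5,8,1,829,130,21,55,2,-,yes
5,9,1,829,130,28,53,3,-,yes
6,10,1,337.5,130,27,53,4,-,yes
6,11,1,337.5,130,28,54,4,-,yes
7,12,1,700,60,28,53,8,-,yes
8,13,2,777.5,130,27,56,1,-,yes
8,14,2,740,145,6,56,0,-,yes
8,15,2,777.5,130,28,56,4,-,no
8,16,2,740,145,28,56,1,-,yes
9,17,2,980,,64,51,6,+,no
10,18,2,900,,26,54,6,-,yes
11,19,1,469.7,90,29,51,12,+,yes
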