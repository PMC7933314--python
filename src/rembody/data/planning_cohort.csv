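patient_id,injections,tgv_cect_ml,tgv_cbct_ml,tgv_maa_ml,tgv_pet_ml,prescribed_gbq,lobar_or_total,changed_administration
1,I:0.75;LHA:0.25,640,626,640,1445,I:0.75;LHA:0.25,0,1
2,VI:0.50;VIII:0.50,392,,412,654,VI:0.5;VIII:0.2,0,0
3,IV:0.50;VIII:0.50,270,206,537,1561,LHA:0.8;RHA:0.7,1,1
4,IV:0.50;VIII:0.50,25,25,83,405,IV:0.3;VIII:0.6,0,1
5,IV:1.00,99,144,218,257,IV:1.0,0,0
6,V-VIII:0.50;IV:0.50,267,292,858,755,V-VIII:0.5;IV:1.0,0,0
7,IV:1.00,135,70,133,181,IV:1.0,0,0
8,VI-VII:1.00,276,228,451,420,VI-VII:1.5,0,0
9,VIII:0.50;VI:0.50,746,511,1127,1277,VIII:1.1;VI:0.5,0,0
10,V-VIII:0.50;IPA:0.50,340,480,707,870,V-VIII:0.65;IPA:0.65,0,0
11,RHA:0.50;RIPA:0.50,1147,1515,1097,1298,RHA:0.9;RIPA:0.7,0,0
12,IV:1.00,361,,350,399,IV-br1:0.4;IV-br2:0.4,0,1
13,VIII:0.33;VII:0.33;II:0.33,960,,917,1118,VIII:0.5;VII:0.5;II:0.2,0,0
14,V-VIII:0.75;IV:0.25,537,,489,622,V-VIII:0.3;IV:0.7,0,0
15,RHA:0.75;IV:0.25,1550,1860,1276,1373,RHA:1.2;IV:0.3,0,0
16,VIII:0.50;VII:0.50,510,903,1260,1357,VIII:0.7;VII:0.7,0,0
17,IV:0.75;II:0.25,290,450,254,350,IV:0.65;II:0.25,0,0
18,AHA:0.42;PHA:0.35;IV:0.22,1186,,1313,1380,AHA:1.7;PHA:1.3;IV:0.4,0,0
19,RHA:0.25;LHA:0.75,1955,1975,1468,1536,RHA:0.4;LHA:1.0,1,0
20,RHA:1.00,2260,2305,2279,2420,RHA:3.4,1,0
21,RHA:0.75;LHA:0.25,1285,1387,1516,1683,RHA:1.0;LHA:0.18,1,0
22,RHA:1.00,760,974,986,992,RHA:0.82,1,0
23,RHA:1.00,700,971,802,922,RHA:0.64,1,0
24,RHA:1.00,580,966,795,792,RHA:1.0,1,0
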