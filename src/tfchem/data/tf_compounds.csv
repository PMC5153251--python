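rt_min,mw_printed,formula,structure,ri_printed,peak_id,tf_only
13.35,212,C15H32,Pentadecane,1500,,0
14.05,226,C16H34,5-methylpentadecane,1541,,0
15.05,226,C16H34,Hexadecane,1600,,0
16.47,240,C17H36,Heptadecane,1700,,0
17.06,254,C18H38,7-methylheptadecane,1742,,0
17.83,254,C18H38,Octadecane,1800,,0
19.15,268,C19H40,Nonadecane,1900,,0
19.89,295,C21H44,*-trimethyloctadecane,1950,,0
19.97,256,C16H32O2,n-Hexadecanoic acid,1956,,0
20.17,282,C18H34O2,"Hexadecenoic acid, ethyl ester",1970,,0
20.50,284,C18H36O2,Ethyl palmitate,1992,,0
20.62,282,C20H42,Eicosane,2000,,0
20.98,268,C18H36O,Octadecanal,2020,,0
22.89,280,C18H32O2,Linoleic acid,2125,,0
23.03,282,C18H34O2,Oleic acid,2137,,1
23.46,308,C20H36O2,"*-Octadecadienoic acid, ethyl ester (possibly Ethyl linoleate)",2155,,0
23.59,310,C20H38O2,Ethyl oleate,2165,,1
24.30,310,C22H46,Docosane,2200,,0
26.27,322,C23H46,*-tricosene,2279,,1
26.56,324,C23H48,Tricosane,2300,,0
29.08,338,C24H50,Tetracosane,2400,,0
30.76,352,C25H52,2-methyltetracosane,2461,,0
31.05,350,C25H50,*-pentacosene,2472,,0
31.26,350,C25H50,*-pentacosene,2480,,0
31.80,352,C25H52,Pentacosane,2500,,0
34.69,366,C26H54,Hexacosane,2600,,0
36.37,380,C27H56,4-methylhexacosane,2658,,0
36.91,378,C27H54,*-heptacosene,2675,,0
37.70,380,C27H56,Heptacosane,2700,,0
39.19,394,C28H58,5-methylheptacosane,2755,,0
40.63,394,C28H58,Octacosane,2800,,0
41.36,422,C30H62,*-trimethylheptacosane,2835,,0
41.88,408,C29H60,4-methyloctacosane,2860,,0
42.23,406,C29H58,*-nonacosene,2877,,0
42.47,422,C30H62,"2,10-dimethyloctacosane",2889,G,0
42.70,408,C29H60,Nonacosane,2900,H,0
42.90,422,C30H62,*-dimethyloctacosane,2918,,0
43.29,422,C30H62,9-methylnonacosane,2938,,0
43.36,422,C30H62,7-methylnonacosane,2942,,0
43.51,422,C30H62,5-methylnonacosane,2951,,0
43.79,436,C31H64,"7,11-dimethylnonacosane",2968,,0
43.90,422,C30H62,3-methylnonacosane,2976,E,0
43.96,436,C31H64,"5,9-dimethylnonacosane",2980,K,0
44.12,450,C32H66,*-trimethylnonacosane,2991,,0
44.42,436,C31H64,"3,7-dimethylnonacosane",3008,B,0
44.74,450,C32H66,"3,7,11-trimethylnonacosane",3036,Q,0
45.01,464,C33H68,"3,7,11,15-tetramethylnonacosane",3056,,0
45.05,436,C31H64,*-methyltriacontane (likely 4-),3060,R,0
45.30,434,C31H62,*-hentriacontene,3074,,0
45.45,450,C32H66,"4,10-dimethyltriacontane",3088,S,0
45.54,386,C27H46O,Cholesterol-like,3090,A,0
45.70,436,C31H64,Hentriacontane,3100,M,0
46.00,464,C33H68,"*-dimethylhentriacontane (likely 9,13)",3139,C,0
46.56,464,C33H68,"5,9-dimethylhentriacontane",3187,D,0
46.69,492,C35H72,"*-pentamethyltriacontane (possibly 7,11,15,19,23)",3199,J,0
46.93,478,C34H70,"*-trimethylhentriacontane (likely 3,7,11-)",3223,O,0
47.15,492,C35H72,"5,9,11,15-tetramethylhentriacontane",3245,N,0
47.59,492,C35H72,*-trimethyldotriacontane or *-tetramethylhentriacontane,3289,P,0
48.78,506,C36H74,"*-Trimethyltritriacontane (possibly 9,13,17)",3412,L,0
49.67,520,C37H76,*-trimethyltetratriacontane,3500,,0
50.28,534,C38H78,*-tetramethyltetratriacontane,3554,,0
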