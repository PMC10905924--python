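age,qx,qx_male,qx_female
0,0.00027929793281866733,0.00035703057110458847,0.00021759560712031334
1,0.00028104794597139104,0.00035926755060633475,0.00021895905079416522
2,0.00028299170055756662,0.00036175218160616751,0.00022047343996989266
3,0.00028515064497014464,0.00036451188038155724,0.00022215548540660546
4,0.00028754860197133247,0.00036757709816226392,0.00022402374780317036
5,0.00029021203151347041,0.0003709816570567348,0.00022609884257751567
6,0.00029317032264797316,0.0003747631231525439,0.00022840366731236017
7,0.00029645611773820857,0.00037896322089991941,0.00023096365437191846
8,0.00030010567254923348,0.00038362829334626092,0.00023380705147757475
9,0.00030415925618343387,0.00038880981329036945,0.00023696523333305297
10,0.00030866159526921066,0.00039456495098677546,0.00024047304773511247
11,0.00031366236729435393,0.00040095720465027629,0.00024436919998349627
12,0.00031921674851964621,0.00040805710070246359,0.00024869667982718724
13,0.00032538602250564708,0.00041594297146785308,0.00025350323564865551
14,0.00033223825595229961,0.00042470181887388492,0.00025884190111080674
15,0.00033984904928996418,0.00043443027365719367,0.00026477158006710244
16,0.00034830237028249389,0.00044523566062038,0.00027135769617370187
17,0.0003576914798096853,0.00045723718164891736,0.00027867291435468289
18,0.00036811996001218095,0.00047056722948168872,0.00028679794206132314
19,0.00037970285609756349,0.00048537284666361202,0.000295822419139391
20,0.00039256794435471587,0.00050181734568721659,0.00030584590609061824
21,0.00040685714030097575,0.00052008210809428856,0.00031697898159455118
22,0.00042272806241816507,0.00054036858225370299,0.00032934446135024498
23,0.00044035576863032944,0.00056290050169238715,0.00034307875162586932
24,0.00045993468455951536,0.00058792634825510781,0.00035833335237600572
25,0.00048168074468180055,0.00061572208701554665,0.00037527652641955456
26,0.00050583376981827577,0.00064659420280666069,0.00039409515297927911
27,0.00053266010695907084,0.00068088307148916893,0.00041499678589418387
28,0.00056245556025991128,0.00071896670268190022,0.00043821193903881284
29,0.00059554864519018036,0.00076126489466543656,0.00046399662394946972
30,0.00063230420129944953,0.00080824384657840476,0.0004926351673900653
31,0.00067312740291758377,0.00086042127790653122,0.00052444333961532141
32,0.00071846821136900552,0.00091837211064782487,0.00055977182743971454
33,0.00076882631699493054,0.00098273477549182253,0.00059901008993012983
34,0.00082475662448611153,0.0010542182099160247,0.00064259063864324784
35,0.00088687534078579766,0.0011336096233452997,0.00069099378886638974
36,0.00095586673117120657,0.0012217831124999856,0.00074475293333986503
37,0.0010324906161323089,0.0013197092188432791,0.00080446039547943382
38,0.0011175906893896581,0.0014284655296959992,0.00087077392523937647
39,0.0012121037458935335,0.001549248435198991,0.00094442390751026117
40,0.0013170699180097278,0.0016833861649354631,0.0010262213603897674
41,0.0014336440283675422,0.0018323532407702459,0.0011170668088676949
42,0.001563108179133188,0.001997786496387377,0.0012179601284918462
43,0.0017068857098263557,0.0021815028292078154,0.0013300114635053095
44,0.0018665566693151225,0.0023855188668978622,0.0014544533348350708
45,0.0020438749623863384,0.0026120727486342865,0.0015926540652593246
46,0.0022407873473576645,0.0028636482407126129,0.0017461326621474038
47,0.0024594544786660233,0.0031430014270217299,0.0019165753124497087
48,0.0027022742072845274,0.0034531902373940992,0.0021058536601850086
49,0.0029719073722414002,0.0037976071008487544,0.0023160450536001687
50,0.0032713063384774976,0.0041800150362456545,0.0025494549675467715
51,0.0036037465597723584,0.0046045875197473496,0.0028086418264653412
52,0.0039728614704790388,0.0050759524965707792,0.0030964444747477726
53,0.0043826810362339597,0.0055992409335374749,0.003416012564168347
54,0.0048376743215114981,0.0061801403385103315,0.0037708401525188284
55,0.0053427964606401757,0.0068249537024038798,0.004164802833486525
56,0.0059035404483437359,0.0075406643483453273,0.0046021987450621804
57,0.006525994195534679,0.0083350071997818631,0.0050877938321528537
58,0.0072169033253158821,0.0092165470036125186,0.0056268717683033431
59,0.0079837402120580547,0.010194764064137884,0.0062252889710844306
60,0.0088347797918632009,0.01128014805668176,0.0068895351751891987
61,0.0097791826941969751,0.012484300493497913,0.0076268000558088467
62,0.010827086260057017,0.013820046405698783,0.0084450464213927656
63,0.011989704019290448,0.015301555779273168,0.0093530905180733148
64,0.013279434195502704,0.016944475235627698,0.010360690006100071
65,0.014709977787541573,0.018766070371121435,0.011478640179356181
66,0.016296466736997806,0.020785379057962738,0.01271887899957258
67,0.018055602625591693,0.023023375851080941,0.014094601503691684
68,0.020005806247426872,0.025503147430681716,0.015620384111500352
69,0.022167378259981052,0.028250078724311734,0.017312319305696544
70,0.024562670923573005,0.03129204897891269,0.019188161071198473
71,0.027216270678906307,0.034659636573055264,0.021267481356499807
72,0.030155190970579393,0.038386330749475617,0.023571837647168969
73,0.033409074282756412,0.042508747681772374,0.026124951508060157
74,0.037010401789836167,0.047066847336447504,0.028952897641894459
75,0.040994708314761596,0.05210414641845551,0.032084302610296711
76,0.045400799401661973,0.057667921257674504,0.035550551848714695
77,0.050270966215114177,0.063809392765200923,0.039386002955087762
78,0.055651192639169511,0.070583883520806467,0.043628202416181816
79,0.061591347326166668,0.07805093460607393,0.048318101923876755
80,0.068145351497156947,0.086274366936108127,0.053500269191424921
81,0.07537131098159966,0.09532226854068393,0.059223086668540037
82,0.083331598266227269,0.10526688549507812,0.065538929733570894
83,0.092092867171923332,0.11618439002119207,0.072504313769671813
84,0.1017259791780406,0.12815449473214113,0.080179996970507261
85,0.11230581637458181,0.14125987719918609,0.088631022736238574
86,0.1239109515894159,0.15558537418254192,0.097926682090821893
87,0.13662314150855304,0.17121690030225689,0.10814037267546417
88,0.15052660375532212,0.1882400420921877,0.11934932658026243
89,0.16570703419288924,0.20673827592257277,0.1316341746426547
90,0.18225031657090052,0.22679075806209992,0.14507831000924909
91,0.20024087362798737,0.24846963830774216,0.15976700895905993
92,0.21975960767447977,0.27183685655902312,0.17578626257376595
93,0.24088138055046393,0.29694039616770085,0.1932212693223988
94,0.26367198900210087,0.32380999083163708,0.21215453670678475
95,0.28818460356000397,0.35245231536538624,0.23266354072800521
96,0.31445565883326099,0.38284573698516122,0.25481789629237139
97,0.3425002128542084,0.41493476455571054,0.27867600128165348
98,0.37230683487601002,0.44862440947715476,0.30428113366182974
99,0.40383213676645646,0.48377476290984334,0.3316570067353044
100,1,1,1
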