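# character -> canonical Kangxi radical number (1-214)
一	1
三	1
上	1
不	1
丙	1
丨	2
中	2
丶	3
丿	4
乏	4
乙	5
亅	6
予	6
二	7
于	7
亠	8
人	9
亻	9
休	9
伴	9
位	9
体	9
余	9
使	9
便	9
促	9
停	9
健	9
儿	10
入	11
全	11
八	12
关	12
具	12
冂	13
再	13
冖	14
冠	14
冫	15
况	15
冷	15
减	15
几	16
凵	17
出	17
刀	18
刂	18
分	18
到	18
力	19
勹	20
匕	21
化	21
匚	22
匸	23
匹	23
医	23
十	24
卜	25
卩	26
即	26
厂	27
压	27
厶	28
又	29
及	29
反	29
发	29
口	30
司	30
合	30
后	30
吐	30
吸	30
呕	30
呼	30
咳	30
咽	30
哮	30
唑	30
喘	30
嗽	30
嘱	30
囊	30
囗	31
四	31
困	31
土	32
地	32
型	32
基	32
塞	32
士	33
夂	34
处	34
夊	35
复	35
夕	36
多	36
大	37
天	37
失	37
头	37
奇	37
女	38
好	38
子	39
孢	39
宀	40
安	40
定	40
家	40
寒	40
察	40
寸	41
对	41
射	41
小	42
尢	43
就	43
尸	44
尼	44
尿	44
局	44
属	44
屮	45
山	46
岛	46
巛	47
工	48
左	48
差	48
己	49
巾	50
布	50
常	50
干	51
并	51
幺	52
广	53
应	53
廴	54
廾	55
异	37
弋	56
弓	57
彐	58
彡	59
彳	60
往	60
心	61
忄	61
急	61
性	61
息	61
恶	61
患	61
悸	61
情	61
感	61
慢	61
戈	62
战	62
户	63
手	64
扌	64
抗	64
折	64
拉	64
振	64
支	65
攴	66
文	67
斑	67
斗	68
斤	69
方	70
无	71
既	71
日	72
时	72
明	72
星	72
显	72
晕	72
曰	73
月	74
有	74
服	74
期	74
木	75
未	75
术	75
松	75
林	75
染	75
查	75
梗	75
椎	75
欠	76
次	76
欲	76
止	77
正	77
歹	78
死	78
殳	79
毋	80
每	80
比	81
毛	82
氏	83
气	84
氟	84
氧	84
氨	84
氯	84
水	85
氵	85
汗	85
沙	85
治	85
注	85
泻	85
泼	85
洛	85
消	85
液	85
溃	85
滴	85
潮	85
火	86
灬	86
炎	86
烦	86
热	86
燥	86
爪	87
父	88
爻	89
爿	90
片	91
牙	92
牛	93
物	93
犬	94
犭	94
状	94
玄	95
玉	96
王	96
环	96
现	96
理	96
瓜	97
瓦	98
甘	99
生	100
用	101
田	102
甲	102
疋	103
疒	104
疗	104
疡	104
疹	104
病	104
症	104
痒	104
痛	104
瘙	104
癶	105
白	106
皮	107
皿	108
盘	108
目	109
眠	109
睡	109
矛	110
矢	111
石	112
硝	112
示	113
礻	113
禾	115
秘	115
程	115
穴	116
突	116
立	117
竹	118
第	118
管	118
米	119
粒	119
糖	119
糸	120
素	120
纟	120
红	120
约	120
经	120
给	120
维	120
缓	120
缶	121
网	122
羊	123
羽	124
老	125
耂	125
者	125
而	126
耒	127
耳	128
联	128
聿	129
肉	130
肝	130
肢	130
肤	130
肺	130
肿	130
胃	130
胆	130
胰	130
胸	130
脉	130
脑	130
腰	130
腹	130
臣	131
自	132
至	133
致	133
臼	134
舌	135
舛	136
舟	137
艮	138
色	139
艸	140
艹	140
节	140
芬	140
苍	140
药	140
莫	140
萄	140
葡	140
虍	141
虫	142
血	143
行	144
衣	145
衤	145
西	146
见	147
观	147
规	147
角	148
解	148
言	149
讠	149
访	149
诉	149
诊	149
该	149
详	149
谷	150
豆	151
豕	152
豸	153
贝	154
赤	155
走	156
足	157
躁	157
身	158
车	159
转	159
较	159
输	159
辛	160
辰	161
辵	162
辶	162
过	162
述	162
适	162
速	162
道	162
邑	163
部	163
酉	164
酚	164
酰	164
釆	165
里	166
量	166
金	167
钅	167
钙	167
钟	167
钠	167
钾	167
镁	167
长	168
门	169
间	169
闷	169
阜	170
阝	170
阿	170
随	170
隶	171
隹	172
难	172
雨	173
霉	173
青	174
静	174
非	175
面	176
革	177
韦	178
韭	179
音	180
页	181
风	182
飞	183
食	184
饣	184
饮	184
首	185
香	186
马	187
骨	188
高	189
鬼	194
鱼	195
鸟	196
鹿	198
麦	199
麻	200
黄	201
黍	202
黑	203
鼎	206
鼓	207
鼠	208
鼻	209
齐	210
齿	211
龙	212
龟	213
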