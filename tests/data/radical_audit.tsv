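# audit list: character -> Kangxi radical number per Unihan kRSUnicode
一	1
不	1
中	2
乏	4
予	6
于	7
人	9
伴	9
使	9
停	9
减	15
出	17
刀	18
分	18
力	19
化	21
匹	23
医	23
即	26
压	27
发	29
口	30
吐	30
呕	30
咳	30
哮	30
唑	30
喘	30
嗽	30
嘱	30
困	31
土	32
处	34
多	36
大	37
天	37
失	37
头	37
女	38
好	38
子	39
孢	39
安	40
定	40
寒	40
寸	41
对	41
射	41
小	42
尼	44
尿	44
局	44
山	46
岛	46
工	48
左	48
巾	50
布	50
干	51
广	53
应	53
弓	57
往	60
心	61
性	61
恶	61
患	61
感	61
慢	61
戈	62
战	62
手	64
抗	64
折	64
拉	64
无	71
日	72
时	72
明	72
星	72
晕	72
月	74
服	74
期	74
木	75
松	75
林	75
椎	75
欠	76
次	76
欲	76
止	77
死	78
每	80
气	84
氧	84
氨	84
氯	84
水	85
汗	85
沙	85
治	85
注	85
泻	85
洛	85
消	85
液	85
滴	85
火	86
炎	86
热	86
牛	93
物	93
犬	94
状	94
玉	96
环	96
现	96
生	100
用	101
田	102
甲	102
疗	104
疹	104
病	104
症	104
痒	104
痛	104
瘙	104
白	106
皮	107
盘	108
目	109
眠	109
睡	109
石	112
硝	112
禾	115
程	115
穴	116
突	116
立	117
竹	118
管	118
米	119
粒	119
糖	119
素	120
红	120
经	120
给	120
维	120
缓	120
者	125
耳	128
联	128
肉	130
肝	130
肢	130
肤	130
肺	130
肿	130
胃	130
胸	130
脉	130
腹	130
自	132
舌	135
色	139
芬	140
药	140
莫	140
萄	140
葡	140
血	143
行	144
西	146
见	147
观	147
角	148
解	148
访	149
诉	149
谷	150
豆	151
贝	154
走	156
足	157
身	158
车	159
转	159
输	159
过	162
述	162
适	162
部	163
酉	164
酚	164
里	166
金	167
钙	167
钟	167
钠	167
钾	167
镁	167
长	168
门	169
间	169
闷	169
阿	170
随	170
难	172
雨	173
霉	173
青	174
静	174
非	175
面	176
革	177
音	180
页	181
食	184
饮	184
香	186
马	187
骨	188
高	189
鬼	194
鱼	195
鸟	196
麻	200
鼻	209
齿	211
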