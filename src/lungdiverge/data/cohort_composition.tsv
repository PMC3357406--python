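group	variable	level	count	printed_percent
AC	stage	I	76	44.9
AC	stage	II	40	23.6
AC	stage	III	22	13.0
AC	stage	IV	27	16.0
AC	stage	n/a	4	2.4
AC	sex	Female	106	62.7
AC	sex	Male	63	37.3
AC	smoking	Current smoker	48	28.4
AC	smoking	Ex-smoker	80	47.3
AC	smoking	n/a	3	1.8
AC	smoking	Non-smoker	38	22.5
SqCC	stage	I	32	34.7
SqCC	stage	II	32	34.7
SqCC	stage	III	14	15.2
SqCC	stage	IV	10	10.9
SqCC	stage	n/a	4	4.4
SqCC	sex	Female	26	28.3
SqCC	sex	Male	66	71.7
SqCC	smoking	Current smoker	30	32.6
SqCC	smoking	Ex-smoker	61	66.3
SqCC	smoking	Non-smoker	1	1.1
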