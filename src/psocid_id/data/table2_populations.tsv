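species	population_code	location	country
L. entomophila	BJ-China	Beijing, China	China
L. entomophila	HuB-China	Hubei province, China	China
L. entomophila	GX-China	Guangxi province, China	China
L. entomophila	SD-China	Shandong province, China	China
L. bostrychophila	BJ-China	Beijing, P. R. China	China
L. bostrychophila	GX-China	Guangxi province. China	China
L. bostrychophila	GZ-China	Guangdong province, China	China
L. bostrychophila	HeN-China	Henan province, China	China
L. bostrychophila	CQ-China	Chongqing, China	China
L. bostrychophila	P-CZ	Prague, Czech Republic	Czech Republic
L. bostrychophila	CZ	Bohemia, Czech Republic	Czech Republic
L. bostrychophila	USA	Manhattan,USA	USA
L. bostrychophila	GER	Berlin, Germany	Germany
L. decolor	CQ-China	Chongqing, China	China
L. decolor	YN-China	Yunnan province, China	China
L. decolor	P-CZ	Prague, Czech Republic	Czech Republic
L. decolor	USA	USA	USA
L. paeta	USA	USA	USA
L. paeta	HeB-China	Hebei province, China	China
L. paeta	SDT-China	Shandong province, China	China
L. paeta	SDC-China	Shandong province, China	China
L. paeta	ZJ-China	Zhejiang province, China	China
L. paeta	HuB-China	Hubei province, China	China
L. paeta	HeN-China	Henan province, China	China
L. paeta	CZ	Prague, Czech Republic	Czech Republic
L. corrodens	CZ	Prague, Czech Republic	Czech Republic
L. corrodens	DMK	Danmark	Denmark
L. corrodens	USA	USA	USA
L. corrodens	USA	USA	USA
L. brunnea	P-CZ	Prague, Czech Republic	Czech Republic
L. brunnea	USA	USA	USA
L. mendax	JS-China	Jiangsu province, China	China
L. pearmani	USA	USA	USA
L. tricolor	SD-China	Shandong provience, China	China
L. rufa	USA	USA	USA
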