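Position	Gene	Ref	Allele	Depth
1810	COI	[G]8	Ref/+1G/-1G/+2GG/T/G/C/+1T/*/-2GG	352526/6177/3116/150/32/25/19/19/10/6
2573	COI	[A]9	Ref/+1A/-1A/T/+2AA/A/+3AAA/-2AA	277857/7636/1788/223/170/13/9/8
3441	tRNA-Asp	[A]8	Ref/+1A/+2AA/-1A/+1C/+3AAA/+1G/G/C/A	438644/195894/3402/1011/69/58/17/10/7/5
3619	ATP8/6	[A]10	Ref/+1A/-1A/+2AA/-2AA/T/+3AAA/A/C	400525/23182/9717/997/185/137/49/14/11
4592	COIII	[T]11	Ref/+1T/-1T/+2TT/-2TT/+3TTT/T/+1A	107531/10859/6363/1027/140/110/20/10
5524	tRNA-Ala	[A]10	Ref/+1A/-1A/+2AA/-2AA/A/+3AAA	97659/3329/2622/131/27/19/9
6361	ND1	[A]10	Ref/+1A/-1A/+2AA/-2AA/+3AAA/C	94957/4984/3410/313/18/17/8
7324	16S rRNA	[TA]9	Ref/-2TA/+2TA	93454/4152/3088
7737	16S rRNA	[A]9	Ref/+1A/-1A/+2AA/C/A	89380/1277/890/32/6/5
8042	16S rRNA	[T]9	Ref/+1T/-1T/+2TT/-2TT/G	96225/1795/1552/40/8/5
8243	12S/tRNA-Val	[T]10	Ref/+1T/-1T/+2TT/-2TT/+3TTT/G	99234/3993/2326/151/31/8/7
8885	12S rRNA	[T]10	Ref/+1T/-1T/+2TT/-2TT/T/+3TTT	86875/4767/3630/287/38/36/18
10026	ND5	[A]10	Ref/-1A/+1A/+2AA/-2AA/+3AAA/C	99166/5465/3630/134/82/6/5
10298	ND5	[A]13	Ref/-1A/+1A/-2AA/+2AA/-3AAA/+3AAA/C	91464/17434/7221/2402/721/241/61/5
11216	ND5	[A]17	Ref/-1A/+1A/-2AA/+2AA/-3AAA/+3AAA/A/*/+2TA/+1C	138074/26622/18595/4443/2859/542/413/96/24/5/5
11483	ND4/4L	[TA]6	Ref/-2TA/+2TA/A/T	200829/3596/2031/19/7
11962	ND4/4L	[A]11	Ref/-1A/+1A/-2AA/+2AA/C/+3AAA/A/-3AAA	203481/18678/10550/646/496/28/20/11/10
12082	ND4/4L	[A]8	Ref/-1A/+1A/T/+2AA/A	215342/1501/821/48/12/7
12505	ND4/4L	[A]9	Ref/-1A/+1A/+2AA/C/-2AA	227869/3067/2631/47/20/9
12697	ND4/4L	[A]8	Ref/+1A/-1A/+2AA/C/A/G	230254/1922/497/23/22/6/6
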