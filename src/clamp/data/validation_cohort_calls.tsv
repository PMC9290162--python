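sample	method	label	vaf_percent
1	sanger	T315I
1	lrsms	T315I	96.8
1	lrsms	F359C	2.1
1	lrsms	H396R	1.2
2	sanger	F359I
2	sanger	T315I
2	lrsms	F359I	84.9
2	lrsms	T315I	14.4
3	sanger	.
3	lrsms	M244V	0.6
4	sanger	Y253H
4	lrsms	Y253H	98.1
4	lrsms	E255	1.7
5	sanger	.
5	lrsms	M244V	0.9
6	sanger	.
6	lrsms	.
7	sanger	Y253H
7	lrsms	Y253H	99.8
8	sanger	.
8	lrsms	.
9	sanger	.
9	lrsms	.
10	sanger	T315I
10	lrsms	T315I	99.9
11	sanger	.
11	lrsms	.
12	sanger	T315I
12	lrsms	T315I	50.0
12	lrsms	E255V	1.9
13	sanger	.
13	lrsms	.
14	sanger	T315I
14	sanger	E255K
14	sanger	F359V
14	lrsms	T315I	45.7
14	lrsms	F359I	23.9
14	lrsms	E255K	12.5
14	lrsms	H396R	12.4
14	lrsms	F359V	4.8
15	sanger	L273M
15	sanger	T315I
15	lrsms	L273M	58.1
15	lrsms	T315I	41.7
15	lrsms	K247R	2.8
16	sanger	T315I
16	lrsms	T315I	99.8
17	sanger	.
17	lrsms	.
18	sanger	.
18	lrsms	E450G	0.5
19	sanger	.
19	lrsms	.
20	sanger	.
20	lrsms	.
21	sanger	.
21	lrsms	.
22	sanger	.
22	lrsms	.
23	sanger	.
23	lrsms	.
24	sanger	F359I
24	lrsms	F359I	91.3
24	lrsms	T315I	8.3
25	sanger	.
25	lrsms	.
26	sanger	.
26	lrsms	T315I	0.6
26	lrsms	E450G	0.5
27	sanger	.
27	lrsms	.
28	sanger	.
28	lrsms	M472I	0.8
29	sanger	F359V
29	lrsms	F359V	99.9
29	lrsms	D276G	0.7
30	sanger	.
30	lrsms	.
31	sanger	.
31	lrsms	.
32	sanger	.
32	lrsms	.
33	sanger	L298V
33	sanger	E255K
33	lrsms	L298V	33.6
33	lrsms	E255K	29.6
34	sanger	.
34	lrsms	.
35	sanger	.
35	lrsms	E450G	0.8
36	sanger	.
36	lrsms	.
37	sanger	.
37	lrsms	.
38	sanger	.
38	lrsms	.
39	sanger	.
39	lrsms	.
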