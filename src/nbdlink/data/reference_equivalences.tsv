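query_pos	query_aa	template_id	template_pos	template_aa
433	A	2HYD	425	I
435	M	2HYD	427	F
516	S	2HYD	507	A
486	K	2HYD	477	K
383	P	2HYD	375	M
520	E	2HYD	511	E
433	A	3B5X	427	H
435	M	3B5X	429	F
516	S	3B5X	510	A
486	K	3B5X	480	S
383	P	3B5X	377	R
520	E	3B5X	514	E
361	S	3B5X	354	K
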