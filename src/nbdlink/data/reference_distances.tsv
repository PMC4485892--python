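pair_label	pos_a	pos_b	conformation	template_pair	distance	route
A433/A433	433	433	2HYD-sandwich	I425/I425	14.1	direct-homolog
M435/M435	435	435	2HYD-sandwich	F427/F427	20.1	direct-homolog
S516/S516	516	516	2HYD-sandwich	A507/A507	9.3	direct-homolog
S361/K486	361	486	2HYD-sandwich	-/K477	12.1	grafted-monomer
S361/S361	361	361	2HYD-sandwich	-/-	50.8	grafted-monomer
K486/K486	486	486	2HYD-sandwich	K477/K477	26.7	direct-homolog
P383/E520	383	520	2HYD-sandwich	M375/E511	7.0	direct-homolog
P383/P383	383	383	2HYD-sandwich	M375/M375	27.6	direct-homolog
E520/E520	520	520	2HYD-sandwich	E511/E511	23.3	direct-homolog
A433/A433	433	433	3B5X-inward-closed	H427/H427	38.4	direct-homolog
M435/M435	435	435	3B5X-inward-closed	F429/F429	45.8	direct-homolog
S516/S516	516	516	3B5X-inward-closed	A510/A510	40.3	direct-homolog
S361/K486	361	486	3B5X-inward-closed	K354/S480	22.45	direct-homolog
S361/S361	361	361	3B5X-inward-closed	K354/K354	28.3	direct-homolog
K486/K486	486	486	3B5X-inward-closed	S480/S480	60.6	direct-homolog
P383/E520	383	520	3B5X-inward-closed	R377/E514	38.4	direct-homolog
P383/P383	383	383	3B5X-inward-closed	R377/R377	12.4	direct-homolog
E520/E520	520	520	3B5X-inward-closed	E514/E514	64.5	direct-homolog
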