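mutant_label	pos_a	pos_b	temperature_C	outcome
A433C	433	433	4	none
M435C	435	435	4	none
S516C	516	516	4	clear
S361C	361	361	4	none
K486C	486	486	4	none
P383C	383	383	4	none
E520C	520	520	4	clear
S361C/K486C	361	486	4	clear
P383C/E520C	383	520	4	clear
A433C	433	433	21	weak
M435C	435	435	21	weak
S516C	516	516	21	clear
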