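species	total_bp	total_gc	lsc_bp	lsc_gc	ssc_bp	ssc_gc	ir_bp	ir_gc	coding_bp	coding_gc	noncoding_bp	noncoding_gc
Camptotheca_acuminata	157877	37.90	87361	36.10	18760	31.90	25878	43.00	91358	40.30	66519	34.50
Nyssa_sinensis	156672	37.90	86184	36.00	18260	32.20	26114	43.00	91279	40.30	65393	34.50
Davidia_involucrata	158409	37.80	87611	36.10	18856	31.60	25971	43.00	90949	40.30	67460	34.50
Diplopanax_stachyanthus	157522	37.80	87640	36.00	18182	31.70	25850	43.00	89793	40.30	67729	34.50
Hydrangea_serrata	157730	37.90	86789	36.10	18711	31.70	26115	43.10	91292	40.20	66438	34.70
Swida_controversa	158674	37.80	87850	36.00	18696	31.90	26064	43.00	91006	40.30	67668	34.40
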