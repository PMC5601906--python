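partition	snp_count	character_count	divergence_pct
complete	4886	162516	3.01
coding	1994	91113	2.19
noncoding	2892	71403	4.05
LSC	3380	91213	3.71
SSC	1069	21039	5.08
IR	437	50264	0.87
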