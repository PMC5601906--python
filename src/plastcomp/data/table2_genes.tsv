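name	category	functional_group	ir_duplicated	introns	pseudogene_in
rrn4.5	rRNA	Ribosomal RNA genes	1	0
rrn5	rRNA	Ribosomal RNA genes	1	0
rrn16	rRNA	Ribosomal RNA genes	1	0
rrn23	rRNA	Ribosomal RNA genes	1	0
trnA_UGC	tRNA	Transfer RNA genes	1	1
trnC_GCA	tRNA	Transfer RNA genes	0	0
trnD_GUC	tRNA	Transfer RNA genes	0	0
trnE_UUC	tRNA	Transfer RNA genes	0	0
trnF_GAA	tRNA	Transfer RNA genes	0	0
trnfM_CAU	tRNA	Transfer RNA genes	0	0
trnG_GCC	tRNA	Transfer RNA genes	0	0
trnG_UCC	tRNA	Transfer RNA genes	0	1
trnH_GUG	tRNA	Transfer RNA genes	0	0
trnI_CAU	tRNA	Transfer RNA genes	1	0
trnI_GAU	tRNA	Transfer RNA genes	1	1
trnK_UUU	tRNA	Transfer RNA genes	0	1
trnL_CAA	tRNA	Transfer RNA genes	1	0
trnL_UAA	tRNA	Transfer RNA genes	0	1
trnL_UAG	tRNA	Transfer RNA genes	0	0
trnM_CAU	tRNA	Transfer RNA genes	0	0
trnN_GUU	tRNA	Transfer RNA genes	1	0
trnP_UGG	tRNA	Transfer RNA genes	0	0
trnQ_UUG	tRNA	Transfer RNA genes	0	0
trnR_ACG	tRNA	Transfer RNA genes	1	0
trnR_UCU	tRNA	Transfer RNA genes	0	0
trnS_GCU	tRNA	Transfer RNA genes	0	0
trnS_GGA	tRNA	Transfer RNA genes	0	0
trnS_UGA	tRNA	Transfer RNA genes	0	0
trnT_GGU	tRNA	Transfer RNA genes	0	0
trnT_UGU	tRNA	Transfer RNA genes	0	0
trnV_GAC	tRNA	Transfer RNA genes	1	0
trnV_UAC	tRNA	Transfer RNA genes	0	1
trnW_CCA	tRNA	Transfer RNA genes	0	0
trnY_GUA	tRNA	Transfer RNA genes	0	0
rps2	protein_coding	Small subunit of ribosome	0	0
rps3	protein_coding	Small subunit of ribosome	0	0
rps4	protein_coding	Small subunit of ribosome	0	0
rps7	protein_coding	Small subunit of ribosome	1	0
rps8	protein_coding	Small subunit of ribosome	0	0
rps11	protein_coding	Small subunit of ribosome	0	0
rps12	protein_coding	Small subunit of ribosome	0	0
rps12*	protein_coding	Small subunit of ribosome	1	1
rps14	protein_coding	Small subunit of ribosome	0	0
rps15	protein_coding	Small subunit of ribosome	0	0
rps16	protein_coding	Small subunit of ribosome	0	1
rps18	protein_coding	Small subunit of ribosome	0	0
rps19	protein_coding	Small subunit of ribosome	0	0
rpl2	protein_coding	Large subunit of ribosome	1	1
rpl14	protein_coding	Large subunit of ribosome	0	0
rpl16	protein_coding	Large subunit of ribosome	0	1
rpl20	protein_coding	Large subunit of ribosome	0	0
rpl22	protein_coding	Large subunit of ribosome	0	0
rpl23	protein_coding	Large subunit of ribosome	1	0
rpl32	protein_coding	Large subunit of ribosome	0	0
rpl33	protein_coding	Large subunit of ribosome	0	0
rpl36	protein_coding	Large subunit of ribosome	0	0
rpoA	protein_coding	DNA-dependent RNA polymerase	0	0
rpoB	protein_coding	DNA-dependent RNA polymerase	0	0
rpoC1	protein_coding	DNA-dependent RNA polymerase	0	1
rpoC2	protein_coding	DNA-dependent RNA polymerase	0	0
infA	protein_coding	Translational initiation factor	0	0
psaA	protein_coding	Subunits of photosystem I	0	0
psaB	protein_coding	Subunits of photosystem I	0	0
psaC	protein_coding	Subunits of photosystem I	0	0
psaI	protein_coding	Subunits of photosystem I	0	0
psaJ	protein_coding	Subunits of photosystem I	0	0
ycf3	protein_coding	Subunits of photosystem I	0	2
ycf4	protein_coding	Subunits of photosystem I	0	0
psbA	protein_coding	Subunits of photosystem II	0	0
psbB	protein_coding	Subunits of photosystem II	0	0
psbC	protein_coding	Subunits of photosystem II	0	0
psbD	protein_coding	Subunits of photosystem II	0	0
psbE	protein_coding	Subunits of photosystem II	0	0
psbF	protein_coding	Subunits of photosystem II	0	0
psbH	protein_coding	Subunits of photosystem II	0	0
psbI	protein_coding	Subunits of photosystem II	0	0
psbJ	protein_coding	Subunits of photosystem II	0	0
psbK	protein_coding	Subunits of photosystem II	0	0
psbL	protein_coding	Subunits of photosystem II	0	0
psbM	protein_coding	Subunits of photosystem II	0	0
psbN	protein_coding	Subunits of photosystem II	0	0
psbT	protein_coding	Subunits of photosystem II	0	0
psbZ	protein_coding	Subunits of photosystem II	0	0
petA	protein_coding	Subunits of cytochrome	0	0
petB	protein_coding	Subunits of cytochrome	0	1
petD	protein_coding	Subunits of cytochrome	0	1
petG	protein_coding	Subunits of cytochrome	0	0
petL	protein_coding	Subunits of cytochrome	0	0
petN	protein_coding	Subunits of cytochrome	0	0
atpA	protein_coding	Subunits of ATP synthase	0	0
atpB	protein_coding	Subunits of ATP synthase	0	0
atpE	protein_coding	Subunits of ATP synthase	0	0
atpF	protein_coding	Subunits of ATP synthase	0	1
atpH	protein_coding	Subunits of ATP synthase	0	0
atpI	protein_coding	Subunits of ATP synthase	0	0
rbcL	protein_coding	Large subunit of Rubisco	0	0
ndhA	protein_coding	Subunits of NADH dehydrogenase	0	1
ndhB	protein_coding	Subunits of NADH dehydrogenase	1	1
ndhC	protein_coding	Subunits of NADH dehydrogenase	0	0
ndhD	protein_coding	Subunits of NADH dehydrogenase	0	0
ndhE	protein_coding	Subunits of NADH dehydrogenase	0	0
ndhF	protein_coding	Subunits of NADH dehydrogenase	0	0
ndhG	protein_coding	Subunits of NADH dehydrogenase	0	0
ndhH	protein_coding	Subunits of NADH dehydrogenase	0	0
ndhI	protein_coding	Subunits of NADH dehydrogenase	0	0
ndhJ	protein_coding	Subunits of NADH dehydrogenase	0	0
ndhK	protein_coding	Subunits of NADH dehydrogenase	0	0
matK	protein_coding	Maturase	0	0
cemA	protein_coding	Envelope membrane protein	0	0
accD	protein_coding	Subunit of acetyl-CoA	0	0
ccsA	protein_coding	C-type cytochrome synthesis gene	0	0
clpP	protein_coding	Protease	0	2
ycf1	protein_coding	Component of TIC complex	0	0
ycf2	protein_coding	Conserved open reading frames	1	0
ycf15	protein_coding	Conserved open reading frames	1	0	Davidia_involucrata
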