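snp_id	rsid	position	allele1	allele2	gene	gene_location	in_validation_panel	poor_clustering
rs587560	rs587560	55245738	A	G	KIR3DL3	intronic	yes	no
rs17207383	rs17207383	55248107	A	C	-	intergenic	no	no
seq-rs10409751	rs10409751	55249570	C	G	-	intergenic	no	no
seq-rs643236	rs643236	55251418	A	G	KIR2DL3	intronic	no	no
seq-t1d-19-59977961-T-C	-	55286149	A	G	KIR2DL1	intronic	no	yes
imm_19_59986266	-	55294454	A	G	KIR2DL1	coding	no	yes
seq-rs670795	rs670795	55306645	A	C	-	intergenic	yes	no
seq-rs35656676	rs35656676	55314897	C	G	-	intergenic	yes	no
seq-rs17173106	rs17173106	55314949	A	G	-	intergenic	yes	no
seq-rs592645	rs592645	55320927	A	T	KIR2DL4	intronic	yes	no
seq-rs3865510	rs3865510	55324239	A	C	KIR2DL4	intronic	yes	no
rs581623	rs581623	55326739	A	G	-	intergenic	yes	no
seq-t1d-19-60034052-C-T	-	55342240	A	G	-	intergenic	no	no
rs4806585	rs4806585	55346424	A	C	KIR2DS4	intronic	no	no
seq-rs62122181	rs62122181	55347366	A	G	KIR2DS4	intronic	no	yes
seq-t1d-19-60056605-A-T	-	55364793	A	T	KIR3DL2	intronic	no	yes
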