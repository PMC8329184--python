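variant_id	chrom	pos	ref_allele	alt_allele	effect_allele	eaf	beta	se	p
rs10085935	8	39806267	T	C	T	0.37	-0.010	0.002	3.326E-09
rs16924894	10	24845525	A	T	A	0.02	0.081	0.015	2.329E-08
rs3184504	12	111884608	T	C	T	0.48	0.015	0.002	6.046E-18
rs11066320	12	112906415	A	G	A	0.43	0.012	0.002	3.101E-11
rs750950	16	87873247	A	C	A	0.64	0.014	0.002	2.342E-16
rs8051149	16	87878822	A	G	A	0.21	0.026	0.003	9.073E-26
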