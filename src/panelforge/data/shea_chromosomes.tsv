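# Per-chromosome summary of the shea (Vitellaria paradoxa) 'KA01' reference
# genome and its high-confidence SNP counts, used by the density report.
chrom	length_bp	n_genes	n_snps
Chr01	80731948	4208	413405
Chr02	74439616	4682	392583
Chr03	57704473	3137	314591
Chr04	59651551	3283	308006
Chr05	59580608	3312	321960
Chr06	49210429	3131	285150
Chr07	55380075	3200	266400
Chr08	52298408	3270	273406
Chr09	47443901	2504	254725
Chr10	46597090	2596	245885
Chr11	38413107	2478	212268
Chr12	37276254	2239	190581
Unscaffolded	8558030	465	9997
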