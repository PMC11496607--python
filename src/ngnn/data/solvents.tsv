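name	aliases	smiles	et30	sp	sdp	sa	sb	citation
toluene	methylbenzene	Cc1ccccc1	33.9	0.782	0.284	0.000	0.128	Reichardt ChemRev 1994; Catalan JPCB 2009
THF	tetrahydrofuran	C1CCOC1	37.4	0.714	0.634	0.000	0.591	Reichardt ChemRev 1994; Catalan JPCB 2009
MeOH	methanol	CO	55.4	0.608	0.904	0.605	0.545	Reichardt ChemRev 1994; Catalan JPCB 2009
MeCN	acetonitrile	CC#N	45.6	0.645	0.974	0.044	0.286	Reichardt ChemRev 1994; Catalan JPCB 2009
hexane	n-hexane	CCCCCC	31.0	0.616	0.000	0.000	0.056	Reichardt ChemRev 1994; Catalan JPCB 2009
H2O	water	O	63.1	0.681	0.997	1.062	0.025	Reichardt ChemRev 1994; Catalan JPCB 2009
EtOH	ethanol	CCO	51.9	0.633	0.783	0.400	0.658	Reichardt ChemRev 1994; Catalan JPCB 2009
ethyl acetate	EtOAc	CCOC(C)=O	38.1	0.656	0.603	0.000	0.542	Reichardt ChemRev 1994; Catalan JPCB 2009
DMSO	dimethyl sulfoxide	CS(C)=O	45.1	0.830	1.000	0.072	0.647	Reichardt ChemRev 1994; Catalan JPCB 2009
DMF	N,N-dimethylformamide	CN(C)C=O	43.2	0.759	0.977	0.031	0.613	Reichardt ChemRev 1994; Catalan JPCB 2009
CHCl3	chloroform	ClC(Cl)Cl	39.1	0.783	0.614	0.047	0.071	Reichardt ChemRev 1994; Catalan JPCB 2009
CH2Cl2	dichloromethane	ClCCl	40.7	0.761	0.769	0.040	0.178	Reichardt ChemRev 1994; Catalan JPCB 2009
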