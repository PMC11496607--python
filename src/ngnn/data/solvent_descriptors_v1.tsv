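family	name	reference
estate	MaxEStateIndex	Kier & Hall, electrotopological state (1999)
estate	MinEStateIndex	Kier & Hall, electrotopological state (1999)
estate	EState_VSA1	Kier & Hall, electrotopological state (1999)
estate	EState_VSA2	Kier & Hall, electrotopological state (1999)
estate	EState_VSA3	Kier & Hall, electrotopological state (1999)
estate	EState_VSA4	Kier & Hall, electrotopological state (1999)
estate	EState_VSA5	Kier & Hall, electrotopological state (1999)
estate	EState_VSA6	Kier & Hall, electrotopological state (1999)
estate	EState_VSA7	Kier & Hall, electrotopological state (1999)
estate	EState_VSA8	Kier & Hall, electrotopological state (1999)
estate	EState_VSA9	Kier & Hall, electrotopological state (1999)
estate	EState_VSA10	Kier & Hall, electrotopological state (1999)
estate	EState_VSA11	Kier & Hall, electrotopological state (1999)
vsa	SlogP_VSA1	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA2	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA3	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA4	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA5	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA6	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA7	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA8	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA9	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA10	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA11	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SlogP_VSA12	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SMR_VSA1	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SMR_VSA2	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SMR_VSA3	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SMR_VSA4	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SMR_VSA5	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SMR_VSA6	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SMR_VSA7	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SMR_VSA8	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SMR_VSA9	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	SMR_VSA10	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	PEOE_VSA1	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	PEOE_VSA2	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	PEOE_VSA3	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	PEOE_VSA4	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	PEOE_VSA5	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	PEOE_VSA6	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	PEOE_VSA7	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	PEOE_VSA8	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	PEOE_VSA9	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	PEOE_VSA10	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	LabuteASA	Labute, J. Mol. Graph. Model. 18 (2000) 464
vsa	TPSA	Labute, J. Mol. Graph. Model. 18 (2000) 464
topological	BalabanJ	Todeschini & Consonni, Handbook of Molecular Descriptors
topological	BertzCT	Todeschini & Consonni, Handbook of Molecular Descriptors
topological	HallKierAlpha	Todeschini & Consonni, Handbook of Molecular Descriptors
topological	AvgIpc	Todeschini & Consonni, Handbook of Molecular Descriptors
topological	Kappa1	Todeschini & Consonni, Handbook of Molecular Descriptors
topological	Kappa2	Todeschini & Consonni, Handbook of Molecular Descriptors
topological	Kappa3	Todeschini & Consonni, Handbook of Molecular Descriptors
connectivity	Chi0	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi1	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi0n	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi1n	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi2n	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi3n	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi4n	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi0v	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi1v	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi2v	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi3v	Kier & Hall, Molecular Connectivity in Chemistry
connectivity	Chi4v	Kier & Hall, Molecular Connectivity in Chemistry
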