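CO	methanol
CCO	ethanol
CCCCO	1-butanol
CCCCCCO	1-hexanol
CCCCC(CC)CO	2-ethyl-1-hexanol
COCCO	2-methoxyethanol
COCCOCCO	2-(2-methoxyethoxy)ethanol
CC(O)C(=O)OCCC(C)C	isopentyl 2-hydroxypropanoate
OCC(=O)OCC	ethyl glycolate
OCCO	ethylene glycol
OCCCO	1,3-propanediol
OCCCCO	1,4-butanediol
OCCCCCCO	1,6-hexanediol
OCCOCCO	diethylene glycol
OCCOCCOCCO	triethylene glycol
OCCOC(=O)CCCCC(=O)OCCO	bis(2-hydroxyethyl) adipate
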