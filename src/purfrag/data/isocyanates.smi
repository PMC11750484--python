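CN=C=O	MIC
O=C=NCc1ccccc1	BIC
O=C=Nc1ccc(Cc2ccc(N=C=O)cc2)cc1	4,4'-MDI
O=C=Nc1ccccc1Cc1ccc(N=C=O)cc1	2,4'-MDI
O=C=Nc1ccccc1Cc1ccccc1N=C=O	2,2'-MDI
Cc1ccc(N=C=O)cc1N=C=O	2,4-TDI
Cc1c(N=C=O)cccc1N=C=O	2,6-TDI
O=C=NCCCCCCN=C=O	HDI
CC1(C)CC(N=C=O)CC(C)(CN=C=O)C1	IPDI
O=C=NC1CCC(CC2CCC(N=C=O)CC2)CC1	HMDI
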