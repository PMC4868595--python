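# Mini restriction-enzyme library, REBASE-style: NAME  RECOGNITION(top/bottom)
# Offsets are relative to the 3' end of the recognition sequence on the
# recognition-bearing strand; negative offsets cut inside the site.
# Type IIS offset cutters
HphI	GGTGA(8/7)
MnlI	CCTC(7/6)
MboII	GAAGA(8/7)
HgaI	GACGC(5/10)
# within-site cutters
EcoRI	GAATTC(-5/-1)
HindIII	AAGCTT(-5/-1)
TaqI	TCGA(-3/-1)
HinfI	GANTC(-4/-1)
AluI	AGCT(-2/-2)
DdeI	CTNAG(-4/-1)
HaeIII	GGCC(-2/-2)
RsaI	GTAC(-2/-2)
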