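# Curated modification mapping table: Unimod-style accession -> PSI-MOD-style
# accession, with monoisotopic mass delta and residue specificity.
# This is a synthetic curated stand-in covering the common modification types
# of shotgun proteomics submissions, not a dump of either ontology; it is
# user-replaceable (same column layout, tab-separated).
# Columns:
#   unimod_acc  psimod_acc  name  composition  mono_delta  specificity  label_family  label_role
# composition: elemental formula of the delta (isotopes in brackets, signed
#   counts allowed), used only for auditing the mono_delta column.
# specificity: comma-separated residue letters and/or N-term / C-term.
# label_family / label_role: non-empty only for isotopic labelling reagents
#   (role is "light" or "heavy"); "-" means not applicable.
UNIMOD:1	MOD:00394	Acetyl	C2H2O	42.010565	K,N-term	-	-
UNIMOD:4	MOD:01060	Carbamidomethyl	C2H3NO	57.021464	C	-	-
UNIMOD:5	MOD:00398	Carbamyl	HCNO	43.005814	K,N-term	-	-
UNIMOD:7	MOD:00400	Deamidated	H-1N-1O	0.984016	N,Q	-	-
UNIMOD:21	MOD:00696	Phospho	HO3P	79.966331	S,T,Y	-	-
UNIMOD:35	MOD:00719	Oxidation	O	15.994915	M	-	-
UNIMOD:105	MOD:00480	ICAT-C	C10H17N3O3	227.126991	C	ICAT	light
UNIMOD:106	MOD:00481	ICAT-C:13C(9)	C[13]9CH17N3O3	236.157185	C	ICAT	heavy
UNIMOD:214	MOD:01499	iTRAQ4plex	C[13]3C4H12N[15]NO	144.102062	K,N-term	-	-
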