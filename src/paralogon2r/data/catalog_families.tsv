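family	full_name	n_taxa_included	n_sequences_included
AZIN	Antizyme Inhibitor	25	54
CHRN	Cholinergic Receptors Nicotinic subunits	32	123
CRO	Ciliary Rootlet Coiled-Coil Protein	28	42
DLGAP	Discs, large (Drosophila) Homolog-associated Protein	25	85
E2F	E2F Transcription Factor	31	84
FAM110	Family with Sequence Similarity 110	25	56
GRHL	Grainyhead like Transcription factor	26	57
ID	Inhibitor of DNA Binding protein	35	65
MROH	Maestro Heat-like Repeat-containing Protein Family	22	46
MYT	Myelin Transcription Factor	22	48
NCOA	Nuclear Receptor Coactivator	22	54
NKAIN	Na+/K+ Transporting ATPase Interacting Protein	24	46
KCNQ	Potassium Voltage-Gated Channel subfamily Q	28	67
RGS	Regulator of G-protein Signalling	31	101
RIMS	Regulating Synaptic Membrane Exocytosis Protein	27	49
RSPO	R-Spondin Homolog	31	60
SLC	Solute Carrier Family	23	74
SNT	Syntrophin, Gamma	28	81
SNX	Sorting Nexin Family	29	43
STMN	Stathmin	22	63
STK	Serine/Threonine-Protein Kinase	25	72
TCEA	Transcription Elongation factor A (SII) Protein	22	51
UBXN	UBX Domain-Containing Protein	22	32
XKR	X Kell Blood Group Precursor-related Family	24	101
YTHDF	YTH Domain-Containing Family Protein	24	50
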