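# Published C-terminal decamers (N -> C) of confirmed bacterial porins and of
# Thermotogales OmpB orthologs / putative syntenic analogs.  The terminal
# residue is position 1 of the anchoring signature.
# group: known_porin = structurally confirmed porin; ortholog = OmpB ortholog;
# analog = putative non-homologous porin occupying the ompB syntenic slot.
name	organism	group	decamer
TM0476	Thermotoga maritima	ortholog	YLYLKASVAF
PhoE_Se	Salmonella enterica	known_porin	IVAIGLTYQF
PhoE_Ec	Escherichia coli	known_porin	IVAVGMTYQF
OmpF_Ec	Escherichia coli	known_porin	TVAVGIVYQF
OmpC_Ec	Escherichia coli	known_porin	IVALGLVYQF
TRQ2_0459	Thermotoga sp. RQ2	ortholog	FGFITYRLAF
Tpet_0444	Thermotoga petrophila	ortholog	YLYLKASVAF
Tnap_0258	Thermotoga naphthophila	ortholog	YLYLKASVAF
CTN_0196	Thermotoga neapolitana	ortholog	YLYLKAEVEF
Tmel_0175	Thermosipho melanesiensis	ortholog	YAKLSWSVSF
Fnod_1725	Fervidobacterium nodosum	ortholog	NLKLTYSASF
Kole_1501	Kosmotoga olearia	ortholog	YAYVGYYAAF
Theba_0319	Mesotoga prima	ortholog	SLGLYFDKYF
Pmob_0056	Petrotoga mobilis	ortholog	YLYLKAEFKF
Tlet_1718	Thermotoga lettingae	analog	TLAWRMRVYF
THA_406	Thermosipho africanus	analog	TLNMNAHFDF
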