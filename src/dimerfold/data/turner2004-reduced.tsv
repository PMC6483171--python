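# turner2004-reduced: nearest-neighbor RNA free-energy parameters at 37 C, kcal/mol.
# Values from the Turner 2004 rule set (Mathews, Disney, Childs, Schroeder, Zuker,
# Turner, PNAS 2004; Turner & Mathews, NAR 2010), as distributed with ViennaRNA.
# Reduced scope: Watson-Crick + G.U stacks, length-dependent loop initiations,
# affine multiloop, terminal AU/GU penalty, intermolecular duplex initiation.
# stack <outer pair XY> <inner pair ZW>: helix step 5'-XZ-3' / 3'-YW-5'.
stack	CG	CG	-3.30
stack	CG	GC	-2.40
stack	CG	GU	-1.40
stack	CG	UG	-2.10
stack	CG	AU	-2.10
stack	CG	UA	-2.10
stack	GC	CG	-3.40
stack	GC	GC	-3.30
stack	GC	GU	-1.50
stack	GC	UG	-2.50
stack	GC	AU	-2.40
stack	GC	UA	-2.20
stack	GU	CG	-2.50
stack	GU	GC	-2.10
stack	GU	GU	-0.50
stack	GU	UG	1.30
stack	GU	AU	-1.30
stack	GU	UA	-1.40
stack	UG	CG	-1.50
stack	UG	GC	-1.40
stack	UG	GU	0.30
stack	UG	UG	-0.50
stack	UG	AU	-1.00
stack	UG	UA	-0.60
stack	AU	CG	-2.20
stack	AU	GC	-2.10
stack	AU	GU	-0.60
stack	AU	UG	-1.40
stack	AU	AU	-0.90
stack	AU	UA	-1.10
stack	UA	CG	-2.40
stack	UA	GC	-2.10
stack	UA	GU	-1.00
stack	UA	UG	-1.30
stack	UA	AU	-1.30
stack	UA	UA	-0.90
hairpin	3	5.40
hairpin	4	5.60
hairpin	5	5.70
hairpin	6	5.40
hairpin	7	6.00
hairpin	8	5.50
hairpin	9	6.40
hairpin	10	6.50
hairpin	11	6.60
hairpin	12	6.70
hairpin	13	6.80
hairpin	14	6.90
hairpin	15	6.90
hairpin	16	7.00
hairpin	17	7.10
hairpin	18	7.10
hairpin	19	7.20
hairpin	20	7.20
hairpin	21	7.30
hairpin	22	7.30
hairpin	23	7.40
hairpin	24	7.40
hairpin	25	7.50
hairpin	26	7.50
hairpin	27	7.50
hairpin	28	7.60
hairpin	29	7.60
hairpin	30	7.70
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
bulge	7	4.60
bulge	8	4.70
bulge	9	4.80
bulge	10	4.90
bulge	11	5.00
bulge	12	5.10
bulge	13	5.20
bulge	14	5.30
bulge	15	5.40
bulge	16	5.40
bulge	17	5.50
bulge	18	5.50
bulge	19	5.60
bulge	20	5.70
bulge	21	5.70
bulge	22	5.80
bulge	23	5.80
bulge	24	5.80
bulge	25	5.90
bulge	26	5.90
bulge	27	6.00
bulge	28	6.00
bulge	29	6.00
bulge	30	6.10
internal	2	1.00
internal	3	1.00
internal	4	1.10
internal	5	2.00
internal	6	2.00
internal	7	2.10
internal	8	2.30
internal	9	2.40
internal	10	2.50
internal	11	2.60
internal	12	2.70
internal	13	2.80
internal	14	2.90
internal	15	2.90
internal	16	3.00
internal	17	3.10
internal	18	3.10
internal	19	3.20
internal	20	3.30
internal	21	3.30
internal	22	3.40
internal	23	3.40
internal	24	3.50
internal	25	3.50
internal	26	3.50
internal	27	3.60
internal	28	3.60
internal	29	3.70
internal	30	3.70
multiloop	closing	9.30
multiloop	branch	-0.90
multiloop	unpaired	0.00
misc	terminal_au	0.50
misc	duplex_init	4.10
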