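macromolecule	fraction_pct	monomer_id	monomer_mw	within_fraction
protein	50.1	aa_avg[c]	109.0	1.0
DNA	3.0	dntp_avg[c]	487.0	1.0
RNA	8.5	ntp_avg[c]	503.0	1.0
phospholipids	0.9	pl_avg[c]	734.0	1.0
peptidoglycan	2.5	pgly_unit[c]	941.0	1.0
lipopolysaccharides	3.4	lps_unit[c]	1793.0	1.0
polysaccharides	15.7	glycan_unit[c]	162.0	1.0
PHB	15.9	phb_unit[c]	86.0	1.0
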