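# Default reaction table: electro-generated ROS chemistry, protein oxidation and
# photon-emitting steps in a pulsed-field treatment chamber. Rate constants for
# bulk steps come from standard aqueous radiation-chemistry / enzymology
# compilations (see provenance column); electrode steps carry k=0 because their
# rates are set by the partitioned electrode current, not by mass action.
# Stoichiometries that the mechanism describes only verbally are flagged
# `assumed` and are user-editable. Columns are tab-separated.
id	reactants	products	k	k_units	kind	z	band_nm	provenance
1	H2O	HO. + H+	0	-	anodic	1		assumed: one-electron water oxidation, HO. intermediate
2	HO. + H2O	H2O2 + H+	0	-	anodic	1		assumed: second one-electron oxidation step
3	H2O2	HO2. + H+	0	-	anodic	1		assumed: third one-electron oxidation step
4	HO2.	3O2 + H+	0	-	anodic	1		assumed: final oxidation step; ROS converted to ground-state 3O2
5a	HO. + HO2.	1O2 + H2O	6.0e9	M-1 s-1	bulk			k Buxton et al. 1988; 1O2-forming disproportionation, products assumed
5b	2 HO.	H2O2	5.5e9	M-1 s-1	bulk			Buxton et al. 1988 (HO. self-recombination)
6	2 HO2.	1O2 + H2O2	8.3e5	M-1 s-1	bulk			k Bielski et al. 1985; 1O2-forming channel assumed
7	HO2. + O2.- + H+	1O2 + H2O2	9.7e7	M-1 s-1	bulk			k Bielski et al. 1985; 1O2-forming channel assumed; H+ buffered
8	1O2	3O2	2.9e5	s-1	emission		1278	monomolecular decay/quenching by water, tau ~3.5 us; Wilkinson et al. 1995
9	2 1O2	2 3O2	1.0e4	M-1 s-1	emission		634	dimol emission; k assumed order-of-magnitude
10	H2O2	HO2. + H+	0	-	anodic	1		one-electron H2O2 electrooxidation
12	O2.- + H2O2	HO. + OH- + 3O2	1.0e3	M-1 s-1	bulk			assumed: trace-metal-catalysed effective Haber-Weiss rate (iron-bearing samples); uncatalysed k=0.13 (Weinstein & Bielski 1979) available as override
13	HO. + H2O2	HO2. + H2O	2.7e7	M-1 s-1	bulk			Buxton et al. 1988
14	BSA	BSA. + H+	0	-	anodic	1		protein electrooxidation with proton abstraction
15	BSA + HO.	BSA. + H2O	5.0e10	M-1 s-1	bulk			assumed: diffusion-limited, multi-site protein + HO.
16	BSA. + 3O2	BSAOO.	1.0e9	M-1 s-1	bulk			assumed: typical carbon radical + O2 addition
17	BSAOO.	0.5 3RCOR* + 0.5 1O2 + BSA_ox	0.05	s-1	bulk			assumed: slow peroxyl cyclization/dimerization + fragmentation; branching configurable
18	3RCOR*	BSA_ox	2.0e5	s-1	emission		425	assumed: triplet carbonyl radiative/non-radiative relaxation
19	Fe2+ + H2O2	Fe3+ + HO. + OH-	76	M-1 s-1	bulk			Fenton; Walling 1975
20	Fe3+ + H2O2	Fe2+ + HO2. + H+	0.01	M-1 s-1	bulk			Fenton-like Fe(III) reduction; compilation estimate
21	SOD + O2.- + H+	SOD + 0.5 H2O2 + 0.5 3O2	2.0e9	M-1 s-1	enzymatic			SOD dismutation, kcat/KM regime; Fridovich 1975; per-substrate stoichiometry
22	CAT + H2O2	CAT + H2O + 0.5 3O2	1.7e7	M-1 s-1	enzymatic			catalase, kcat/KM regime; compilation; per-substrate stoichiometry
23	H2O	H. + OH-	0	-	cathodic	1		water electroreduction, H atom intermediate
24	H. + H2O	H2 + OH-	0	-	cathodic	1		water electroreduction to hydrogen
25	3O2	O2.-	0	-	cathodic	1		oxygen electroreduction to superoxide
26	O2.- + H+	HO2-	0	-	cathodic	1		superoxide electroreduction to hydroperoxide anion
27	HO2- + H+	H2O2	3.2e3	s-1(eff)	bulk			pH-effective protonation: 5e10 M-1 s-1 x [H+] at pH 7.2
28	H2O2	HO. + OH-	0	-	cathodic	1		H2O2 electroreduction, HO. intermediate
29	HO.	OH-	0	-	cathodic	1		HO. electroreduction to hydroxide
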