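# Aqueous diffusion coefficients (25 degC) used for inter-compartment exchange.
# Small-species values from standard compilations; macromolecular species are
# listed with D=0 here because accumulated protein at the electrode is treated
# as retained (see methods note) and moves only by the explicit migration term.
species	D_m2_per_s
HO.	2.3e-9
HO2.	1.0e-9
O2.-	1.75e-9
H2O2	1.4e-9
HO2-	1.4e-9
3O2	2.1e-9
1O2	2.1e-9
H.	7.0e-9
H2	4.5e-9
Fe2+	7.1e-10
Fe3+	6.0e-10
BSA	0
BSA.	0
BSAOO.	0
BSA_ox	0
3RCOR*	0
SOD	0
CAT	0
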