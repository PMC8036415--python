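trinucleotide	duplex_dG	duplex_dH	duplex_dS	gc_fraction	purine_fraction
AAA	-1.0000	-7.9000	-22.2000	0.000000	1.000000
AAC	-1.2200	-8.1500	-22.3000	0.333333	0.666667
AAG	-1.1400	-7.8500	-21.6000	0.333333	1.000000
AAT	-0.9400	-7.5500	-21.3000	0.000000	0.666667
ACA	-1.4450	-8.4500	-22.5500	0.333333	0.666667
ACC	-1.6400	-8.2000	-21.1500	0.666667	0.333333
ACG	-1.8050	-9.5000	-24.8000	0.666667	0.666667
ACT	-1.3600	-8.1000	-21.7000	0.333333	0.333333
AGA	-1.2900	-8.0000	-21.6000	0.333333	1.000000
AGC	-1.7600	-8.8000	-22.7000	0.666667	0.666667
AGG	-1.5600	-7.9000	-20.4500	0.666667	1.000000
AGT	-1.3600	-8.1000	-21.7000	0.333333	0.666667
ATA	-0.7300	-7.2000	-20.8500	0.000000	0.666667
ATC	-1.0900	-7.7000	-21.3000	0.333333	0.333333
ATG	-1.1650	-7.8500	-21.5500	0.333333	0.666667
ATT	-0.9400	-7.5500	-21.3000	0.000000	0.333333
CAA	-1.2250	-8.2000	-22.4500	0.333333	0.666667
CAC	-1.4450	-8.4500	-22.5500	0.666667	0.333333
CAG	-1.3650	-8.1500	-21.8500	0.666667	0.666667
CAT	-1.1650	-7.8500	-21.5500	0.333333	0.333333
CCA	-1.6450	-8.2500	-21.3000	0.666667	0.333333
CCC	-1.8400	-8.0000	-19.9000	1.000000	0.000000
CCG	-2.0050	-9.3000	-23.5500	1.000000	0.333333
CCT	-1.5600	-7.9000	-20.4500	0.666667	0.000000
CGA	-1.7350	-9.4000	-24.7000	0.666667	0.666667
CGC	-2.2050	-10.2000	-25.8000	1.000000	0.333333
CGG	-2.0050	-9.3000	-23.5500	1.000000	0.666667
CGT	-1.8050	-9.5000	-24.8000	0.666667	0.333333
CTA	-0.9300	-7.5000	-21.1500	0.333333	0.333333
CTC	-1.2900	-8.0000	-21.6000	0.666667	0.000000
CTG	-1.3650	-8.1500	-21.8500	0.666667	0.333333
CTT	-1.1400	-7.8500	-21.6000	0.333333	0.000000
GAA	-1.1500	-8.0500	-22.2000	0.333333	1.000000
GAC	-1.3700	-8.3000	-22.3000	0.666667	0.666667
GAG	-1.2900	-8.0000	-21.6000	0.666667	1.000000
GAT	-1.0900	-7.7000	-21.3000	0.333333	0.666667
GCA	-1.8450	-9.1500	-23.5500	0.666667	0.666667
GCC	-2.0400	-8.9000	-22.1500	1.000000	0.333333
GCG	-2.2050	-10.2000	-25.8000	1.000000	0.666667
GCT	-1.7600	-8.8000	-22.7000	0.666667	0.333333
GGA	-1.5700	-8.1000	-21.0500	0.666667	1.000000
GGC	-2.0400	-8.9000	-22.1500	1.000000	0.666667
GGG	-1.8400	-8.0000	-19.9000	1.000000	1.000000
GGT	-1.6400	-8.2000	-21.1500	0.666667	0.666667
GTA	-1.0100	-7.8000	-21.8500	0.333333	0.666667
GTC	-1.3700	-8.3000	-22.3000	0.666667	0.333333
GTG	-1.4450	-8.4500	-22.5500	0.666667	0.666667
GTT	-1.2200	-8.1500	-22.3000	0.333333	0.333333
TAA	-0.7900	-7.5500	-21.7500	0.000000	0.666667
TAC	-1.0100	-7.8000	-21.8500	0.333333	0.333333
TAG	-0.9300	-7.5000	-21.1500	0.333333	0.666667
TAT	-0.7300	-7.2000	-20.8500	0.000000	0.333333
TCA	-1.3750	-8.3500	-22.4500	0.333333	0.333333
TCC	-1.5700	-8.1000	-21.0500	0.666667	0.000000
TCG	-1.7350	-9.4000	-24.7000	0.666667	0.333333
TCT	-1.2900	-8.0000	-21.6000	0.333333	0.000000
TGA	-1.3750	-8.3500	-22.4500	0.333333	0.666667
TGC	-1.8450	-9.1500	-23.5500	0.666667	0.333333
TGG	-1.6450	-8.2500	-21.3000	0.666667	0.666667
TGT	-1.4450	-8.4500	-22.5500	0.333333	0.333333
TTA	-0.7900	-7.5500	-21.7500	0.000000	0.333333
TTC	-1.1500	-8.0500	-22.2000	0.333333	0.000000
TTG	-1.2250	-8.2000	-22.4500	0.333333	0.333333
TTT	-1.0000	-7.9000	-22.2000	0.000000	0.000000
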