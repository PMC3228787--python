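set	chrom	insert_start	insert_end	gene	positive_wells	total_wells
background	11	116201218	116201584	APOA4;APOC3	4	5
background	11	1721407	1721765	HCCA2	3	6
background	11	66008803	66009164	DPP3	2	2
background	11	71615350	71615709	INPPL1	2	2
non_muscle	15	83184998	83185491	ALPK3	2	2
non_muscle	18	40637097	40637579	SETBP1	3	4
non_muscle	22	22516569	22517062	DERL3;SLC2A11	10	11
non_muscle	22	22883584	22884017	CABIN1	2	4
muscle	1	119250477	119250882	TBX15	2	2
muscle	1	199611961	199612457	TNNT2	2	4
muscle	2	144878533	144878970	ZEB2	2	2
muscle	2	88147915	88148315	SMYD1	4	4
muscle	4	37728494	37728957	TBC1D1	2	4
muscle	6	42106373	42106867	CCND3	2	2
muscle	6	7127364	7127817	RREB1	2	4
muscle	9	35677887	35678364	TPM2	6	9
muscle	14	104259362	104259861	INF2;ADSSL1	2	3
muscle	19	3326530	3326884	NFIC	4	4
muscle	19	54184834	54185225	GYS1	2	3
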