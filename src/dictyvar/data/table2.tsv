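chrom_site	gene_id	samples	consequence	impact	aa_change
NC_007087.3:2556092	DDB_G0269332	22	missense_var.	Moderate	D/N
NC_007087.3:3010110	DDB_G0270828	21-NF1	missense_var.	Moderate	L/F
NC_007087.3:3624901	DDB_G0270964	18-NF1	missense_var.	Moderate	N/H
NC_007087.3:3928085	DDB_G0269956 (RTE)	21-NF2	upstream_gene_var.	Modifier	-
NC_007087.3:4563335	DDB_G0270834 (sgmA)	5-NF2	missense_var.	Moderate	L/F
NC_007088.5:1741979	DDB_G0272244 (grlG)	6	stop_gained	High	L/*
NC_007088.5:1741982	DDB_G0272244 (grlG)	7 & 7-NF2	missense_var.	Moderate	P/R
NC_007088.5:1742043	DDB_G0272244 (grlG)	11	missense_var.	Moderate	E/K
NC_007088.5:1742355	DDB_G0272244 (grlG)	17	missense_var.	Moderate	I/F
NC_007088.5:1742362	DDB_G0272244 (grlG)	13 & 13-NF2	missense_var.	Moderate	N/K
NC_007088.5:1742375	DDB_G0272244 (grlG)	10 & 10-NF3	stop_gained	High	L/*
NC_007088.5:1742506	DDB_G0272244 (grlG)	18-NF1	missense_var.	Moderate	L/F
NC_007088.5:1743478	DDB_G0272244 (grlG)	2	missense_var.	Moderate	Y/N
NC_007088.5:1743823	DDB_G0272244 (grlG)	21 & 21-NF2	stop_gained	High	G/*
NC_007088.5:1743844	DDB_G0272244 (grlG)	22	stop_gained	High	K/*
NC_007088.5:1761939	DDB_G0272484	16-NF2	missense_var.	Moderate	E/Q
NC_007088.5:4313995	DDB_G0274875 (rnf160)	16-NF2	stop_gained	High	E/*
NC_007088.5:6565220	DDB_G0276291	17	missense_var.	Moderate	K/N
NC_007088.5:6762467	DDB_G0276367	17	stop_gained	High	W/*
NC_007088.5:6787007	DDB_G0276529	7-NF2 & 16-NF2	missense_var.	Moderate	M/L
NC_007088.5:6871012	DDB_G0276553	7 & 7-NF2	upstream_gene_var.	Modifier	-
NC_007088.5:7954466	DDB_G0277481	21-NF2	missense_var.	Moderate	M/K
NC_007089.4:1029309	DDB_G0278531	24-NF1	stop_gained	High	K/*
NC_007089.4:1073554	DDB_G0278559	7 & 7-NF2	missense_var.	Moderate	G/S
NC_007089.4:1101637	DDB_G0278575	7 & 7-NF2	upstream_gene_var.	Modifier	-
NC_007089.4:3459101	DDB_G0280505 (tmem144A)	5-NF2	missense_var.	Moderate	M/I
NC_007089.4:5126190	DDB_G0281923 (mrhA)	21-NF1	downstream_gene_var.	Modifier	-
NC_007089.4:5671190	DDB_G0282355	12 & 12-NF1	upstream_gene_var.	Modifier	-
NC_007090.3:2549009	DDB_G0284845 (gxcC)	3-NF1	upstream_gene_var.	Modifier	-
NC_007091.3:905736	DDB_G0287967	18-NF1	downstream_gene_var.	Modifier	-
NC_007091.3:1993104	DDB_G0288805	22	stop_gained	High	K/*
NC_007091.3:2942727	DDB_G0289555 (arkA)	21-NF1	missense_var.	Moderate	T/K
NC_007091.3:2996049	DDB_G0289583	11	missense_var.	Moderate	C/Y
NC_007091.3:4205385	DDB_G0290523	21-NF2	synonymous_var.	Low	-
NC_007091.3:4793752	DDB_G0290943 (pks39)	20-NF1 & 20-NF3	missense_var.	Moderate	P/S
NC_007091.3:4956884	DDB_G0291085 (gxcE)	21-NF2	missense_var.	Moderate	T/I
NC_007092.3:1299121	DDB_G0292198 (RTE)	5-NF2	missense_var.	Moderate	H/L
NC_007092.3:1984519	DDB_G0292696 (colA)	9 & 9-NF3	missense_var.	Moderate	P/S
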