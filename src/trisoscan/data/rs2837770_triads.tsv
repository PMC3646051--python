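# trisoscan trio genotype table (v1 dialect)
# 26 trisomic HSCR-DS triads genotyped at rs2837770 (chr21:40956222, DSCAM intron 3)
# encoding: dosage columns count copies of the MINOR allele (A); major allele G
# layout: parental roles (CDJP = correctly disjoining, NDJP = non-disjoining);
#         parental sides are not recorded per triad in this dataset
trio_id	snp_id	position	minor_allele	major_allele	cdjp_dosage	ndjp_dosage	child_dosage	ploidy
triad01	rs2837770	40956222	A	G	1	1	2	3
triad02	rs2837770	40956222	A	G	1	0	1	3
triad03	rs2837770	40956222	A	G	0	2	2	3
triad04	rs2837770	40956222	A	G	2	0	1	3
triad05	rs2837770	40956222	A	G	1	1	2	3
triad06	rs2837770	40956222	A	G	1	1	3	3
triad07	rs2837770	40956222	A	G	1	0	1	3
triad08	rs2837770	40956222	A	G	1	1	2	3
triad09	rs2837770	40956222	A	G	2	0	1	3
triad10	rs2837770	40956222	A	G	0	0	0	3
triad11	rs2837770	40956222	A	G	0	1	1	3
triad12	rs2837770	40956222	A	G	0	0	0	3
triad13	rs2837770	40956222	A	G	2	1	2	3
triad14	rs2837770	40956222	A	G	2	2	3	3
triad15	rs2837770	40956222	A	G	1	1	2	3
triad16	rs2837770	40956222	A	G	1	2	3	3
triad17	rs2837770	40956222	A	G	0	0	0	3
triad18	rs2837770	40956222	A	G	1	2	3	3
triad19	rs2837770	40956222	A	G	1	2	3	3
triad20	rs2837770	40956222	A	G	1	2	3	3
triad21	rs2837770	40956222	A	G	1	0	1	3
triad22	rs2837770	40956222	A	G	1	0	1	3
triad23	rs2837770	40956222	A	G	1	1	2	3
triad24	rs2837770	40956222	A	G	0	0	0	3
triad25	rs2837770	40956222	A	G	2	1	3	3
triad26	rs2837770	40956222	A	G	1	0	1	3
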