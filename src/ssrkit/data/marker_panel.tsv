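marker	forward	reverse	motif	repeats	size_range	ta
Evg-01	AGTCATTGTGCGCAGTTTCC	GGAGGACTCCATGTGGATGAG	CTT	8	100-120	60
Evg-02	GGAGAAGCATTTGAAGGTTCTTGT	TCGCATTTATCCCTGGCAC	AG	12	118-153	55
Evg-03	ACAGCATAAGCGAAATAGCAG	ACAGCATAAGCGAAATAGCAG	AG	12	107-123	60
Evg-04	GCCATCGAGAGCTAAGGG	GGGCAAGGCCGTAAGATCAAC	AG	21	113-147	60
Evg-05	AGTTGTCACCAATTGCACC	GCCATCCTCCACACATGCC	GA	22	103-141	60
Evg-06	CCGAAGTGCAACACCAGAGT	CGCTTTGCTCAACATCACC	GAA	9	202-211	60
Evg-07	GGTTGTCCTCAAGAACGTGG	TGATGCCTAATGCCTCTCCC	GTG	9	73-94	60
Evg-08	CCATCGACGCCTTAACAGAG	TGAACCTCGGGAGTGACATAAG	GA	21	164-190	60
Evg-09	GCCTTTCGTATGCTTGGTGG	ACGTTGTTGCCGACATTCTG	GA	13	141-175	60
Evg-10	CAGCCTGTGCAGCTAATCAC	CAGCAGTTGCAGATCGTGTC	AG	21	191-210	60
Evg-11	GGCCTAGTGACATGATGGTG	TGATGCTAGATTCAAAGTCAAGG	AC	13	135-160	60
Evg-12	TGCAACCCTTTGCTGCATTC	AGCATCATTCGCCATGGTTG	TG	14	135-154	60
Evg-13	CTTGAAAGCATTGCATGTGG	CTCACCACTGTAGACCTCAGC	CA	14	189-229	60
Evg-14	AACCAATCTGCCTGCATGTG	GCCAGTGATTGTTGAGGTGG	TGA	8	153-159	60
Evg-15	TCCTTTAGGTTATTTGGTTGCC	CCTTGGACATGCCTCACATC	AG	15	110-134	55
Evg-16	GGCTAGTCCAGTTGGAAAGAG	GTAATCACCTCTGCCTTCACC	AG	13	109-117	60
Evg-17	GCGTCTGGTATGCTCAACTG	TCGGGAATGATACAGAGGCG	TCA	8	111-154	60
Evg-18	TCACTCCGATGGAAGGGATG	TCTCCACCATTTTAGTTGGCAC	GAG	7	181-188	60
Evg-19	GGTATGAAAGCCACACCACC	AGTTCACCCACGCCTCAC	GT	16	234-255	60
Evg-20	TTGCTCTCTGCTACTGACGG	CCGGTAACTTGGTGGAAGTC	CA	17	138-148	60
Evg-21	CAGGCAACCACTGCGATATG	CAGTTGTCTCCCCAGGTGC	CA	12	106-116	60
Evg-22	CTATCCAGGAGCCCATCTCG	ACTCTTCTCTTCGCCTGTGG	CA	15	88-94	60
Evg-23	CCACCAAAGGGCTCCTCG	TCGGATTCTCCCGCTATTGG	AC	13	129-143	60
Evg-24	TTTTCGGACGGTCTCTGTGG	TTCTTCTGCTGGCGTTTGAG	TTG	8	155-162	60
Evg-25	CACGTTGATGTCGTTCCGTC	GAATCGCTTCAAGGCGTAGG	CT	13	201-229	60
Evg-26	AAGCCATTGATGACTCCCCG	CAGTTGCACGCAGAGAAAAC	AC	12	110-139	60
Evg-27	GCAATAGAATGGTACGGAGCG	TTTTGACTGTTCCGACGGTG	AG	16	103-123	60
Evg-28	AAGCCACGGAATCAGCAAAC	ACCCACTACCTTTCCCTAAGC	AC	12	201-209	60
Evg-29	GTTCGACTCGTCCAAGAAGG	ACTGTCTTAGTGATAGCCATGC	AC	15	103-113	60
Evg-48	TAATTCTTCCCACCGGGGTC	GACCACTTACTTTTTGCACGC	TG	12	127-133	60
Evg-49	TCCTGCACCCTCCATATTCC	TCTCTCTCTCTGATCTTCGTAGC	GA	13	226-234	60
Evg-50	ATCTTGAACGTGGGGAAGGG	TGATACCTGGTGAGGATGCG	TG	13	162-188	60
Evg-51	TGAATGAGTGGGGGATGCTG	AATGGATCGTTATCCAACGTG	CAT	9	145-148	60
Evg-52	TATGGGAAGGGGATCCACAC	CAAATGCCGATAGGGACAGC	CA	13	212-231	60
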