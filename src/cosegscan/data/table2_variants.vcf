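##fileformat=VCFv4.2
##reference=GRCh37/hg19
##contig=<ID=8>
##contig=<ID=9>
##contig=<ID=11>
##contig=<ID=12>
##contig=<ID=15>
##contig=<ID=17>
##contig=<ID=20>
##INFO=<ID=CONSEQ,Number=A,Type=String,Description="Consequence class">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=INHOUSE,Number=A,Type=Integer,Description="In-house database count">
##INFO=<ID=AC_GNOMAD,Number=A,Type=Integer,Description="Allele count in GNOMAD">
##INFO=<ID=AN_GNOMAD,Number=1,Type=Integer,Description="Allele number in GNOMAD">
##INFO=<ID=PPH_S,Number=1,Type=Float,Description="PolyPhen score">
##INFO=<ID=PPH_C,Number=1,Type=String,Description="PolyPhen class">
##INFO=<ID=SIFT_S,Number=1,Type=Float,Description="SIFT score">
##INFO=<ID=SIFT_C,Number=1,Type=String,Description="SIFT class">
##INFO=<ID=COND_NT,Number=1,Type=String,Description="Nucleotide conservation">
##INFO=<ID=COND_AA,Number=1,Type=String,Description="Amino-acid conservation">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=SS,Number=1,Type=Integer,Description="Read-seed support">
##FORMAT=<ID=CL,Number=1,Type=Integer,Description="Clonal (duplicate) reads">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	I_1	I_2	II_1	II_2	III_1	III_2
8	145066215	.	G	A	.	PASS	GENE=GRINA;CONSEQ=missense;INHOUSE=0;AC_GNOMAD=2;AN_GNOMAD=282710;PPH_S=1;PPH_C=probably_damaging;SIFT_S=0;SIFT_C=deleterious;COND_NT=highly;COND_AA=highly	GT:DP:AD:SS:CL	0/1:40:20,20:10:1	0/0:40:40,0:0:0	0/1:42:21,21:11:1	0/0:38:38,0:0:0	0/1:44:23,21:9:2	0/0:41:41,0:0:0
9	125239752	rs143862742	C	T	.	PASS	GENE=OR1J1;CONSEQ=missense;INHOUSE=0;AC_GNOMAD=4;AN_GNOMAD=281994;PPH_S=0.001;PPH_C=benign;SIFT_S=0.56;SIFT_C=tolerated;COND_NT=weakly;COND_AA=highly	GT:DP:AD:SS:CL	0/1:38:19,19:9:1	0/0:40:40,0:0:0	0/1:36:18,18:8:0	0/0:39:39,0:0:0	0/1:40:20,20:10:1	0/0:37:37,0:0:0
9	127990266	rs142347258	G	A	.	PASS	GENE=RABEPK;CONSEQ=missense;INHOUSE=1;AC_GNOMAD=80;AN_GNOMAD=278552;PPH_S=1;PPH_C=probably_damaging;SIFT_S=0;SIFT_C=deleterious;COND_NT=highly;COND_AA=highly	GT:DP:AD:SS:CL	0/1:45:23,22:11:2	0/0:43:43,0:0:0	0/1:41:20,21:10:1	0/0:40:40,0:0:0	0/1:39:20,19:9:1	0/0:42:42,0:0:0
11	33052944	.	C	T	.	PASS	GENE=DEPDC7;CONSEQ=missense;INHOUSE=0;AC_GNOMAD=0;AN_GNOMAD=249446;PPH_S=0.896;PPH_C=possibly_damaging;SIFT_S=0.07;SIFT_C=tolerated;COND_NT=moderately;COND_AA=moderately	GT:DP:AD:SS:CL	0/1:37:18,19:9:1	0/0:36:36,0:0:0	0/1:40:20,20:10:1	0/0:41:41,0:0:0	0/1:43:22,21:10:1	0/0:38:38,0:0:0
11	95712527	rs201299551	T	C	.	PASS	GENE=MAML2;CONSEQ=missense;INHOUSE=2;AC_GNOMAD=95;AN_GNOMAD=279812;PPH_S=0.998;PPH_C=probably_damaging;SIFT_S=0.06;SIFT_C=tolerated;COND_NT=moderately;COND_AA=highly	GT:DP:AD:SS:CL	0/1:42:21,21:10:1	0/0:40:40,0:0:0	0/1:38:19,19:9:1	0/0:37:37,0:0:0	0/1:41:21,20:10:2	0/0:44:44,0:0:0
11	123777296	rs201007236	G	A	.	PASS	GENE=OR8D4;CONSEQ=missense;INHOUSE=2;AC_GNOMAD=224;AN_GNOMAD=282640;PPH_S=0;PPH_C=benign;SIFT_S=0;SIFT_C=deleterious;COND_NT=weakly;COND_AA=weakly	GT:DP:AD:SS:CL	0/1:39:20,19:9:1	0/0:41:41,0:0:0	0/1:40:20,20:10:1	0/0:39:39,0:0:0	0/1:36:18,18:8:1	0/0:40:40,0:0:0
11	125786960	rs370049057	C	G	.	PASS	GENE=DDX25;CONSEQ=missense;INHOUSE=0;AC_GNOMAD=3;AN_GNOMAD=241854;PPH_S=0;PPH_C=benign;SIFT_S=0.49;SIFT_C=tolerated;COND_NT=weakly;COND_AA=highly	GT:DP:AD:SS:CL	0/1:41:21,20:10:1	0/0:39:39,0:0:0	0/1:37:18,19:9:1	0/0:40:40,0:0:0	0/1:42:21,21:11:1	0/0:36:36,0:0:0
12	1949897	rs376597005	G	A	.	PASS	GENE=CACNA2D4;CONSEQ=splice_site;INHOUSE=0;AC_GNOMAD=9;AN_GNOMAD=280408	GT:DP:AD:SS:CL	0/1:40:20,20:10:1	0/0:42:42,0:0:0	0/1:44:22,22:11:1	0/0:38:38,0:0:0	0/1:39:20,19:9:1	0/0:41:41,0:0:0
15	79614380	.	C	T	.	PASS	GENE=TMED3;CONSEQ=missense;INHOUSE=0;AC_GNOMAD=3;AN_GNOMAD=282836;PPH_S=0.773;PPH_C=possibly_damaging;SIFT_S=0.06;SIFT_C=tolerated;COND_NT=moderately;COND_AA=highly	GT:DP:AD:SS:CL	0/1:38:19,19:9:1	0/0:40:40,0:0:0	0/1:41:20,21:10:1	0/0:43:43,0:0:0	0/1:40:20,20:10:1	0/0:39:39,0:0:0
17	18043906	rs200146361	C	T	.	PASS	GENE=MYO15A;CONSEQ=missense;INHOUSE=2;AC_GNOMAD=513;AN_GNOMAD=280690;PPH_S=0.999;PPH_C=probably_damaging;COND_NT=weakly;COND_AA=highly	GT:DP:AD:SS:CL	0/1:43:22,21:10:1	0/0:41:41,0:0:0	0/1:39:19,20:10:1	0/0:40:40,0:0:0	0/1:38:19,19:9:1	0/0:42:42,0:0:0
20	47740944	rs201180807	T	C	.	PASS	GENE=STAU1;CONSEQ=missense;INHOUSE=1;AC_GNOMAD=32;AN_GNOMAD=282876;PPH_S=0.911;PPH_C=possibly_damaging;SIFT_S=0.33;SIFT_C=tolerated;COND_NT=weakly;COND_AA=highly	GT:DP:AD:SS:CL	0/1:40:20,20:10:1	0/0:38:38,0:0:0	0/1:42:21,21:11:1	0/0:40:40,0:0:0	0/1:41:20,21:10:1	0/0:39:39,0:0:0
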