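"""Bundled reference dataset: seven japonica rice cultivars vs Nipponbare.

Summary tables from a published whole-genome resequencing of seven
*Oryza sativa* cultivars (five temperate japonica, the landrace-derived
Omachi, and the tropical japonica Moroberekan) mapped against the
Nipponbare IRGSP1.0 reference. They serve two purposes: worked example
input for the table/summary utilities, and ground for exact arithmetic
identities (partition sums, cross-sample percentages) that the pipeline
asserts before writing any table of its own.

All loaders return pandas DataFrames parsed from the inline TSV text.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

CULTIVARS = [
    "Omachi", "Yamadanishiki", "Kameji", "Gohyakumangoku",
    "Koshihikari", "Norin8", "Moroberekan",
]

# Mapped-read volumes, >=5x genome coverage and mean depth (unique reads).
_MAPPING_SUMMARY = """\
cultivar	mapped_nucleotides	mapped_coverage_ge5_pct	unique_nucleotides	unique_coverage_ge5_pct	average_depth
Omachi	19860548296	95.9	16630615027	87.3	51
Yamadanishiki	14879630564	96.0	12458183627	88.8	38
Kameji	15440489841	95.6	13024192299	87.8	40
Gohyakumangoku	20204766808	96.2	17088347679	89.3	51
Koshihikari	16560127574	97.0	13914811848	90.1	41
Norin8	22155138982	97.0	18740487803	89.6	56
Moroberekan	11909078634	91.5	9924861817	83.4	32
"""

# Genes per CDS-coverage bin (coverage of coding sequence by reads).
_GENE_COVERAGE_BINS = """\
bin	Omachi	Yamadanishiki	Kameji	Gohyakumangoku	Koshihikari	Norin8	Moroberekan
100	36629	36687	33229	38940	40296	38589	39193
90<=	4522	3669	5861	2674	2039	3333	2324
80<=	1115	1326	1897	822	515	742	595
70<=	480	743	1054	432	259	366	258
60<=	321	441	599	254	183	216	196
50<=	211	273	446	184	152	173	166
40<=	165	233	283	160	122	136	128
30<=	121	169	185	135	94	108	124
20<=	127	143	165	121	119	111	106
10<=	108	102	126	76	67	90	118
0<	95	107	124	92	80	83	118
0	620	621	545	624	588	567	1188
"""

# Per-chromosome SNP / insertion / deletion counts.
_CHROMOSOME_COUNTS = """\
type	chromosome	Omachi	Yamadanishiki	Kameji	Gohyakumangoku	Koshihikari	Norin8	Moroberekan
SNP	1	14683	14460	6217	7059	18138	2780	82017
SNP	2	10198	9322	7203	8876	6603	5893	41374
SNP	3	6111	6074	5428	4138	4499	2920	50560
SNP	4	26042	16178	14865	25723	17242	22211	84996
SNP	5	5706	6119	2677	5801	2053	1184	61350
SNP	6	15461	15329	3307	13571	2019	6778	94539
SNP	7	12938	10644	10752	10431	11829	3136	61282
SNP	8	10751	15596	4995	6727	11820	2137	85159
SNP	9	2953	1379	1522	17471	547	2700	38306
SNP	10	4460	6663	3627	4789	6237	7999	92007
SNP	11	17834	17610	12215	27182	21715	17399	61069
SNP	12	5662	4283	4159	10319	12753	10154	74789
insertion	1	1900	2037	2236	1328	2312	619	8752
insertion	2	1469	1423	1950	1344	1065	952	4797
insertion	3	893	937	1041	875	795	522	5492
insertion	4	3183	2672	3192	3361	2657	2901	7057
insertion	5	921	942	753	968	391	327	5684
insertion	6	1526	1618	1038	1640	373	858	8267
insertion	7	1472	1345	1979	1247	1518	473	5981
insertion	8	1248	1586	1482	938	1088	337	7017
insertion	9	403	309	724	1628	180	473	3425
insertion	10	645	823	2419	663	848	893	6637
insertion	11	1784	1855	2835	2718	2277	1812	5924
insertion	12	852	725	1002	1284	1618	1321	6031
deletion	1	1956	2045	2333	1440	2476	679	9700
deletion	2	1618	1508	2085	1371	1138	978	5454
deletion	3	1035	1025	1057	829	884	509	6129
deletion	4	4065	3404	4085	4248	3477	3772	8586
deletion	5	1060	1083	787	1127	427	411	6457
deletion	6	1731	1814	1078	1712	380	967	9479
deletion	7	1698	1494	2211	1315	1668	505	6642
deletion	8	1448	1741	1597	1007	1126	282	7634
deletion	9	479	351	795	1806	151	487	3835
deletion	10	773	900	2688	743	883	945	7541
deletion	11	2112	2119	3183	3146	2608	2181	6304
deletion	12	1095	897	1158	1577	1844	1477	6772
"""

# Region-class counts: SNPs then InDels (insertions + deletions pooled).
_ANNOTATION_COUNTS = """\
set	class	Omachi	Yamadanishiki	Kameji	Gohyakumangoku	Koshihikari	Norin8	Moroberekan
SNP	intergenic	107927	100279	62598	119362	95469	69833	700701
SNP	genic	24872	23378	14369	22725	19986	15458	126747
SNP	intron	12351	11932	7354	11248	9641	7667	68116
SNP	UTRs	4665	4255	2387	4367	3737	2929	24131
SNP	CDS	7856	7191	4628	7110	6608	4862	34500
SNP	synonymous	3668	3355	2100	3251	3008	2142	15876
SNP	nonsynonymous	4188	3836	2528	3859	3600	2720	18624
InDel	intergenic	29041	28302	36091	32085	26584	20481	131783
InDel	genic	6325	6351	7617	6230	5600	4200	27814
InDel	intron	3971	4019	4907	3869	3345	2551	18236
InDel	UTRs	1515	1488	1652	1488	1381	958	6616
InDel	CDS	839	844	1058	873	874	691	2962
"""

# Contig classification against the reference (unique / multi / unanchored
# scaffolds / no hit).
_CONTIG_CLASSIFICATION = """\
cultivar	total	unique	multi	unanchored	no_hit
Omachi	6903	1834	3250	231	1588
Yamadanishiki	4020	827	2785	63	345
Kameji	5415	1088	3189	101	1037
Gohyakumangoku	4555	821	2949	78	707
Koshihikari	3773	809	2482	60	422
Norin8	2554	434	1802	42	276
Moroberekan	23706	6717	14292	358	2339
"""

# High-unique-fraction contigs, those overlapping depth-0 regions, and the
# genes found there.
_NEWLY_MAPPED = """\
cultivar	candidate_contigs	newly_mapped_contigs	newly_covered_genes
Omachi	547	75	28
Yamadanishiki	245	21	9
Kameji	362	15	4
Gohyakumangoku	225	13	7
Koshihikari	298	19	5
Norin8	115	7	2
Moroberekan	1926	165	64
"""


def _read(text: str, **kw) -> pd.DataFrame:
    return pd.read_csv(StringIO(text), sep="\t", **kw)


def load_mapping_summary() -> pd.DataFrame:
    """Mapped/unique nucleotide volumes, >=5x coverage %, average depth."""
    return _read(_MAPPING_SUMMARY, index_col="cultivar")


def load_gene_coverage_bins() -> pd.DataFrame:
    """Gene counts per CDS-coverage bin; every column sums to 44,514 genes."""
    return _read(_GENE_COVERAGE_BINS, index_col="bin")


def load_chromosome_counts() -> pd.DataFrame:
    """Per-chromosome SNP/insertion/deletion counts for the seven cultivars."""
    return _read(_CHROMOSOME_COUNTS, index_col=["type", "chromosome"])


def load_annotation_counts() -> pd.DataFrame:
    """Region-class counts (SNP and InDel sets) for the seven cultivars."""
    return _read(_ANNOTATION_COUNTS, index_col=["set", "class"])


def load_contig_classification() -> pd.DataFrame:
    """Contig classification counts per cultivar."""
    return _read(_CONTIG_CLASSIFICATION, index_col="cultivar")


def load_newly_mapped_counts() -> pd.DataFrame:
    """Newly mapped contig and newly covered gene counts per cultivar."""
    return _read(_NEWLY_MAPPED, index_col="cultivar")
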