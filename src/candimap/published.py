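"""Reference summary tables from the eighteen-strain *Neurospora crassa*
classical-mutant resequencing dataset, transcribed as in-package fixtures.

These are the printed cohort-level summaries (per-strain SNP categories,
indel distributions, per-contig SNP counts, occurrence spectra, unique-SNP
counts, nonsense tallies) that the package's arithmetic — percentage columns,
spectrum totals, rate estimators, enrichment ratios — can be exercised
against without access to the underlying sequencing data.

Strains are keyed by their stock-center accession numbers. Counts are
transcribed verbatim; every derived quantity (percentages, totals, rates) is
recomputed by the package rather than stored.
"""

from __future__ import annotations

# Surveyed reference genome length (bases) used by the rate estimators.
GENOME_SIZE = 41_061_603

# Per-strain SNP counts by effect category:
# strain -> (total, nc, synonymous, nonsynonymous, utr3, utr5, intron, nonsense)
SNP_CATEGORY_COUNTS: dict[str, tuple[int, ...]] = {
    "106":  (23579, 14110, 4536, 2269, 851, 494, 1143, 18),
    "305":  (90195, 49883, 18740, 8417, 4875, 2560, 4709, 67),
    "309":  (13274, 9949, 1725, 667, 321, 144, 414, 11),
    "322":  (142489, 88879, 24733, 11525, 6692, 3112, 6413, 95),
    "821":  (188346, 112490, 35810, 17193, 8458, 4177, 8825, 122),
    "1211": (20493, 16100, 2263, 1146, 339, 187, 380, 19),
    "1303": (59356, 41212, 8773, 4330, 1828, 816, 2119, 35),
    "1363": (146641, 71259, 35955, 15999, 8535, 4463, 8685, 137),
    "2261": (44839, 25265, 9894, 4507, 1772, 911, 2111, 37),
    "3114": (41085, 24550, 9176, 3186, 1461, 751, 1626, 31),
    "3246": (21533, 14301, 3405, 1556, 839, 404, 843, 14),
    "3562": (106533, 57767, 22686, 10480, 5800, 2830, 5862, 78),
    "3564": (47981, 31886, 7821, 3702, 1661, 777, 1737, 36),
    "3566": (37516, 29134, 3962, 1875, 806, 354, 1198, 27),
    "3831": (22961, 17290, 2563, 1369, 523, 253, 792, 15),
    "3921": (80311, 47446, 16023, 7557, 3158, 1605, 3901, 84),
    "7022": (78991, 51944, 12585, 5843, 3110, 1602, 3270, 45),
    "7035": (18487, 13174, 2656, 1160, 472, 241, 686, 13),
}

# Per-strain indel distribution:
# strain -> (total, unique, cds, nc, intron, splice_site, other)
INDEL_DISTRIBUTION: dict[str, tuple[int, ...]] = {
    "106":  (3607, 136, 294, 2636, 289, 7, 381),
    "305":  (13335, 816, 1014, 9492, 1052, 18, 1759),
    "309":  (1959, 123, 137, 1466, 151, 3, 202),
    "322":  (15105, 2001, 701, 11182, 1236, 22, 1964),
    "821":  (21224, 6941, 919, 16066, 1637, 27, 2575),
    "1211": (1494, 100, 103, 1141, 106, 3, 141),
    "1303": (6110, 501, 321, 4746, 413, 7, 623),
    "1363": (24952, 5213, 2091, 17573, 1997, 31, 3260),
    "2261": (7059, 546, 600, 5143, 584, 6, 726),
    "3114": (4211, 3468, 246, 2971, 369, 6, 619),
    "3246": (2310, 89, 124, 1781, 146, 4, 255),
    "3562": (13753, 1920, 741, 10131, 1119, 19, 1743),
    "3564": (4960, 116, 274, 3747, 387, 8, 544),
    "3566": (3714, 471, 199, 2933, 261, 6, 315),
    "3831": (2450, 140, 138, 1922, 168, 4, 218),
    "3921": (9743, 979, 581, 7391, 748, 10, 1013),
    "7022": (8907, 918, 471, 6765, 625, 8, 1038),
    "7035": (1869, 93, 134, 1386, 148, 2, 199),
}

# Per-strain SNP counts on supercontigs 1-7 plus the ">7" remainder:
# strain -> (c1, c2, c3, c4, c5, c6, c7, rest)
SNPS_BY_CONTIG: dict[str, tuple[int, ...]] = {
    "106":  (5044, 947, 3607, 2250, 853, 391, 9186, 1301),
    "305":  (38046, 2537, 8514, 1019, 26797, 857, 8075, 4350),
    "309":  (4943, 2055, 891, 592, 896, 454, 604, 2839),
    "322":  (29658, 7256, 28243, 12754, 24790, 16428, 22415, 946),
    "821":  (45205, 12122, 16891, 41336, 15980, 30781, 19517, 6514),
    "1211": (4379, 2207, 4267, 1635, 1094, 1608, 3633, 1670),
    "1303": (7227, 13847, 10817, 4606, 5237, 12333, 3341, 1947),
    "1363": (43626, 21549, 19525, 8625, 32371, 3402, 17307, 236),
    "2261": (1304, 789, 10200, 3545, 261, 10966, 15258, 2516),
    "3114": (2725, 2165, 27516, 1868, 1614, 1710, 1731, 1756),
    "3246": (7811, 845, 792, 2606, 6415, 482, 547, 2035),
    "3562": (9178, 4064, 19381, 28334, 20810, 13947, 8024, 2795),
    "3564": (5492, 3142, 1510, 4691, 16787, 12046, 1828, 2485),
    "3566": (8701, 5056, 1402, 9660, 4716, 1698, 1570, 4713),
    "3831": (2410, 1584, 6176, 1187, 2824, 1177, 5243, 2360),
    "3921": (16641, 2307, 17416, 9018, 14521, 5537, 12038, 2833),
    "7022": (32843, 3897, 1749, 3105, 11562, 11989, 10164, 3682),
    "7035": (6040, 1396, 3145, 3668, 675, 668, 869, 2026),
}

# SNP occurrence spectrum: number of carrier strains -> number of SNP keys.
SNP_OCCURRENCE_SPECTRUM: dict[int, int] = {
    1: 227988, 2: 115667, 3: 68186, 4: 40033, 5: 24418, 6: 13026,
    7: 5285, 8: 3817, 9: 2912, 10: 769, 11: 559, 12: 68, 13: 49,
    14: 33, 15: 43, 16: 48, 17: 42, 18: 96,
}

# Per-strain private (unique) SNP counts.
UNIQUE_SNP_COUNTS: dict[str, int] = {
    "821": 73336, "3114": 29263, "1363": 21607, "3562": 16432, "7022": 15721,
    "3921": 9433, "1303": 9355, "305": 6653, "3566": 5306, "3564": 4612,
    "3246": 4253, "322": 3496, "1211": 3468, "2261": 3227, "7035": 2714,
    "3831": 1962, "106": 1033, "309": 704,
}

# Indel occurrence spectrum: carrier strains -> (indel keys, CDS indel keys).
INDEL_OCCURRENCE_SPECTRUM: dict[int, tuple[int, int]] = {
    1: (25894, 1885), 2: (16682, 1168), 3: (8818, 481), 4: (4968, 284),
    5: (3235, 167), 6: (1586, 69), 7: (640, 39), 8: (453, 25), 9: (347, 17),
    10: (108, 2), 11: (56, 4), 12: (25, 0), 13: (22, 0), 14: (14, 1),
    15: (15, 1), 16: (13, 1), 17: (19, 2), 18: (57, 15),
}

# Indels-per-gene histogram: number of genes -> indel count per gene.
INDELS_PER_ORF: dict[int, int] = {
    1: 1352, 2: 495, 3: 198, 4: 96, 5: 55, 6: 31, 7: 19, 8: 9,
    9: 3, 10: 4, 11: 3, 12: 0, 13: 4, 23: 1,
}

# Per-strain nonsense-mutation counts (mapped, i.e. per strain).
NONSENSE_PER_STRAIN: dict[str, int] = {
    "106": 18, "305": 67, "309": 11, "322": 95, "821": 122, "1211": 19,
    "1303": 35, "1363": 137, "2261": 37, "3114": 31, "3246": 14,
    "3562": 78, "3564": 36, "3566": 27, "3831": 15, "3921": 84,
    "7022": 45, "7035": 13,
}

# Cohort-level nonsense/annotation facts used by the enrichment estimator.
DISTINCT_NONSENSE = 405
NONSENSE_IN_CONSERVED_HYPOTHETICAL = 313
TOTAL_ORFS = 9_734
CONSERVED_HYPOTHETICAL_ORFS = 6_481

# Unique-SNP counts behind the published rate and density estimates.
RATE_EXAMPLES = {
    "309": {"unique_snps": 704, "unique_indels": 123},
    "106": {"unique_snps": 1033},
}
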