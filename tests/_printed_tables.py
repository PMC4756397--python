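"""Published enrichment-table rows used as fixed oracles.

Each row: (table, foreground, feature, a, n, A, N, printed_or) where a/n are
foreground counts, A/N background counts (inclusive convention) and
printed_or the odds ratio published at 2 decimals.
"""

# Table 1: detectable-5hmC probes per tissue vs the QC-passing array.
# Main strata: N = 374,094; n = 37,145 (pfc) / 65,563 (cbl).
# Alt-event block: N = 138,640; n = 14,429 (pfc) / 25,582 (cbl).
T1 = [
    ("t1", "pfc", "island", 2868, 37145, 120922, 374094, 0.18),
    ("t1", "pfc", "shore", 11934, 37145, 87312, 374094, 1.55),
    ("t1", "pfc", "shelf", 5434, 37145, 32912, 374094, 1.78),
    ("t1", "pfc", "outside", 16565, 37145, 124010, 374094, 1.62),
    ("t1", "pfc", "cgi_unannotated", 344, 37145, 8938, 374094, 0.38),
    ("t1", "pfc", "intergenic", 4367, 37145, 52325, 374094, 0.82),
    ("t1", "pfc", "distal_promoter", 1986, 37145, 16990, 374094, 1.19),
    ("t1", "pfc", "proximal_promoter", 9693, 37145, 148029, 374094, 0.54),
    ("t1", "pfc", "gene_body", 19870, 37145, 140919, 374094, 1.90),
    ("t1", "pfc", "downstream", 885, 37145, 6893, 374094, 1.30),
    ("t1", "pfc", "tfbs", 14623, 37145, 184178, 374094, 0.67),
    ("t1", "pfc", "dhs", 4449, 37145, 49903, 374094, 0.88),
    ("t1", "pfc", "A3SS", 330, 14429, 3347, 138640, 0.95),
    ("t1", "pfc", "A5SS", 357, 14429, 3364, 138640, 1.02),
    ("t1", "pfc", "AFE", 4897, 14429, 57956, 138640, 0.72),
    ("t1", "pfc", "ALE", 1353, 14429, 9026, 138640, 1.49),
    ("t1", "pfc", "CE", 7783, 14429, 60203, 138640, 1.53),
    ("t1", "pfc", "CNE", 1592, 14429, 20661, 138640, 0.71),
    ("t1", "pfc", "EI", 19, 14429, 137, 138640, 1.33),
    ("t1", "pfc", "II", 3080, 14429, 27746, 138640, 1.08),
    ("t1", "pfc", "IR", 1550, 14429, 16175, 138640, 0.91),
    ("t1", "pfc", "MXE", 1880, 14429, 13054, 138640, 1.44),
    ("t1", "cbl", "island", 6524, 65563, 120922, 374094, 0.23),
    ("t1", "cbl", "shore", 18544, 65563, 87312, 374094, 1.30),
    ("t1", "cbl", "shelf", 9958, 65563, 32912, 374094, 1.86),
    ("t1", "cbl", "outside", 29831, 65563, 124010, 374094, 1.68),
    ("t1", "cbl", "cgi_unannotated", 706, 65563, 8938, 374094, 0.44),
    ("t1", "cbl", "intergenic", 7461, 65563, 52325, 374094, 0.79),
    ("t1", "cbl", "distal_promoter", 2897, 65563, 16990, 374094, 0.97),
    ("t1", "cbl", "proximal_promoter", 13544, 65563, 148029, 374094, 0.40),
    ("t1", "cbl", "gene_body", 39335, 65563, 140919, 374094, 2.48),
    ("t1", "cbl", "downstream", 1620, 65563, 6893, 374094, 1.35),
    ("t1", "cbl", "tfbs", 19499, 65563, 184178, 374094, 0.44),
    ("t1", "cbl", "dhs", 6227, 65563, 49903, 374094, 0.68),
    ("t1", "cbl", "A3SS", 700, 25582, 3347, 138640, 1.14),
    ("t1", "cbl", "A5SS", 710, 25582, 3364, 138640, 1.15),
    ("t1", "cbl", "AFE", 7332, 25582, 57956, 138640, 0.56),
    ("t1", "cbl", "ALE", 2554, 25582, 9026, 138640, 1.59),
    ("t1", "cbl", "CE", 13980, 25582, 60203, 138640, 1.57),
    ("t1", "cbl", "CNE", 3149, 25582, 20661, 138640, 0.80),
    ("t1", "cbl", "EI", 45, 25582, 137, 138640, 1.78),
    ("t1", "cbl", "II", 4974, 25582, 27746, 138640, 0.96),
    ("t1", "cbl", "IR", 3025, 25582, 16175, 138640, 1.02),
    ("t1", "cbl", "MXE", 3221, 25582, 13054, 138640, 1.39),
]

# Table 2: top-1,000 loci by 5hmC level per tissue vs all detectable loci.
# Main strata: N = 79,263; n = 1,000. Alt block: N = 30,659; n = 398 / 451.
T2 = [
    ("t2", "pfc", "island", 121, 1000, 7837, 79263, 1.25),
    ("t2", "pfc", "shore", 472, 1000, 22593, 79263, 2.24),
    ("t2", "pfc", "shelf", 93, 1000, 11674, 79263, 0.59),
    ("t2", "pfc", "outside", 307, 1000, 36342, 79263, 0.52),
    ("t2", "pfc", "cgi_unannotated", 7, 1000, 817, 79263, 0.68),
    ("t2", "pfc", "intergenic", 89, 1000, 9604, 79263, 0.71),
    ("t2", "pfc", "distal_promoter", 46, 1000, 3703, 79263, 0.98),
    ("t2", "pfc", "proximal_promoter", 365, 1000, 16979, 79263, 2.11),
    ("t2", "pfc", "gene_body", 474, 1000, 46238, 79263, 0.64),
    ("t2", "pfc", "downstream", 19, 1000, 1922, 79263, 0.78),
    ("t2", "pfc", "tfbs", 545, 1000, 25482, 79263, 2.53),
    ("t2", "pfc", "dhs", 150, 1000, 8155, 79263, 1.54),
    ("t2", "pfc", "A3SS", 8, 398, 798, 30659, 0.77),
    ("t2", "pfc", "A5SS", 12, 398, 827, 30659, 1.12),
    ("t2", "pfc", "AFE", 158, 398, 9159, 30659, 1.55),
    ("t2", "pfc", "ALE", 27, 398, 3017, 30659, 0.67),
    ("t2", "pfc", "CE", 185, 398, 16604, 30659, 0.74),
    ("t2", "pfc", "CNE", 53, 398, 3755, 30659, 1.10),
    ("t2", "pfc", "EI", 1, 398, 50, 30659, 1.54),
    ("t2", "pfc", "II", 89, 398, 6003, 30659, 1.18),
    ("t2", "pfc", "IR", 63, 398, 3529, 30659, 1.45),
    ("t2", "pfc", "MXE", 43, 398, 3814, 30659, 0.85),
    ("t2", "cbl", "island", 275, 1000, 7837, 79263, 3.46),
    ("t2", "cbl", "shore", 276, 1000, 22593, 79263, 0.96),
    ("t2", "cbl", "shelf", 121, 1000, 11674, 79263, 0.80),
    ("t2", "cbl", "outside", 326, 1000, 36342, 79263, 0.57),
    ("t2", "cbl", "cgi_unannotated", 2, 1000, 817, 79263, 0.19),
    ("t2", "cbl", "intergenic", 74, 1000, 9604, 79263, 0.58),
    ("t2", "cbl", "distal_promoter", 19, 1000, 3703, 79263, 0.40),
    ("t2", "cbl", "proximal_promoter", 206, 1000, 16979, 79263, 0.95),
    ("t2", "cbl", "gene_body", 670, 1000, 46238, 79263, 1.45),
    ("t2", "cbl", "downstream", 29, 1000, 1922, 79263, 1.20),
    ("t2", "cbl", "tfbs", 383, 1000, 25482, 79263, 1.31),
    ("t2", "cbl", "dhs", 143, 1000, 8155, 79263, 1.45),
    ("t2", "cbl", "A3SS", 22, 451, 798, 30659, 1.92),
    ("t2", "cbl", "A5SS", 17, 451, 827, 30659, 1.41),
    ("t2", "cbl", "AFE", 112, 451, 9159, 30659, 0.78),
    ("t2", "cbl", "ALE", 46, 451, 3017, 30659, 1.04),
    ("t2", "cbl", "CE", 208, 451, 16604, 30659, 0.72),
    ("t2", "cbl", "CNE", 62, 451, 3755, 30659, 1.14),
    ("t2", "cbl", "EI", 2, 451, 50, 30659, 2.73),
    ("t2", "cbl", "II", 87, 451, 6003, 30659, 0.98),
    ("t2", "cbl", "IR", 80, 451, 3529, 30659, 1.66),
    ("t2", "cbl", "MXE", 35, 451, 3814, 30659, 0.59),
]

# Table 3: top-1,000 tissue-specific positions vs all detectable loci.
T3 = [
    ("t3", "tshmp", "island", 317, 1000, 7837, 79263, 4.23),
    ("t3", "tshmp", "shore", 209, 1000, 22593, 79263, 0.66),
    ("t3", "tshmp", "shelf", 92, 1000, 11674, 79263, 0.59),
    ("t3", "tshmp", "outside", 381, 1000, 36342, 79263, 0.73),
    ("t3", "tshmp", "cgi_unannotated", 1, 1000, 817, 79263, 0.10),
    ("t3", "tshmp", "intergenic", 132, 1000, 9604, 79263, 1.10),
    ("t3", "tshmp", "distal_promoter", 25, 1000, 3703, 79263, 0.52),
    ("t3", "tshmp", "proximal_promoter", 121, 1000, 16979, 79263, 0.50),
    ("t3", "tshmp", "gene_body", 690, 1000, 46238, 79263, 1.59),
    ("t3", "tshmp", "downstream", 31, 1000, 1922, 79263, 1.29),
    ("t3", "tshmp", "tfbs", 125, 1000, 25482, 79263, 0.30),
    ("t3", "tshmp", "dhs", 280, 1000, 8155, 79263, 3.39),
    ("t3", "tshmp", "A3SS", 14, 404, 798, 30659, 1.34),
    ("t3", "tshmp", "A5SS", 17, 404, 827, 30659, 1.58),
    ("t3", "tshmp", "AFE", 92, 404, 9159, 30659, 0.69),
    ("t3", "tshmp", "ALE", 40, 404, 3017, 30659, 1.01),
    ("t3", "tshmp", "CE", 202, 404, 16604, 30659, 0.85),
    ("t3", "tshmp", "CNE", 69, 404, 3755, 30659, 1.48),
    ("t3", "tshmp", "EI", 1, 404, 50, 30659, 1.52),
    ("t3", "tshmp", "II", 59, 404, 6003, 30659, 0.70),
    ("t3", "tshmp", "IR", 54, 404, 3529, 30659, 1.19),
    ("t3", "tshmp", "MXE", 39, 404, 3814, 30659, 0.75),
]

# Table 4: top-1,000 most inter-individually variable loci per tissue vs all
# detectable loci. Alt block n = 385 (pfc) / 418 (cbl).
T4 = [
    ("t4", "pfc", "island", 159, 1000, 7837, 79263, 1.72),
    ("t4", "pfc", "shore", 270, 1000, 22593, 79263, 0.93),
    ("t4", "pfc", "shelf", 107, 1000, 11674, 79263, 0.69),
    ("t4", "pfc", "outside", 376, 1000, 36342, 79263, 0.71),
    ("t4", "pfc", "cgi_unannotated", 88, 1000, 817, 79263, 9.26),
    ("t4", "pfc", "intergenic", 99, 1000, 9604, 79263, 0.80),
    ("t4", "pfc", "distal_promoter", 36, 1000, 3703, 79263, 0.76),
    ("t4", "pfc", "proximal_promoter", 172, 1000, 16979, 79263, 0.76),
    ("t4", "pfc", "gene_body", 583, 1000, 46238, 79263, 1.00),
    ("t4", "pfc", "downstream", 22, 1000, 1922, 79263, 0.91),
    ("t4", "pfc", "tfbs", 298, 1000, 25482, 79263, 0.90),
    ("t4", "pfc", "dhs", 77, 1000, 8155, 79263, 0.73),
    ("t4", "pfc", "A3SS", 15, 385, 798, 30659, 1.52),
    ("t4", "pfc", "A5SS", 10, 385, 827, 30659, 0.96),
    ("t4", "pfc", "AFE", 103, 385, 9159, 30659, 0.86),
    ("t4", "pfc", "ALE", 36, 385, 3017, 30659, 0.95),
    ("t4", "pfc", "CE", 200, 385, 16604, 30659, 0.92),
    ("t4", "pfc", "CNE", 60, 385, 3755, 30659, 1.32),
    ("t4", "pfc", "EI", 1, 385, 50, 30659, 1.59),
    ("t4", "pfc", "II", 74, 385, 6003, 30659, 0.98),
    ("t4", "pfc", "IR", 41, 385, 3529, 30659, 0.92),
    ("t4", "pfc", "MXE", 40, 385, 3814, 30659, 0.82),
    ("t4", "cbl", "island", 301, 1000, 7837, 79263, 3.92),
    ("t4", "cbl", "shore", 171, 1000, 22593, 79263, 0.52),
    ("t4", "cbl", "shelf", 134, 1000, 11674, 79263, 0.90),
    ("t4", "cbl", "outside", 281, 1000, 36342, 79263, 0.46),
    ("t4", "cbl", "cgi_unannotated", 113, 1000, 817, 79263, 12.23),
    ("t4", "cbl", "intergenic", 80, 1000, 9604, 79263, 0.63),
    ("t4", "cbl", "distal_promoter", 30, 1000, 3703, 79263, 0.63),
    ("t4", "cbl", "proximal_promoter", 113, 1000, 16979, 79263, 0.47),
    ("t4", "cbl", "gene_body", 642, 1000, 46238, 79263, 1.28),
    ("t4", "cbl", "downstream", 22, 1000, 1922, 79263, 0.91),
    ("t4", "cbl", "tfbs", 242, 1000, 25482, 79263, 0.67),
    ("t4", "cbl", "dhs", 61, 1000, 8155, 79263, 0.57),
    ("t4", "cbl", "A3SS", 15, 418, 798, 30659, 1.39),
    ("t4", "cbl", "A5SS", 17, 418, 827, 30659, 1.53),
    ("t4", "cbl", "AFE", 82, 418, 9159, 30659, 0.57),
    ("t4", "cbl", "ALE", 38, 418, 3017, 30659, 0.92),
    ("t4", "cbl", "CE", 187, 418, 16604, 30659, 0.69),
    ("t4", "cbl", "CNE", 86, 418, 3755, 30659, 1.86),
    ("t4", "cbl", "EI", 2, 418, 50, 30659, 2.94),
    ("t4", "cbl", "II", 69, 418, 6003, 30659, 0.81),
    ("t4", "cbl", "IR", 68, 418, 3529, 30659, 1.49),
    ("t4", "cbl", "MXE", 31, 418, 3814, 30659, 0.56),
]

ALL_ROWS = T1 + T2 + T3 + T4

# Headline set sizes used for inclusion-exclusion checks.
SET_SIZES = {"n_pfc": 37145, "n_cbl": 65563, "n_union": 79263, "n_both": 23445,
             "n_pfc_only": 13700, "n_cbl_only": 42118}
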