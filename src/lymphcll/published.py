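"""Published summary statistics of the 30-patient CLL discovery cohort.

These are the printed report-table values for the original nCounter cohort
(30 CLL, 5 normal peripheral-blood and 4 purified B-cell samples): group
means and fold-change cells for the worked examples, and the per-gene
coefficients of variation of the 44 CLL-preferential genes from which the
13-gene homogeneous core is filtered. They serve as fixed reference inputs
for worked examples and reproduction checks — nothing in the pipeline
computes *from* them except the table-rendering and CV-filter operations
they exercise.
"""

from __future__ import annotations

#: Genes expressed preferentially by B cells: (gene, mean normal PB,
#: mean pure B cells, printed ratio pure B / normal PB, printed p).
B_CELL_TABLE = [
    ("CD268/BAFF-R", 940.25, 39402.54, 41.9, 0.001),
    ("CD83", 3282.52, 136406.91, 41.6, 0.033),
    ("CD79A", 3447.71, 119505.02, 34.7, 0.003),
    ("CD69", 5409.08, 181679.96, 33.6, 0.010),
    ("CD23/FCER2", 226.31, 7362.71, 32.5, 0.000),
    ("CD20", 2112.32, 66914.33, 31.7, 0.000),
    ("CD22", 824.90, 23927.76, 29.0, 0.002),
    ("CD19", 607.52, 17177.12, 28.3, 0.003),
    ("CD40/TNFRSF5", 541.65, 12031.25, 22.2, 0.000),
    ("CD200", 142.54, 3101.54, 21.8, 0.002),
    ("CD79B", 181.90, 3672.57, 20.2, 0.039),
    ("CD267/TACI", 167.24, 2259.35, 13.5, 0.004),
    ("CD180", 443.95, 3135.11, 7.1, 0.000),
    ("CD70/CD27L", 67.95, 476.84, 7.0, 0.007),
    ("CD32/FCGR2B", 1652.00, 6086.44, 3.7, 0.023),
    ("CD81", 4430.14, 16162.38, 3.6, 0.007),
    ("CD124/IL4R", 4546.82, 14900.94, 3.3, 0.000),
    ("CD24", 919.00, 2537.83, 2.8, 0.013),
    ("CD150", 288.06, 788.85, 2.7, 0.009),
    ("CD71/TFRC", 2572.30, 6537.91, 2.5, 0.030),
    ("CD74", 51335.01, 121141.05, 2.4, 0.000),
    ("CD38", 496.21, 1108.49, 2.2, 0.048),
    ("SOX11", 1.48, 128.09, 86.7, 0.011),
    ("PAX5", 267.77, 10912.48, 40.8, 0.000),
    ("EBF1", 9.86, 368.40, 37.4, 0.021),
    ("IRF4", 1106.86, 7649.87, 6.9, 0.024),
    ("JUN", 6269.40, 28921.65, 4.6, 0.000),
    ("BCL2", 1728.64, 7690.48, 4.4, 0.003),
    ("MYC", 1640.93, 5322.69, 3.2, 0.000),
    ("IGHD", 1071.88, 23185.99, 21.6, 0.000),
    ("IGHM", 10313.33, 198106.21, 19.2, 0.003),
    ("kappa", 11354.34, 70720.31, 6.2, 0.000),
    ("lambda", 17487.73, 64435.64, 3.7, 0.002),
]

#: The 44 CLL-preferential genes: (gene, mean across CLL samples, SD, CV).
CLL_44_TABLE = [
    ("ABCA6", 3783.3, 1942.9, 0.51),
    ("ADAM29", 482.5, 857.1, 1.78),
    ("AICDA", 69.9, 143.7, 2.06),
    ("BIK", 414.0, 426.0, 1.03),
    ("BMI1", 607.6, 202.4, 0.33),
    ("BUB1B", 152.4, 118.6, 0.78),
    ("CD200", 10131.9, 4443.1, 0.44),
    ("CD24", 9424.4, 7446.1, 0.79),
    ("CD269/BCMA", 1857.3, 1201.7, 0.65),
    ("CD27/TNFRSF7", 8532.6, 3512.4, 0.41),
    ("CD5", 4039.1, 1799.7, 0.45),
    ("CHIT1", 243.2, 162.8, 0.67),
    ("CLLU1", 5605.3, 12595.8, 2.25),
    ("CNR1/CB1", 357.5, 533.3, 1.49),
    ("COL9A2", 4955.2, 2398.9, 0.48),
    ("CTLA4", 12573.8, 11128.3, 0.89),
    ("CXCR3", 1609.2, 849.2, 0.53),
    ("DMD", 3625.7, 3727.6, 1.03),
    ("DNMBP", 4539.7, 2102.5, 0.46),
    ("FAIM3/Toso", 44146.0, 20379.2, 0.46),
    ("FCER2/CD23", 15988.5, 8133.0, 0.51),
    ("FGF2", 707.3, 693.6, 0.98),
    ("FGFR1", 554.3, 784.8, 1.42),
    ("FILIP1L", 2284.9, 1636.2, 0.72),
    ("FLT3", 406.5, 512.4, 1.26),
    ("FMOD", 17401.2, 12667.9, 0.73),
    ("GNRH1", 518.1, 232.4, 0.45),
    ("IGFBP4", 4858.1, 3366.4, 0.69),
    ("IGHG1-4", 13373.7, 11186.2, 0.84),
    ("IGSF3", 1129.0, 692.7, 0.61),
    ("IL2RA/IL2R", 2205.9, 1462.3, 0.66),
    ("kappa", 128933.8, 120715.3, 0.94),
    ("lambda", 142654.3, 170967.7, 1.20),
    ("LEF1", 7270.0, 2323.7, 0.32),
    ("LILRA4", 1799.4, 2540.1, 1.41),
    ("LPL", 641.1, 681.2, 1.06),
    ("RAPGEF3", 817.9, 457.3, 0.56),
    ("RASGRF1", 2960.0, 1436.7, 0.49),
    ("ROR1", 2376.8, 1107.6, 0.47),
    ("SELP/CD62", 1067.6, 708.9, 0.66),
    ("SEPT10", 667.5, 1305.7, 1.96),
    ("SFMBT1", 11065.5, 3547.0, 0.32),
    ("TTN", 7243.9, 3010.2, 0.42),
    ("WNT3", 5240.6, 5963.0, 1.14),
]

#: The 13 homogeneously expressed core genes (CV < 0.5 across CLL samples).
CORE_13_GENES = [
    "BMI1",
    "CD200",
    "CD27/TNFRSF7",
    "CD5",
    "COL9A2",
    "DNMBP",
    "FAIM3/Toso",
    "GNRH1",
    "LEF1",
    "RASGRF1",
    "ROR1",
    "SFMBT1",
    "TTN",
]

#: Surface-protein transcript quantification: (gene, mean normal PB,
#: mean pure B, mean CLL, printed ratio CLL/normal PB, printed ratio
#: CLL/pure B, printed p).
SURFACE_TABLE = [
    ("CD43", 1886.17, 17.20, 1253.7, 0.7, 72.9, 0.000),
    ("CD5", 1782.16, 250.99, 4039.1, 2.3, 16.1, 0.000),
    ("CD200", 142.54, 3101.54, 10131.9, 71.1, 3.3, 0.000),
    ("FCER2/CD23", 226.31, 7362.71, 15988.5, 70.6, 2.2, 0.000),
    ("CD79B", 181.90, 3672.57, 4665.0, 25.6, 1.3, 0.421),
    ("CD19", 607.52, 17177.12, 19164.6, 31.5, 1.1, 0.480),
    ("CD38", 496.21, 1108.49, 860.8, 1.7, 0.8, 0.760),
    ("CD79A", 3447.71, 119505.02, 64178.8, 18.6, 0.5, 0.016),
    ("CD22", 824.90, 23927.76, 8597.4, 10.4, 0.4, 0.004),
    ("MS4A1/CD20", 2112.32, 66914.33, 19628.9, 9.3, 0.3, 0.000),
]

#: IgVH mutation-status genes: (gene, mean mutated, SD, mean unmutated, SD,
#: printed ratio unmut/mut, printed p) for the unmutated-up block ...
MUT_UP_IN_UNMUTATED = [
    ("SEPT10", 10, 20, 1172, 1556, 121.0, 0.00866),
    ("AICDA", 1, 0, 121, 174, 106.5, 0.01562),
    ("LDOC1", 7, 14, 368, 233, 55.4, 0.00001),
    ("FARP1", 3, 4, 54, 83, 18.4, 0.02412),
    ("LPL", 91, 89, 1072, 620, 11.7, 0.00001),
    ("CNR1", 50, 71, 582, 616, 11.6, 0.00413),
    ("CD38", 137, 119, 1429, 2119, 10.4, 0.02506),
    ("DMD", 1421, 1718, 5379, 3931, 3.8, 0.00115),
    ("CEACAM1", 194, 165, 590, 540, 3.0, 0.02355),
    ("CRY1", 501, 571, 1380, 450, 2.8, 0.00007),
    ("ZAP70", 1341, 563, 3482, 1209, 2.6, 0.00001),
    ("ITGA4", 600, 318, 1529, 1079, 2.5, 0.00632),
    ("TCL1A", 15285, 14608, 38680, 18435, 2.5, 0.00048),
    ("CD26", 60, 63, 151, 105, 2.5, 0.00429),
    ("CHIT1", 135, 100, 325, 157, 2.4, 0.00045),
    ("IGHM", 145269, 131768, 333881, 138491, 2.3, 0.00494),
    ("EPB41L2", 136, 116, 305, 293, 2.2, 0.03937),
    ("VPREB3", 2530, 1420, 5505, 1873, 2.2, 0.00265),
    ("ABCA6", 2295, 1010, 4643, 1812, 2.0, 0.00351),
]

#: ... and (gene, mean mutated, SD, mean unmutated, SD, printed ratio
#: mut/unmut, printed p) for the mutated-up block.
MUT_UP_IN_MUTATED = [
    ("CTLA4", 18370, 13614, 8503, 6686, 2.2, 0.03908),
    ("RARA", 3398, 3056, 1185, 586, 2.9, 0.03850),
    ("LGMN", 114, 94, 38, 38, 3.0, 0.03412),
    ("CD150", 1665, 1117, 490, 326, 3.4, 0.00781),
    ("ADAM29", 1061, 1091, 66, 259, 16.0, 0.00803),
]

#: LDOC1-correlated genes: (gene, mean LDOC1-negative samples, mean
#: LDOC1-positive samples, printed ratio pos/neg, printed p); the last two
#: rows are printed with the inverse (neg/pos) ratio orientation.
LDOC1_TABLE_POS = [
    ("LDOC1", 1, 483, 483.4, 0.0000),
    ("SEPT10", 68, 1365, 20.2, 0.0138),
    ("LPL", 154, 1331, 8.6, 0.0000),
    ("CD26/DPP4", 45, 162, 3.6, 0.0023),
    ("EPB41L2", 132, 353, 2.7, 0.0280),
    ("CXCR6", 33, 89, 2.7, 0.0374),
    ("CRY1", 551, 1404, 2.5, 0.0001),
]
LDOC1_TABLE_NEG = [
    ("CD150", 1373, 462, 3.0, 0.0086),
    ("ADAM29", 832, 2, 451.3, 0.0096),
]

#: Polyclonal kappa/lambda reference interval parameters.
KL_REFERENCE_MEAN = 0.89
KL_REFERENCE_SD = 0.22

#: The nine normalization-gene candidates of the code set and the three
#: retained by geNorm stability ranking.
HK_CANDIDATES = ["ACTB", "TBP", "RPL19", "RPLP0", "G6PD", "ABCF1", "B2M", "TPT1", "RPS23"]
HK_SELECTED = ["RPL19", "RPLP0", "TPT1"]
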