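"""Published summary statistics for the Soay sheep body-size study.

The long-term study of the unmanaged Soay sheep population on St Kilda
genotyped 5805 sheep at 37 037 informative autosomal SNPs (Ovine SNP50
BeadChip, sheep genome v3.1) and partitioned phenotypic variance for five
adult body-size traits (foreleg, hindleg, metacarpal, weight, jaw) across
the 26 autosomes, with a mixed-model refit of the top leg-length SNPs.

These printed per-chromosome and per-SNP summaries are shipped as *inputs*
for downstream arithmetic (sums, ratios, regressions against chromosome
length) and for cross-checking the pipeline's own output layout.  Nothing
here is recomputed from raw data; the raw data live in a restricted-access
repository and are never required by this package.
"""

from __future__ import annotations

import io

import pandas as pd

N_SNPS_TOTAL = 37_037
N_SHEEP_GENOTYPED = 5_805

TRAITS = ("foreleg", "hindleg", "metacarpal", "weight", "jaw")

# Per-chromosome physical length (Mb), SNP count, and per-trait additive
# variance V_A, heritability share h2 and likelihood-ratio statistic from
# the chromosome-partition animal models.
_CHROM_CSV = """\
chrom,length_mb,n_snps,foreleg_va,foreleg_h2,foreleg_lrt,hindleg_va,hindleg_h2,hindleg_lrt,metacarpal_va,metacarpal_h2,metacarpal_lrt,weight_va,weight_h2,weight_lrt,jaw_va,jaw_h2,jaw_lrt
1,276,4138,1.012,0.023,2.093,2.076,0.044,2.722,0.024,0.001,0.002,0.447,0.048,3.833,2.086,0.103,12.829
2,249,3842,0.906,0.021,1.871,2.348,0.05,4.103,0.167,0.01,0.145,0.408,0.043,2.711,0.619,0.031,1.469
3,224,3540,0.085,0.002,0.022,0,0,0,0.642,0.04,1.81,0.061,0.006,0.091,0.639,0.032,1.845
4,119,1992,0,0,0,0.771,0.016,0.706,0.628,0.039,3.011,0.159,0.017,0.81,0.535,0.027,1.637
5,108,1702,1.38,0.032,4.312,0,0,0,1.38,0.085,9.787,0.067,0.007,0.132,0.196,0.01,0.371
6,117,1784,2.067,0.047,9.933,4.737,0.1,17.036,0.745,0.046,4.175,0.659,0.07,14.414,1.046,0.052,8.126
7,100,1653,1.056,0.024,3.492,2.316,0.049,6.328,0.988,0.062,7.753,0,0,0,1.036,0.051,4.014
8,91,1535,0.188,0.004,0.186,1.035,0.022,1.343,0.135,0.008,0.217,0.158,0.017,1.307,0.06,0.003,0.028
9,95,1546,0.884,0.02,2.993,2.007,0.043,4.458,0.061,0.004,0.037,0.426,0.046,8.111,1.771,0.087,8.978
10,86,1416,0,0,0,1.141,0.024,1.466,0,0,0,0.205,0.022,1.21,0.378,0.019,1.061
11,62,853,1.541,0.035,8.991,2.233,0.048,6.206,0.427,0.027,3.136,0,0,0,0.991,0.049,6.375
12,79,1218,0,0,0,0,0,0,0,0,0,0,0,0,0.327,0.016,1.032
13,83,1165,0.337,0.008,0.521,1.652,0.035,4.283,0.499,0.031,2.712,0.174,0.018,1.261,0.025,0.001,0.006
14,63,786,0,0,0,0,0,0,0.586,0.036,3.288,0,0,0,0.71,0.035,2.015
15,81,1204,0.37,0.008,0.646,0.345,0.007,0.248,0.516,0.032,3.396,0,0,0,0,0,0
16,72,1091,1.843,0.042,5.959,3.38,0.071,7.585,2.098,0.129,22.814,0.005,0.001,0.002,0,0,0
17,72,1032,0.203,0.005,0.193,0,0,0,0.042,0.003,0.032,0,0,0,0.871,0.043,6.915
18,69,1003,0,0,0,0,0,0,0.109,0.007,0.247,0,0,0,0,0,0
19,60,846,1.116,0.026,6.397,1.816,0.038,5.25,0.886,0.055,8.642,0.086,0.009,0.382,0,0,0
20,51,801,1.052,0.024,4.639,0.693,0.015,1.155,0,0,0,0.006,0.001,0.003,0.222,0.011,0.577
21,50,587,0,0,0,0,0,0,0,0,0,0,0,0,0.163,0.008,0.693
22,51,804,0.548,0.013,1.243,0,0,0,0,0,0,0.029,0.003,0.036,0,0,0
23,62,741,0,0,0,0,0,0,0,0,0,0.066,0.007,0.249,0.94,0.047,4.655
24,42,439,0.222,0.005,0.646,0.39,0.008,0.619,0.002,0,0,0.013,0.001,0.021,0.095,0.005,0.077
25,45,685,0,0,0,0,0,0,0.21,0.013,0.8,0.079,0.008,0.355,0.24,0.012,0.739
26,44,634,0.139,0.003,0.08,0.071,0.001,0.007,0.279,0.017,0.763,0.26,0.028,3.243,0.059,0.003,0.057
"""

# Whole-genome (all-autosome GRM) fits: genomic V_A and heritability.
_GENOME_CSV = """\
trait,va,h2
foreleg,11.107,0.255
hindleg,20.924,0.444
metacarpal,7.928,0.494
weight,2.926,0.312
jaw,10.69,0.53
"""

# Mixed-model refit of the leg-length QTL SNPs: additive effect of the
# minor allele (mm), its SE, Wald P, SNP variance 2pq*a^2, genomic V_A,
# genomic h2, and the minor allele frequency in the full genotyped sample.
_SNP_CSV = """\
trait,snp,chrom,effect,se,p,v_snp,v_a,h2,h2_snp,share_va,maf
foreleg,s63944.1,16,-4.147,0.583,2.93e-12,1.493,10.963,0.252,0.034,0.136,0.045
foreleg,s23172.1,16,-4.035,0.582,9.64e-12,1.419,10.963,0.252,0.033,0.129,0.046
foreleg,s22142.1,16,-3.979,0.578,1.31e-11,1.397,10.963,0.252,0.032,0.127,0.046
foreleg,s74894.1,19,-2.512,0.405,1.00e-09,1.149,10.963,0.252,0.026,0.105,0.101
hindleg,s23172.1,16,-5.939,0.774,5.72e-14,3.073,20.65,0.438,0.065,0.149,0.046
hindleg,s22142.1,16,-5.931,0.777,7.48e-14,3.054,20.65,0.438,0.065,0.148,0.045
hindleg,s63944.1,16,-5.839,0.769,9.98e-14,3.008,20.65,0.438,0.064,0.146,0.046
hindleg,s74894.1,19,-2.557,0.547,3.61e-06,1.19,20.65,0.438,0.025,0.058,0.101
metacarpal,s23172.1,16,-3.727,0.458,1.74e-15,1.21,7.81,0.487,0.075,0.155,0.046
metacarpal,s22142.1,16,-3.643,0.451,2.77e-15,1.171,7.81,0.487,0.073,0.15,0.046
metacarpal,s63944.1,16,-3.427,0.453,1.14e-13,1.02,7.81,0.487,0.064,0.131,0.045
metacarpal,s74894.1,19,-2.438,0.343,2.70e-12,1.082,7.81,0.487,0.067,0.139,0.101
"""


def chromosome_table() -> pd.DataFrame:
    """Per-chromosome lengths, SNP counts and partition estimates."""
    return pd.read_csv(io.StringIO(_CHROM_CSV))


def genome_table() -> pd.DataFrame:
    """Whole-genome genomic V_A and h2 per trait."""
    return pd.read_csv(io.StringIO(_GENOME_CSV))


def snp_effect_table() -> pd.DataFrame:
    """Refitted leg-length QTL SNP effects and variance decompositions."""
    return pd.read_csv(io.StringIO(_SNP_CSV))
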