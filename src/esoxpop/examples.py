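"""Bundled reference tables for a 12-fish Muskellunge broodstock cohort.

These small published summaries — per-sample sequencing statistics, the 47
sex-discordant SNPs in the anti-Müllerian hormone gene (*amh*) on
chromosome 8 of the Northern Pike assembly, breadth-of-coverage counts, and
the per-sample ROH/Froh table at the headline stringency — serve as worked
examples and ground truth for the package's summary operations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HOM_REF, HET

__all__ = [
    "iowa_seq_stats", "iowa_breadth_of_coverage", "amh_markers",
    "amh_genotype_matrix", "iowa_roh_summary",
]

# sample_id, sex, lake, sequenced reads, aligned %, high-quality %, depth (x)
_SEQ_STATS = [
    ("s1", "female", "Okoboji", 203_824_613, 86.34, 96.85, 16.23),
    ("s2", "female", "Okoboji", 315_700_163, 86.16, 96.78, 24.93),
    ("s3", "female", "Okoboji", 306_850_333, 86.04, 96.99, 24.34),
    ("s4", "male", "Okoboji", 99_981_043, 87.30, 96.22, 8.26),
    ("s5", "male", "Okoboji", 150_029_226, 86.38, 96.75, 12.12),
    ("s6", "male", "Okoboji", 538_733_400, 87.32, 96.44, 41.53),
    ("s7", "female", "Big Spirit", 438_773_328, 86.29, 95.68, 49.98),
    ("s8", "female", "Big Spirit", 538_733_400, 85.62, 95.29, 47.41),
    ("s9", "female", "Big Spirit", 510_088_829, 85.62, 94.77, 47.41),
    ("s10", "male", "Big Spirit", 157_555_467, 86.76, 96.56, 14.34),
    ("s11", "male", "Big Spirit", 140_430_988, 86.73, 96.41, 12.81),
    ("s12", "male", "Big Spirit", 177_235_006, 85.92, 96.56, 15.80),
]

# depth threshold (x), bases above threshold
_BREADTH = [
    (0, 735_465_012, 80.05),
    (10, 607_490_936, 66.12),
    (20, 539_961_789, 58.77),
    (50, 21_395_310, 2.33),
    (100, 7_981_231, 0.87),
    (1000, 260_029, 0.03),
]

# position on chromosome 8, female genotype (homozygous), male genotype (het)
_AMH = [
    (12874481, "GG", "CG"), (12874504, "TT", "CT"), (12874507, "CC", "TC"),
    (12874514, "CC", "TC"), (12874526, "CC", "AC"), (12874527, "TT", "AT"),
    (12874533, "CC", "TC"), (12874566, "AA", "TA"), (12874586, "GG", "AG"),
    (12874588, "CC", "TC"), (12874615, "AA", "CA"), (12874618, "AA", "GA"),
    (12874754, "CC", "GC"), (12874758, "CC", "TC"), (12874767, "GG", "AG"),
    (12874789, "TT", "CT"), (12874791, "AA", "GA"), (12874806, "AA", "CA"),
    (12874809, "TT", "CT"), (12874836, "GG", "AG"), (12874848, "GG", "CG"),
    (12874854, "CC", "TC"), (12874858, "CC", "TC"), (12874860, "GG", "AG"),
    (12874865, "TT", "CT"), (12874882, "AA", "TA"), (12874913, "TT", "AT"),
    (12874914, "GG", "AG"), (12874937, "CC", "TC"), (12875043, "AA", "GA"),
    (12875046, "CC", "AC"), (12875056, "CC", "TC"), (12875960, "AA", "GA"),
    (12875988, "TT", "GT"), (12875992, "TT", "GT"), (12876003, "CC", "TC"),
    (12876008, "CC", "TC"), (12876021, "TT", "AT"), (12876022, "CC", "TC"),
    (12876024, "CC", "AC"), (12876026, "TT", "AT"), (12876049, "CC", "AC"),
    (12876056, "TT", "AT"), (12876057, "CC", "TC"), (12876063, "CC", "GC"),
    (12876066, "AA", "TA"), (12876083, "TT", "GT"),
]

# sample, sex, lake, n ROH, total Kb, mean length Kb, Froh
# (headline stringency: 20-SNP windows, <= 3 heterozygotes)
_ROH_SUMMARY = [
    ("S1", "female", "Okoboji", 0, 0.00, 0.00, 0.00),
    ("S2", "female", "Okoboji", 2, 12_622.20, 6311.08, 0.01),
    ("S3", "female", "Okoboji", 3, 23_042.30, 7680.75, 0.03),
    ("S4", "male", "Okoboji", 2, 12_730.70, 6365.36, 0.01),
    ("S5", "male", "Okoboji", 2, 15_358.40, 7679.21, 0.02),
    ("S6", "male", "Okoboji", 4, 24_561.20, 6140.30, 0.03),
    ("S7", "female", "Big Spirit", 5, 36_351.40, 7270.28, 0.04),
    ("S8", "female", "Big Spirit", 5, 36_499.60, 7299.91, 0.04),
    ("S9", "female", "Big Spirit", 7, 50_042.80, 7148.97, 0.05),
    ("S10", "male", "Big Spirit", 4, 31_859.10, 7964.77, 0.03),
    ("S11", "male", "Big Spirit", 3, 21_129.30, 7043.11, 0.02),
    ("S12", "male", "Big Spirit", 5, 36_699.20, 7339.84, 0.04),
]


def iowa_seq_stats() -> pd.DataFrame:
    """Per-sample sequencing summary of the 12-fish broodstock cohort."""
    return pd.DataFrame(_SEQ_STATS, columns=[
        "sample_id", "sex", "lake", "sequenced_reads", "aligned_pct",
        "high_quality_pct", "mean_depth"])


def iowa_breadth_of_coverage() -> pd.DataFrame:
    """Cohort-average breadth of coverage at several depth thresholds."""
    return pd.DataFrame(_BREADTH, columns=["threshold", "bases", "pct"])


def amh_markers() -> pd.DataFrame:
    """The 47 sex-discordant *amh* SNPs (chromosome 8)."""
    return pd.DataFrame(_AMH, columns=["pos", "female_genotype", "male_genotype"])


def amh_genotype_matrix() -> GenotypeMatrix:
    """12-sample x 47-marker matrix rebuilt from the *amh* genotype table.

    Each female is homozygous for the shared female allele (taken as ref);
    each male is heterozygous for a male-specific allele (taken as alt).
    """
    sex = [s[1] for s in _SEQ_STATS]
    n_s, n_v = len(sex), len(_AMH)
    calls = np.zeros((n_s, n_v), dtype=np.int8)
    refs, alts, poss = [], [], []
    for j, (pos, f_gt, m_gt) in enumerate(_AMH):
        ref = f_gt[0]
        alt = next(a for a in m_gt if a != ref)
        refs.append(ref)
        alts.append(alt)
        poss.append(pos)
        for i, sx in enumerate(sex):
            calls[i, j] = HET if sx == "male" else HOM_REF
    return GenotypeMatrix(
        sample_ids=[s[0] for s in _SEQ_STATS],
        chrom=np.full(n_v, "8", dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        calls=calls,
        site_qual=np.full(n_v, 60.0),
        sample_sex=sex,
    )


def iowa_roh_summary() -> pd.DataFrame:
    """Per-sample ROH counts, total/mean lengths (Kb) and Froh."""
    return pd.DataFrame(_ROH_SUMMARY, columns=[
        "sample_id", "sex", "lake", "n_segments", "total_kb",
        "mean_length_kb", "froh"])
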