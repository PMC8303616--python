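"""Screen for perfectly sex-discordant markers and between-sex Fst.

A marker is sex-discordant when every non-missing call of one sex is
heterozygous while every non-missing call of the other sex is the same
homozygote — the pattern a hemizygous sex-determining haplotype (e.g. a
male-specific allele of a master sex gene such as *amh*) leaves in a
diploid SNP panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING
from .window_stats import WindowSpec, make_windows, snp_fst, window_mfst, overall_fst

__all__ = ["find_sex_discordant", "sex_fst"]


def _genotype_string(code: int, ref: str, alt: str) -> str:
    if code == HOM_REF:
        return ref + ref
    if code == HOM_ALT:
        return alt + alt
    if code == HET:
        return alt + ref  # carrier-specific allele first
    return ".."


def find_sex_discordant(gm: GenotypeMatrix, min_call_rate_per_sex: float = 1.0,
                        region: tuple[str, int, int] | None = None) -> pd.DataFrame:
    """Markers where the sexes have fixed, opposite het/hom genotypes.

    Requires ``sample_sex`` labels on the matrix and both sexes present.
    A marker qualifies when, among non-missing calls, one sex is entirely
    heterozygous and the other entirely a single shared homozygote, and each
    sex meets ``min_call_rate_per_sex`` (default 1.0: no missing calls
    tolerated).  ``region`` restricts the scan to ``(chrom, start, end)``
    1-based inclusive.
    """
    if gm.sample_sex is None:
        raise ValueError("matrix has no sample_sex labels")
    sex = np.array(gm.sample_sex)
    f_idx = np.flatnonzero(sex == "female")
    m_idx = np.flatnonzero(sex == "male")
    if len(f_idx) == 0 or len(m_idx) == 0:
        raise ValueError("both sexes must be represented")

    keep = np.ones(gm.n_variants, dtype=bool)
    if region is not None:
        c, a, b = region
        keep = (gm.chrom == c) & (gm.pos >= a) & (gm.pos <= b)

    rows = []
    for j in np.flatnonzero(keep):
        fc = gm.calls[f_idx, j]
        mc = gm.calls[m_idx, j]
        f_called = fc[fc != MISSING]
        m_called = mc[mc != MISSING]
        if len(f_called) < min_call_rate_per_sex * len(f_idx):
            continue
        if len(m_called) < min_call_rate_per_sex * len(m_idx):
            continue
        if len(f_called) == 0 or len(m_called) == 0:
            continue
        f_uniform = np.all(f_called == f_called[0])
        m_uniform = np.all(m_called == m_called[0])
        if not (f_uniform and m_uniform):
            continue
        f_gt, m_gt = int(f_called[0]), int(m_called[0])
        male_het = m_gt == HET and f_gt in (HOM_REF, HOM_ALT)
        female_het = f_gt == HET and m_gt in (HOM_REF, HOM_ALT)
        if not (male_het ^ female_het):
            continue
        rows.append({
            "chrom": gm.chrom[j],
            "pos": int(gm.pos[j]),
            "female_genotype": _genotype_string(f_gt, gm.ref[j], gm.alt[j]),
            "male_genotype": _genotype_string(m_gt, gm.ref[j], gm.alt[j]),
            "pattern": ("all-male-het/all-female-hom" if male_het
                        else "all-female-het/all-male-hom"),
        })
    return pd.DataFrame(rows, columns=["chrom", "pos", "female_genotype",
                                       "male_genotype", "pattern"])


def sex_fst(gm: GenotypeMatrix, chrom_lengths: dict[str, int] | None = None,
            spec: WindowSpec = WindowSpec()) -> tuple[float, pd.DataFrame]:
    """Overall Fst between sexes plus per-window mFst.

    Overall Fst is the genome-wide mean of per-SNP Weir–Cockerham
    estimates, consistent with the windowed-mean convention.  Chromosome
    lengths default to the last SNP position per chromosome.
    """
    if gm.sample_sex is None:
        raise ValueError("matrix has no sample_sex labels")
    females = [s for s, x in zip(gm.sample_ids, gm.sample_sex) if x == "female"]
    males = [s for s, x in zip(gm.sample_ids, gm.sample_sex) if x == "male"]
    if len(females) < 2 or len(males) < 2:
        raise ValueError("need >= 2 samples of each sex")
    if chrom_lengths is None:
        chrom_lengths = {c: int(gm.pos[sl].max()) for c, sl in gm.chrom_slices()}
    fst = snp_fst(gm, females, males)
    windows = make_windows(chrom_lengths, spec)
    mfst = window_mfst(gm, fst, windows, spec.min_snps_per_window)
    return overall_fst(fst), mfst
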