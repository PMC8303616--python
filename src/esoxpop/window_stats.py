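"""Sliding-window pooled heterozygosity (Hp/ZHp) and mean Fst (mFst).

Pooled heterozygosity over a window is

    Hp = 2 * S_maj * S_min / (S_maj + S_min)^2

where S_maj and S_min are the sums over all SNPs in the window of the
major- and minor-allele counts (major = the more frequent of ref/alt among
non-missing calls at that SNP).  Hp lies in [0, 0.5]; windows are
standardized genome-wide to ZHp = (Hp - mean) / sd and |ZHp| > 3 flags an
outlier window.

Per-SNP Fst uses the Weir & Cockerham (1984) two-population
variance-component estimator (theta-hat = a / (a + b + c)); mFst is the
arithmetic mean of per-SNP estimates inside each window.  Negative per-SNP
estimates are kept as computed.  Hudson's estimator is available as an
alternative for sensitivity analysis.

Windows default to 0.5 Mb with a 0.25 Mb step (50 % overlap), anchored at
offset 0 of each chromosome; internally windows are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING

__all__ = [
    "WindowSpec", "HpNormalization", "make_windows", "pooled_het",
    "normalize_hp", "snp_fst", "window_mfst", "overall_fst", "genome_fst",
    "weir_cockerham_components", "weir_cockerham_fst", "hudson_fst",
    "NormalizationError",
]

ZHP_OUTLIER_SD = 3.0
MFST_HIGH = 0.9


class NormalizationError(ValueError):
    """All windows have identical Hp: the Z-score is undefined."""


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.  size=2*step gives 50% overlap."""

    size: int = 500_000
    step: int = 250_000
    min_snps_per_window: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")


@dataclass(frozen=True)
class HpNormalization:
    """Genome-wide moments used for the ZHp transform (sample sd, ddof=1)."""

    mu_hp: float
    sigma_hp: float
    n_windows: int


def make_windows(chrom_lengths: Mapping[str, int], spec: WindowSpec) -> pd.DataFrame:
    """Enumerate sliding windows per chromosome.

    Windows start at 0-based offsets 0, step, 2*step, ... and are half-open
    ``[start, start+size)`` clipped at the chromosome end; a window exists
    iff its start is inside the chromosome.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + spec.size, length)))
            start += spec.step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _window_slices(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Index ranges of SNPs (1-based pos) falling in 0-based half-open windows."""
    pos0 = pos - 1
    return (np.searchsorted(pos0, starts, side="left"),
            np.searchsorted(pos0, ends, side="left"))


def _per_window_sums(gm: GenotypeMatrix, windows: pd.DataFrame,
                     values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-SNP ``values`` (NaN-aware, columns) into each window.

    Returns (n_snps, sums) aligned with ``windows``; ``values`` has shape
    (n_quantities, n_variants).
    """
    n_w = len(windows)
    n_q = values.shape[0]
    counts = np.zeros(n_w, dtype=np.int64)
    sums = np.zeros((n_q, n_w))
    by_chrom = {c: sl for c, sl in gm.chrom_slices()}
    for chrom, grp in windows.groupby("chrom", sort=False):
        sl = by_chrom.get(chrom)
        if sl is None:
            continue
        pos = gm.pos[sl]
        vals = values[:, sl]
        valid = ~np.isnan(vals)
        cum = np.concatenate([np.zeros((n_q, 1)),
                              np.cumsum(np.where(valid, vals, 0.0), axis=1)], axis=1)
        cum_n = np.concatenate([np.zeros((n_q, 1), dtype=np.int64),
                                np.cumsum(valid, axis=1)], axis=1)
        lo, hi = _window_slices(pos, grp["start"].to_numpy(), grp["end"].to_numpy())
        idx = grp.index.to_numpy()
        counts[idx] = (cum_n[0, hi] - cum_n[0, lo]).astype(np.int64)
        sums[:, idx] = cum[:, hi] - cum[:, lo]
    return counts, sums


def pooled_het(gm: GenotypeMatrix, windows: pd.DataFrame,
               min_snps_per_window: int = 10) -> pd.DataFrame:
    """Per-window major/minor allele-count sums and pooled heterozygosity.

    Windows with fewer than ``min_snps_per_window`` SNPs (or zero total
    allele count) get ``hp = NaN``.  The returned frame has columns
    chrom, start, end, n_snps, sum_maj, sum_min, hp.
    """
    ref_c, alt_c = gm.allele_counts()
    maj = np.maximum(ref_c, alt_c).astype(float)  # ties break toward ref
    mnr = np.minimum(ref_c, alt_c).astype(float)
    n_snps, sums = _per_window_sums(gm, windows, np.vstack([maj, mnr]))
    sum_maj, sum_min = sums
    tot = sum_maj + sum_min
    with np.errstate(invalid="ignore", divide="ignore"):
        hp = np.where(tot > 0, 2.0 * sum_maj * sum_min / tot**2, np.nan)
    hp = np.where(n_snps >= min_snps_per_window, hp, np.nan)
    out = windows.copy()
    out["n_snps"] = n_snps
    out["sum_maj"] = sum_maj.astype(np.int64)
    out["sum_min"] = sum_min.astype(np.int64)
    out["hp"] = hp
    return out


def normalize_hp(stats: pd.DataFrame) -> tuple[pd.DataFrame, HpNormalization]:
    """Standardize window Hp genome-wide: zhp = (hp - mu) / sigma.

    Moments use every window with a defined hp and the sample (ddof=1)
    standard deviation.  Adds ``zhp`` and ``outlier`` (|zhp| > 3) columns.
    """
    hp = stats["hp"].to_numpy(float)
    defined = ~np.isnan(hp)
    if defined.sum() < 2:
        raise NormalizationError("need >= 2 windows with defined hp")
    mu = float(np.mean(hp[defined]))
    sigma = float(np.std(hp[defined], ddof=1))
    if sigma == 0.0 or np.all(hp[defined] == hp[defined][0]):
        raise NormalizationError("all window hp values identical; sigma = 0")
    out = stats.copy()
    out["zhp"] = (hp - mu) / sigma
    out["outlier"] = np.abs(out["zhp"]) > ZHP_OUTLIER_SD
    return out, HpNormalization(mu_hp=mu, sigma_hp=sigma, n_windows=int(defined.sum()))


# ----------------------------------------------------------------------
# Fst
# ----------------------------------------------------------------------

def _group_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_called, alt_freq, het_fraction) for one group's calls."""
    n_ref = (calls == HOM_REF).sum(axis=0)
    n_het = (calls == HET).sum(axis=0)
    n_alt = (calls == HOM_ALT).sum(axis=0)
    n = n_ref + n_het + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_alt + n_het) / (2 * n)
        h = n_het / n
    return n, p, h


def weir_cockerham_components(n1, p1, h1, n2, p2, h2):
    """Vectorized Weir & Cockerham (1984) variance components (a, b, c).

    Arguments are per-site diploid sample sizes, alt-allele frequencies and
    observed heterozygote fractions of the two populations.  ``a`` is the
    among-population component, ``b`` among individuals within populations,
    ``c`` within individuals; theta-hat = a / (a + b + c).
    """
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    h1 = np.asarray(h1, float); h2 = np.asarray(h2, float)
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    return a, b, c


def weir_cockerham_fst(n1, p1, h1, n2, p2, h2):
    """Per-site Weir & Cockerham theta-hat = a/(a+b+c).

    NaN where the total variance is zero (site monomorphic in both groups).
    The per-site ratio is noisy and, averaged over loci, biased downward;
    for a single genome-wide value prefer :func:`genome_fst`.
    """
    a, b, c = weir_cockerham_components(n1, p1, h1, n2, p2, h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        return np.where(denom != 0.0, a / np.where(denom != 0.0, denom, 1.0), np.nan)


def hudson_fst(n1, p1, n2, p2):
    """Hudson-style estimator from allele frequencies (no het correction)."""
    n1 = np.asarray(n1, float); n2 = np.asarray(n2, float)
    p1 = np.asarray(p1, float); p2 = np.asarray(p2, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return np.where(den != 0.0, num / np.where(den != 0.0, den, 1.0), np.nan)


def snp_fst(gm: GenotypeMatrix, group_a: Sequence[str], group_b: Sequence[str],
            estimator: str = "wc", min_group_n: int = 2) -> pd.DataFrame:
    """Per-SNP Fst between two sample groups.

    Sites where either group has fewer than ``min_group_n`` non-missing
    diploid calls are reported as NaN (and tallied in the ``skipped``
    attribute of the result frame).  Negative estimates are not clipped.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ia = [gm.sample_index(s) for s in group_a]
    ib = [gm.sample_index(s) for s in group_b]
    n1, p1, h1 = _group_counts(gm.calls[ia, :])
    n2, p2, h2 = _group_counts(gm.calls[ib, :])
    ok = (n1 >= min_group_n) & (n2 >= min_group_n)
    if estimator == "wc":
        fst = weir_cockerham_fst(n1, p1, h1, n2, p2, h2)
    elif estimator == "hudson":
        fst = hudson_fst(n1, p1, n2, p2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    fst = np.where(ok, fst, np.nan)
    out = pd.DataFrame({"chrom": gm.chrom, "pos": gm.pos, "fst": fst})
    out.attrs["skipped_low_n"] = int((~ok).sum())
    return out


def window_mfst(gm: GenotypeMatrix, fst: pd.DataFrame, windows: pd.DataFrame,
                min_snps_per_window: int = 10) -> pd.DataFrame:
    """Arithmetic mean of per-SNP Fst inside each window.

    ``fst`` must be positioned on the same coordinate system as ``gm``
    (it is the output of :func:`snp_fst` on the same matrix).  Windows with
    fewer than ``min_snps_per_window`` defined per-SNP values get NaN;
    windows with mfst > 0.9 are flagged ``high``.
    """
    vals = fst["fst"].to_numpy(float)[None, :]
    n_snps, sums = _per_window_sums(gm, windows, vals)
    with np.errstate(invalid="ignore"):
        mfst = np.where(n_snps > 0, sums[0] / np.maximum(n_snps, 1), np.nan)
    mfst = np.where(n_snps >= min_snps_per_window, mfst, np.nan)
    out = windows.copy()
    out["n_snps"] = n_snps
    out["mfst"] = mfst
    out["high"] = np.nan_to_num(mfst, nan=-np.inf) > MFST_HIGH
    return out


def overall_fst(fst: pd.DataFrame) -> float:
    """Genome-wide mean of per-SNP Fst (consistent with the mFst convention)."""
    vals = fst["fst"].to_numpy(float)
    if np.all(np.isnan(vals)):
        raise ValueError("no defined per-SNP Fst values")
    return float(np.nanmean(vals))


def genome_fst(gm: GenotypeMatrix, group_a: Sequence[str], group_b: Sequence[str],
               min_group_n: int = 2) -> float:
    """Multi-locus Weir–Cockerham Fst: ratio of summed variance components.

    sum(a) / sum(a+b+c) over all usable sites — the standard genome-wide
    estimator (the "weighted" Fst of common toolkits).  Unlike the mean of
    per-SNP ratios it is a consistent estimator of the differentiation
    parameter, so it is the right quantity for a single overall value.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ia = [gm.sample_index(s) for s in group_a]
    ib = [gm.sample_index(s) for s in group_b]
    n1, p1, h1 = _group_counts(gm.calls[ia, :])
    n2, p2, h2 = _group_counts(gm.calls[ib, :])
    ok = (n1 >= min_group_n) & (n2 >= min_group_n)
    a, b, c = weir_cockerham_components(n1, p1, h1, n2, p2, h2)
    tot = (a + b + c)[ok]
    if not np.any(tot != 0):
        raise ValueError("no variable sites; genome-wide Fst undefined")
    return float(a[ok].sum() / tot.sum())
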