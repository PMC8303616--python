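"""Genotype PCA for population-structure visualization.

Genotypes are coded as alternate-allele dosage (0/1/2), missing calls are
mean-imputed per site, sites are mean-centered (optionally Patterson-scaled
by sqrt(p(1-p))), and the sample coordinates come from an SVD of the
resulting matrix.  Variance-explained fractions are relative to the total
variance of the centered matrix, so they sum to at most 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MISSING

__all__ = ["PcaResult", "genotype_pca"]


@dataclass
class PcaResult:
    coords: pd.DataFrame          # samples x PC1..PCk
    variance_explained: np.ndarray  # length k, non-increasing, sums to <= 1

    def __post_init__(self) -> None:
        v = self.variance_explained
        assert np.all(v >= -1e-12) and v.sum() <= 1 + 1e-9
        assert np.all(np.diff(v) <= 1e-12)


def genotype_pca(gm: GenotypeMatrix, k: int = 2, scaling: str = "center") -> PcaResult:
    """Principal components of the sample-by-site dosage matrix.

    Parameters
    ----------
    k
        Number of components; must be < n_samples.
    scaling
        ``"center"`` (mean-center only) or ``"patterson"`` (additionally
        divide each site by sqrt(p(1-p)), p the mean dosage / 2).

    Raises
    ------
    ValueError
        If ``k >= n_samples``, fewer than 2 polymorphic sites remain after
        imputation, or the matrix has zero total variance (all samples
        identical).
    """
    if k >= gm.n_samples:
        raise ValueError(f"k={k} must be < n_samples={gm.n_samples}")
    dosage = gm.calls.astype(float)
    dosage[gm.calls == MISSING] = np.nan
    site_mean = np.nanmean(dosage, axis=0)
    site_mean = np.nan_to_num(site_mean)  # all-missing sites -> 0
    inds = np.where(np.isnan(dosage))
    dosage[inds] = site_mean[inds[1]]

    var = dosage.var(axis=0)
    poly = var > 0
    if poly.sum() < 2:
        raise ValueError("need >= 2 polymorphic sites after imputation")
    x = dosage[:, poly] - site_mean[poly]
    if scaling == "patterson":
        p = site_mean[poly] / 2.0
        x = x / np.sqrt(p * (1 - p))
    elif scaling != "center":
        raise ValueError(f"unknown scaling {scaling!r}")

    total_var = float((x**2).sum())
    if total_var == 0.0:
        raise ValueError("zero total variance: all samples identical")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    # deterministic sign: largest-magnitude coordinate positive per component
    for c in range(k):
        i = np.argmax(np.abs(coords[:, c]))
        if coords[i, c] < 0:
            coords[:, c] = -coords[:, c]
    frac = (s[:k] ** 2) / total_var
    return PcaResult(
        coords=pd.DataFrame(coords, index=gm.sample_ids,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        variance_explained=frac,
    )
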