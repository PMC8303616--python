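"""Runs of homozygosity via a SNP-scanning-window algorithm, and Froh.

The detector mirrors the classic scanning-window heuristic: windows of
``window_snps`` consecutive SNPs slide one SNP at a time along each
chromosome; a window is homozygous-compatible when it contains at most
``max_het_per_window`` heterozygous calls (and at most
``max_missing_per_window`` missing calls).  Each SNP is scored with the
fraction of windows covering it that are compatible; SNPs at or above
``hit_fraction`` are run-eligible.  Maximal stretches of consecutive
eligible SNPs become candidate segments, are split wherever adjacent SNPs
are further apart than ``max_gap``, and are reported when they span at least
``min_length`` bp and contain at least ``min_snps_per_segment`` SNPs.
Segment coordinates are the outermost SNP positions, so length is SNP-span.

Froh is the summed length of reported segments divided by an explicit
denominator (the number of base pairs of genome assessed) — the denominator
is deliberately a required argument, never guessed.

The stringency grid pairs window sizes {5, 10, 20} with heterozygote
allowances {1, 2, 3}; the (20 SNPs, 3 het) cell is the headline setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HET, MISSING

__all__ = ["ROHConfig", "detect_roh", "froh", "froh_from_totals",
           "stringency_sweep", "default_grid", "HEADLINE_CONFIG"]

WINDOW_SNPS_GRID = (5, 10, 20)
MAX_HET_GRID = (1, 2, 3)


@dataclass(frozen=True)
class ROHConfig:
    """Stringency parameters for ROH calling.

    ``min_length`` (1 Mb) and ``max_gap`` (500 kb) are fixed study-wide;
    ``window_snps`` and ``max_het_per_window`` form the stringency grid.
    ``hit_fraction``, ``max_missing_per_window`` and ``min_snps_per_segment``
    complete the scanning-window rule set and are always recorded in output.
    """

    window_snps: int = 20
    max_het_per_window: int = 3
    min_length: int = 1_000_000
    max_gap: int = 500_000
    hit_fraction: float = 0.05
    max_missing_per_window: int = 5
    min_snps_per_segment: int = 25

    def __post_init__(self) -> None:
        if not (self.window_snps > self.max_het_per_window >= 0):
            raise ValueError("require window_snps > max_het_per_window >= 0")
        if self.min_length <= 0 or self.max_gap <= 0:
            raise ValueError("min_length and max_gap must be positive")
        if not (0.0 < self.hit_fraction <= 1.0):
            raise ValueError("hit_fraction must be in (0,1]")

    def label(self) -> str:
        return f"w{self.window_snps}_h{self.max_het_per_window}"


HEADLINE_CONFIG = ROHConfig(window_snps=20, max_het_per_window=3)


def default_grid() -> list[ROHConfig]:
    """The 3x3 stringency grid (window sizes x heterozygote allowances)."""
    return [ROHConfig(window_snps=w, max_het_per_window=h)
            for w in WINDOW_SNPS_GRID for h in MAX_HET_GRID]


_SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "length", "n_snps", "n_het"]


def detect_roh(gm: GenotypeMatrix, sample: str, cfg: ROHConfig = HEADLINE_CONFIG
               ) -> pd.DataFrame:
    """Call ROH segments for one sample.

    Returns a frame with columns sample_id, chrom, start, end, length,
    n_snps, n_het, sorted by position; segments never overlap.
    """
    s_idx = gm.sample_index(sample)
    rows: list[tuple] = []
    for chrom, sl in gm.chrom_slices():
        pos = gm.pos[sl]
        calls = gm.calls[s_idx, sl]
        n = len(pos)
        w = cfg.window_snps
        if n < w:
            warnings.warn(
                f"{chrom}: {n} SNPs < window size {w}; no ROH called there",
                stacklevel=2,
            )
            continue
        het = (calls == HET).astype(np.int64)
        mis = (calls == MISSING).astype(np.int64)
        cum_het = np.concatenate([[0], np.cumsum(het)])
        cum_mis = np.concatenate([[0], np.cumsum(mis)])
        # window i covers SNPs [i, i+w)
        n_win = n - w + 1
        win_het = cum_het[w:] - cum_het[:-w]
        win_mis = cum_mis[w:] - cum_mis[:-w]
        compat = ((win_het <= cfg.max_het_per_window)
                  & (win_mis <= cfg.max_missing_per_window)).astype(np.int64)
        cum_compat = np.concatenate([[0], np.cumsum(compat)])
        j = np.arange(n)
        lo = np.maximum(0, j - w + 1)
        hi = np.minimum(j, n_win - 1)
        n_cover = hi - lo + 1
        frac = (cum_compat[hi + 1] - cum_compat[lo]) / n_cover
        eligible = frac >= cfg.hit_fraction

        # maximal runs of eligible SNPs, split at gaps > max_gap
        k = 0
        while k < n:
            if not eligible[k]:
                k += 1
                continue
            run_end = k
            while run_end + 1 < n and eligible[run_end + 1]:
                run_end += 1
            # split on spacing
            seg_start = k
            for m in range(k, run_end + 1):
                is_last = m == run_end
                gap_after = (pos[m + 1] - pos[m]) if m + 1 <= run_end else 0
                if is_last or gap_after > cfg.max_gap:
                    a, b = seg_start, m
                    span = int(pos[b] - pos[a])
                    n_snps = b - a + 1
                    if span >= cfg.min_length and n_snps >= cfg.min_snps_per_segment:
                        rows.append((sample, chrom, int(pos[a]), int(pos[b]),
                                     span, n_snps, int(het[a:b + 1].sum())))
                    seg_start = m + 1
            k = run_end + 1
    return pd.DataFrame(rows, columns=_SEG_COLUMNS).astype(
        {c: np.int64 for c in ("start", "end", "length", "n_snps", "n_het")})


def detect_roh_all(gm: GenotypeMatrix, cfg: ROHConfig = HEADLINE_CONFIG) -> pd.DataFrame:
    """Call ROH for every sample; concatenation of per-sample results."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parts = [detect_roh(gm, s, cfg) for s in gm.sample_ids]
    out = (pd.concat(parts, ignore_index=True) if parts
           else pd.DataFrame(columns=_SEG_COLUMNS))
    return out.astype({c: np.int64
                       for c in ("start", "end", "length", "n_snps", "n_het")})


def froh(segments: pd.DataFrame, denominator: int,
         sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-sample inbreeding coefficient from ROH segments.

    froh = total segment length / denominator, where ``denominator`` is the
    genome length assessed (bp).  ``sample_ids`` forces rows (with zeros) for
    samples that have no segments.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    ids = sample_ids if sample_ids is not None else sorted(
        segments["sample_id"].unique().tolist()) if len(segments) else []
    rows = []
    for s in ids:
        seg = segments[segments["sample_id"] == s] if len(segments) else segments
        n = int(len(seg))
        total = int(seg["length"].sum()) if n else 0
        rows.append({
            "sample_id": s,
            "n_segments": n,
            "total_length": total,
            "mean_length": total / n if n else 0.0,
            "denominator": denominator,
            "froh": total / denominator,
        })
    return pd.DataFrame(rows, columns=["sample_id", "n_segments", "total_length",
                                       "mean_length", "denominator", "froh"])


def froh_from_totals(sample_id: str, n_segments: int, total_length: float,
                     denominator: float) -> dict:
    """Froh summary from already-aggregated per-sample ROH totals (bp)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return {
        "sample_id": sample_id,
        "n_segments": int(n_segments),
        "total_length": float(total_length),
        "mean_length": total_length / n_segments if n_segments else 0.0,
        "denominator": float(denominator),
        "froh": total_length / denominator,
    }


def stringency_sweep(gm: GenotypeMatrix, denominator: int,
                     grid: list[ROHConfig] | None = None) -> pd.DataFrame:
    """Froh table across the stringency grid.

    One row per (config, sample); the (20, 3) cell is marked ``headline``.
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("grid must be non-empty")
    parts = []
    for cfg in grid:
        segs = detect_roh_all(gm, cfg)
        tab = froh(segs, denominator, sample_ids=gm.sample_ids)
        tab.insert(0, "window_snps", cfg.window_snps)
        tab.insert(1, "max_het_per_window", cfg.max_het_per_window)
        tab.insert(2, "headline", cfg.window_snps == 20 and cfg.max_het_per_window == 3)
        parts.append(tab)
    return pd.concat(parts, ignore_index=True)
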