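"""Per-sample sequencing summaries and depth-of-coverage tracks.

Inputs are tabular (per-sample read/alignment statistics, per-base or
per-window depth); this module never touches alignments itself.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cohort_summary", "breadth_of_coverage", "depth_per_window",
           "SEQ_STAT_COLUMNS"]

# canonical column names of a per-sample sequencing summary table
SEQ_STAT_COLUMNS = ["sample_id", "sequenced_reads", "aligned_pct",
                    "high_quality_pct", "mean_depth"]


def cohort_summary(stats: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample standard deviation of each numeric column, at 2 dp.

    Expects one row per sample.  Percent columns must already be on the
    0-100 scale.
    """
    if len(stats) < 2:
        raise ValueError("cohort summary needs at least 2 samples")
    num = stats.select_dtypes(include=[np.number])
    out = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
    # builtin round() is correctly rounded for doubles; np.round's scale-by-100
    # intermediate can flip ties the wrong way
    out = out.map(lambda v: round(float(v), 2))
    out.index.name = "field"
    return out


def breadth_of_coverage(depths: np.ndarray, thresholds: list[float],
                        widths: np.ndarray | None = None) -> pd.DataFrame:
    """Bases covered at each depth threshold.

    A threshold of 0 is read as "covered at all" and counted strictly
    (depth > 0); every other threshold counts depth >= t, i.e. "at least
    t-fold".  ``widths`` turns a per-window mean-depth vector into base
    counts; omitted, each entry is one base.
    """
    depths = np.asarray(depths, dtype=float)
    if any(t < 0 for t in thresholds):
        raise ValueError("negative depth threshold")
    if sorted(thresholds) != list(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    w = np.ones_like(depths) if widths is None else np.asarray(widths, dtype=float)
    total = w.sum()
    rows = []
    for t in thresholds:
        sel = depths > t if t == 0 else depths >= t
        bases = float(w[sel].sum())
        rows.append({"threshold": t, "bases": bases,
                     "fraction": bases / total if total else 0.0})
    return pd.DataFrame(rows)


def depth_per_window(depth: np.ndarray, window_size: int,
                     chrom: str = "chr1") -> pd.DataFrame:
    """Mean depth in non-overlapping tiling windows of a per-base track.

    The trailing partial window is reported with its true width.  Returns
    chrom, start (0-based), end, width, mean_depth.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    depth = np.asarray(depth, dtype=float)
    n = len(depth)
    rows = []
    for start in range(0, n, window_size):
        end = min(start + window_size, n)
        rows.append({
            "chrom": chrom, "start": start, "end": end, "width": end - start,
            "mean_depth": float(depth[start:end].mean()),
        })
    return pd.DataFrame(rows)
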