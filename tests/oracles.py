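"""Independent brute-force oracles used to cross-check the implementations.

Deliberately written with explicit Python loops and scalar arithmetic so
they share no code path with the vectorized package routines.
"""

from esoxpop.genotypes import HET, MISSING


def brute_force_roh(pos, calls, cfg):
    """Exhaustively apply the scanning-window ROH rules to one chromosome.

    Returns a list of ``(start, end, n_snps)`` tuples.
    """
    n = len(pos)
    w = cfg.window_snps
    if n < w:
        return []
    compat = []
    for i in range(n - w + 1):
        window = calls[i:i + w]
        het = sum(1 for c in window if c == HET)
        mis = sum(1 for c in window if c == MISSING)
        compat.append(het <= cfg.max_het_per_window
                      and mis <= cfg.max_missing_per_window)
    eligible = []
    for j in range(n):
        covering = [compat[i] for i in range(max(0, j - w + 1),
                                             min(j, n - w) + 1)]
        eligible.append(sum(covering) / len(covering) >= cfg.hit_fraction)
    segs = []
    j = 0
    while j < n:
        if not eligible[j]:
            j += 1
            continue
        k = j
        while k + 1 < n and eligible[k + 1]:
            k += 1
        start = j
        for m in range(j, k + 1):
            if m == k or pos[m + 1] - pos[m] > cfg.max_gap:
                span = int(pos[m] - pos[start])
                n_snps = m - start + 1
                if span >= cfg.min_length and n_snps >= cfg.min_snps_per_segment:
                    segs.append((int(pos[start]), int(pos[m]), n_snps))
                start = m + 1
        j = k + 1
    return segs


def scalar_weir_cockerham(n1, p1, h1, n2, p2, h2):
    """Direct scalar evaluation of the two-population W&C (1984) theta-hat."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a / (a + b + c)
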