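"""Two-population diploid genotype simulator.

Allele frequencies follow the Balding–Nichols model: each site has an
ancestral frequency p0 drawn uniformly, and each population draws its own
frequency from Beta(p0*(1-F)/F, (1-p0)*(1-F)/F), which has mean p0 and
variance p0*(1-p0)*F, so F is the expected fixation index between the
populations.  Genotypes are binomial draws per diploid; no linkage or
recombination map is modelled — long homozygous tracts and the sex-linked
locus are planted explicitly and recorded in a truth table.

The planted sex locus mimics a master sex-determining gene with a
male-specific haplotype: every male is heterozygous and every female is
homozygous for the reference allele at each of its markers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING

__all__ = ["SimConfig", "TruthTable", "simulate", "wgs_cohort_config",
           "combined_cohort_config"]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic two-population study.

    Defaults emulate a small, densely genotyped broodstock cohort of 12
    diploids (6 per sex, 6 per population) with strong differentiation
    between populations (F = 0.24) and WGS-like depth (mean 26x).

    ``roh_plants`` entries are ``(sample_index, chrom, start_bp, end_bp)``
    with 1-based inclusive coordinates; inside a tract every call of that
    sample is forced homozygous for the site's major allele in the sample's
    population.  ``sex_locus`` is ``(chrom, start_bp, end_bp, n_markers)``.

    ``plant_low_qual_sites`` / ``plant_low_call_rate_sites`` /
    ``plant_monomorphic_sites`` force exact numbers of background sites to
    fail the corresponding retention filter, so filter reports can be checked
    against planted truth.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_snps: int = 2_000
    pop_sizes: tuple[int, int] = (6, 6)
    fst_param: float = 0.24
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    depth_mean: float = 26.0
    depth_dispersion: float = 8.0
    qual_range: tuple[float, float] = (30.0, 60.0)
    roh_plants: tuple[tuple[int, str, int, int], ...] = ()
    sex_locus: tuple[str, int, int, int] | None = None
    sample_sex: tuple[str, ...] | None = None
    plant_low_qual_sites: int = 0
    plant_low_call_rate_sites: int = 0
    plant_monomorphic_sites: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst_param < 1.0):
            raise ValueError("fst_param must be in [0,1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0,1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie within (0,1)")
        if self.n_snps > self.n_chrom * self.chrom_length:
            raise ValueError("n_snps exceeds available positions")
        seen: dict[int, list[tuple[str, int, int]]] = {}
        for s, c, a, b in self.roh_plants:
            if not (1 <= a < b <= self.chrom_length):
                raise ValueError(f"planted tract ({c}:{a}-{b}) outside chromosome")
            for c2, a2, b2 in seen.get(s, []):
                if c2 == c and a <= b2 and a2 <= b:
                    raise ValueError("planted ROH tracts overlap within a sample")
            seen.setdefault(s, []).append((c, a, b))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class TruthTable:
    """Ground truth recorded alongside a simulated dataset.

    ``sites`` holds per-site ancestral (``p0``) and per-population
    (``p_pop1``, ``p_pop2``) alternate-allele frequencies plus planted-feature
    flags; coordinates in ``roh_plants`` and ``sex_markers`` are 1-based.
    """

    sites: pd.DataFrame
    roh_plants: pd.DataFrame
    sex_markers: pd.DataFrame
    config_digest: str
    planted_filter_counts: dict[str, int] = field(default_factory=dict)


def wgs_cohort_config(seed: int = 0) -> SimConfig:
    """Small dense cohort: 12 diploids, 6 per sex, WGS-like density/depth.

    Includes long planted homozygous tracts in a few samples and a
    47-marker sex-linked locus (all males het, all females hom-ref).
    """
    return SimConfig(
        seed=seed,
        n_chrom=2,
        chrom_length=10_000_000,
        n_snps=4_000,
        pop_sizes=(6, 6),
        fst_param=0.05,
        depth_mean=26.0,
        sample_sex=("female", "male") * 6,
        roh_plants=(
            (3, "chr2", 6_000_001, 7_200_000),
            (6, "chr1", 1_000_001, 2_600_000),
            (8, "chr1", 5_000_001, 8_000_000),
            (8, "chr2", 1_000_001, 2_500_000),
        ),
        sex_locus=("chr2", 4_000_000, 4_150_000, 47),
    )


def combined_cohort_config(seed: int = 0) -> SimConfig:
    """Two strongly diverged cohorts, one large and sparse with missingness."""
    return SimConfig(
        seed=seed,
        n_chrom=2,
        chrom_length=10_000_000,
        n_snps=1_000,
        pop_sizes=(12, 200),
        fst_param=0.24,
        missing_rate=0.05,
        depth_mean=11.0,
    )


def _pop_frequencies(rng: np.random.Generator, p0: np.ndarray, F: float) -> np.ndarray:
    """Draw one population's per-site frequencies under Balding–Nichols."""
    if F == 0.0:
        return p0.copy()
    scale = (1.0 - F) / F
    return rng.beta(p0 * scale, (1.0 - p0) * scale)


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Generate genotypes and truth table; fully reproducible from the seed."""
    rng = np.random.default_rng(cfg.seed)
    n1, n2 = cfg.pop_sizes
    n_samples = n1 + n2
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]

    sex = list(cfg.sample_sex) if cfg.sample_sex is not None else None
    if cfg.sex_locus is not None and sex is None:
        raise ValueError("sex_locus requires sample_sex labels")

    # --- positions ----------------------------------------------------
    per_chrom = [cfg.n_snps // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_snps % cfg.n_chrom):
        per_chrom[i] += 1

    sex_chrom, sex_positions = None, np.array([], dtype=np.int64)
    if cfg.sex_locus is not None:
        sex_chrom, s_start, s_end, n_mark = cfg.sex_locus
        if sex_chrom not in chroms:
            raise ValueError(f"sex locus chromosome {sex_chrom!r} not simulated")
        sex_positions = np.sort(
            rng.choice(np.arange(s_start, s_end + 1), size=n_mark, replace=False)
        )

    chrom_col, pos_col = [], []
    sex_marker_mask = []
    for c, n_c in zip(chroms, per_chrom):
        if c == sex_chrom:
            n_bg = n_c - len(sex_positions)
            if n_bg < 0:
                raise ValueError("sex locus has more markers than SNPs on its chromosome")
            bg = rng.choice(cfg.chrom_length, size=n_bg + len(sex_positions), replace=False) + 1
            bg = rng.permutation(np.setdiff1d(bg, sex_positions))[:n_bg]
            pos = np.sort(np.concatenate([bg, sex_positions]))
            in_sex = np.isin(pos, sex_positions)
        else:
            pos = np.sort(rng.choice(cfg.chrom_length, size=n_c, replace=False) + 1)
            in_sex = np.zeros(len(pos), dtype=bool)
        chrom_col.append(np.full(len(pos), c, dtype=object))
        pos_col.append(pos.astype(np.int64))
        sex_marker_mask.append(in_sex)
    chrom_arr = np.concatenate(chrom_col)
    pos_arr = np.concatenate(pos_col)
    is_sex_marker = np.concatenate(sex_marker_mask)
    n_v = len(pos_arr)

    # --- frequencies and genotypes ------------------------------------
    lo, hi = cfg.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=n_v)
    p_pop = np.vstack([
        _pop_frequencies(rng, p0, cfg.fst_param),
        _pop_frequencies(rng, p0, cfg.fst_param),
    ])
    pop_of_sample = np.array([0] * n1 + [1] * n2)
    dosage = rng.binomial(2, p_pop[pop_of_sample, :], size=(n_samples, n_v))
    calls = dosage.astype(np.int8)  # dosage 0/1/2 maps directly onto call codes

    # --- alleles ------------------------------------------------------
    nts = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_v)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_v)) % 4
    ref_arr = nts[ref_idx].astype(object)
    alt_arr = nts[alt_idx].astype(object)

    planted_cell = np.zeros((n_samples, n_v), dtype=bool)

    # --- planted ROH tracts -------------------------------------------
    roh_rows = []
    for s_idx, c, a, b in cfg.roh_plants:
        in_tract = (chrom_arr == c) & (pos_arr >= a) & (pos_arr <= b)
        major_is_alt = p_pop[pop_of_sample[s_idx], :] > 0.5
        forced = np.where(major_is_alt, HOM_ALT, HOM_REF).astype(np.int8)
        calls[s_idx, in_tract] = forced[in_tract]
        planted_cell[s_idx, in_tract] = True
        roh_rows.append({"sample_index": s_idx, "chrom": c, "start": a, "end": b,
                         "n_snps": int(in_tract.sum())})

    # --- planted sex locus --------------------------------------------
    if cfg.sex_locus is not None:
        male = np.array([s == "male" for s in sex])
        calls[np.ix_(male, is_sex_marker)] = HET
        calls[np.ix_(~male, is_sex_marker)] = HOM_REF
        planted_cell[:, is_sex_marker] = True

    # --- planted filter casualties ------------------------------------
    qual = rng.uniform(cfg.qual_range[0], cfg.qual_range[1], size=n_v)
    plantable = ~planted_cell.any(axis=0)
    avail = np.flatnonzero(plantable)
    need = (cfg.plant_low_qual_sites + cfg.plant_low_call_rate_sites
            + cfg.plant_monomorphic_sites)
    if need > len(avail):
        raise ValueError("not enough background sites for planted filter casualties")
    chosen = rng.choice(avail, size=need, replace=False) if need else np.array([], dtype=int)
    k = 0
    lq = chosen[k:k + cfg.plant_low_qual_sites]; k += cfg.plant_low_qual_sites
    lcr = chosen[k:k + cfg.plant_low_call_rate_sites]; k += cfg.plant_low_call_rate_sites
    mono = chosen[k:k + cfg.plant_monomorphic_sites]
    qual[lq] = rng.uniform(0.0, 15.0, size=len(lq))
    for j in lcr:
        # knock out just over half the cohort so call rate < 0.5
        n_drop = n_samples // 2 + 1
        drop = rng.choice(n_samples, size=n_drop, replace=False)
        calls[drop, j] = MISSING
        planted_cell[:, j] = True
    calls[:, mono] = HOM_REF
    planted_cell[:, mono] = True

    # --- missingness outside planted features -------------------------
    if cfg.missing_rate > 0:
        miss = rng.random((n_samples, n_v)) < cfg.missing_rate
        miss &= ~planted_cell
        calls[miss] = MISSING

    # --- depth --------------------------------------------------------
    k_disp = cfg.depth_dispersion
    p_nb = k_disp / (k_disp + cfg.depth_mean)
    depth = rng.negative_binomial(k_disp, p_nb, size=(n_samples, n_v))

    gm = GenotypeMatrix(
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
        chrom=chrom_arr,
        pos=pos_arr,
        ref=ref_arr,
        alt=alt_arr,
        calls=calls,
        site_qual=qual,
        depth=depth,
        sample_sex=sex,
        sample_population=["pop1"] * n1 + ["pop2"] * n2,
    )

    sites = pd.DataFrame({
        "chrom": chrom_arr,
        "pos": pos_arr,
        "p0": p0,
        "p_pop1": p_pop[0],
        "p_pop2": p_pop[1],
        "is_sex_marker": is_sex_marker,
        "planted_low_qual": np.isin(np.arange(n_v), lq),
        "planted_low_call_rate": np.isin(np.arange(n_v), lcr),
        "planted_monomorphic": np.isin(np.arange(n_v), mono),
    })
    truth = TruthTable(
        sites=sites,
        roh_plants=pd.DataFrame(roh_rows, columns=["sample_index", "chrom",
                                                   "start", "end", "n_snps"]),
        sex_markers=pd.DataFrame({
            "chrom": chrom_arr[is_sex_marker],
            "pos": pos_arr[is_sex_marker],
        }),
        config_digest=cfg.digest(),
        planted_filter_counts={
            "low_qual": int(len(lq)),
            "low_call_rate": int(len(lcr)),
            "monomorphic": int(len(mono)),
        },
    )
    return gm, truth


def simulate_to_vcf(cfg: SimConfig, path: str) -> TruthTable:
    """Simulate and write straight to VCF; header records seed and digest."""
    from .variant_io import write_vcf

    gm, truth = simulate(cfg)
    write_vcf(gm, path, extra_header_lines=[
        f"##esoxpop_sim_seed={cfg.seed}",
        f"##esoxpop_sim_config={cfg.digest()}",
    ])
    return truth
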