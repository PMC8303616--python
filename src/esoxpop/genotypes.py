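"""Core genotype container shared by every analysis.

Genotype calls are stored as a dense ``(n_samples, n_variants)`` int8 matrix
with the codes below.  All statistics in this package are phase-free, so
phased and unphased heterozygotes collapse to the same code.  Coordinates are
1-based inclusive (the VCF convention); window arithmetic converts to 0-based
half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

# call codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

CALL_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

_NUCLEOTIDES = frozenset("ACGT")
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


class GenotypeError(ValueError):
    """Raised when a genotype matrix violates its structural invariants."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP call matrix with positions and alleles.

    Attributes
    ----------
    sample_ids
        Ordered sample labels.
    chrom, pos
        Per-variant chromosome name and 1-based coordinate; positions must be
        strictly increasing within each chromosome.
    ref, alt
        Single-nucleotide reference / alternate alleles.
    calls
        ``(n_samples, n_variants)`` int8 array of call codes.
    site_qual
        Per-variant quality score (VCF QUAL).
    depth
        Optional ``(n_samples, n_variants)`` per-genotype read depth.
    sample_sex
        Optional per-sample label in ``{"female", "male", "unknown"}``.
    sample_population
        Optional per-sample population label.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    site_qual: np.ndarray
    depth: np.ndarray | None = None
    sample_sex: list[str] | None = None
    sample_population: list[str] | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.site_qual = np.asarray(self.site_qual, dtype=np.float64)
        if self.depth is not None:
            self.depth = np.asarray(self.depth)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n_s, n_v = len(self.sample_ids), len(self.pos)
        if self.calls.shape != (n_s, n_v):
            raise GenotypeError(
                f"calls shape {self.calls.shape} != (n_samples={n_s}, n_variants={n_v})"
            )
        for arr, name in ((self.chrom, "chrom"), (self.ref, "ref"),
                          (self.alt, "alt"), (self.site_qual, "site_qual")):
            if len(arr) != n_v:
                raise GenotypeError(f"{name} has length {len(arr)}, expected {n_v}")
        if self.depth is not None and self.depth.shape != (n_s, n_v):
            raise GenotypeError("depth shape does not match calls")
        if self.sample_sex is not None and len(self.sample_sex) != n_s:
            raise GenotypeError("sample_sex length mismatch")
        if self.sample_population is not None and len(self.sample_population) != n_s:
            raise GenotypeError("sample_population length mismatch")
        for r, a in zip(self.ref, self.alt):
            if r not in _NUCLEOTIDES or a not in _NUCLEOTIDES or r == a:
                raise GenotypeError(f"not a biallelic SNP: ref={r!r} alt={a!r}")
        for c, idx in self.chrom_slices():
            p = self.pos[idx]
            if np.any(np.diff(p) <= 0):
                raise GenotypeError(f"positions not strictly increasing on {c}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def chrom_slices(self) -> Iterator[tuple[str, slice]]:
        """Yield ``(chrom, slice)`` pairs in input order.

        Variants of one chromosome must be contiguous (guaranteed by the
        reader and the simulator).
        """
        if self.n_variants == 0:
            return
        bounds = [0] + list(np.nonzero(self.chrom[1:] != self.chrom[:-1])[0] + 1) + [self.n_variants]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            yield str(self.chrom[lo]), slice(lo, hi)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise GenotypeError(f"unknown sample {sample_id!r}") from None

    # ------------------------------------------------------------------
    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant (ref_count, alt_count) over non-missing calls.

        Each homozygote contributes 2 copies of its allele, each heterozygote
        one of each.
        """
        hom_ref = (self.calls == HOM_REF).sum(axis=0)
        het = (self.calls == HET).sum(axis=0)
        hom_alt = (self.calls == HOM_ALT).sum(axis=0)
        return 2 * hom_ref + het, 2 * hom_alt + het

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per variant."""
        return (self.calls != MISSING).sum(axis=0) / self.n_samples

    def is_monomorphic(self) -> np.ndarray:
        """True where all non-missing calls are identical and homozygous."""
        n_ref = (self.calls == HOM_REF).sum(axis=0)
        n_het = (self.calls == HET).sum(axis=0)
        n_alt = (self.calls == HOM_ALT).sum(axis=0)
        n_called = n_ref + n_het + n_alt
        return (n_het == 0) & ((n_ref == n_called) | (n_alt == n_called))

    def alt_frequency(self) -> np.ndarray:
        """Alternate-allele frequency per variant (NaN where all missing)."""
        rc, ac = self.allele_counts()
        tot = rc + ac
        with np.errstate(invalid="ignore"):
            return np.where(tot > 0, ac / np.maximum(tot, 1), np.nan)

    # ------------------------------------------------------------------
    def take_variants(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            calls=self.calls[:, idx],
            site_qual=self.site_qual[idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def take_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            calls=self.calls[idx, :],
            depth=None if self.depth is None else self.depth[idx, :],
            sample_sex=None if self.sample_sex is None else [self.sample_sex[i] for i in idx],
            sample_population=None if self.sample_population is None
            else [self.sample_population[i] for i in idx],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Equality on calls, positions and alleles (the round-trip contract)."""
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.calls, other.calls)
        )


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in _TRANSITIONS
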