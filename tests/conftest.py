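import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from esoxpop.genotypes import GenotypeMatrix


def build_gm(calls, pos=None, chrom="chr1", ref="A", alt="G", qual=50.0,
             depth=None, sample_sex=None, sample_population=None):
    """Construct a GenotypeMatrix from a (n_samples, n_variants) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_s, n_v = calls.shape
    if pos is None:
        pos = np.arange(1, n_v + 1) * 1000
    chrom_arr = (np.full(n_v, chrom, dtype=object) if isinstance(chrom, str)
                 else np.asarray(chrom, dtype=object))
    ref_arr = (np.full(n_v, ref, dtype=object) if isinstance(ref, str)
               else np.asarray(ref, dtype=object))
    alt_arr = (np.full(n_v, alt, dtype=object) if isinstance(alt, str)
               else np.asarray(alt, dtype=object))
    qual_arr = (np.full(n_v, qual, dtype=float) if np.isscalar(qual)
                else np.asarray(qual, dtype=float))
    return GenotypeMatrix(
        sample_ids=[f"s{i + 1}" for i in range(n_s)],
        chrom=chrom_arr, pos=np.asarray(pos, dtype=np.int64),
        ref=ref_arr, alt=alt_arr, calls=calls, site_qual=qual_arr,
        depth=None if depth is None else np.asarray(depth),
        sample_sex=sample_sex, sample_population=sample_population,
    )


@pytest.fixture
def fixed_opposite_gm():
    """6+6 samples, 50 SNPs: group A hom_ref, group B hom_alt everywhere."""
    calls = np.vstack([np.zeros((6, 50)), np.full((6, 50), 2)]).astype(np.int8)
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(np.arange(1, 500_001), size=50, replace=False))
    return build_gm(calls, pos=pos,
                    sample_population=["A"] * 6 + ["B"] * 6)
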