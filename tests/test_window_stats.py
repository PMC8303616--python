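import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from esoxpop import synthetic_data as sd
from esoxpop import window_stats as ws
from esoxpop.genotypes import HOM_REF, HET, HOM_ALT

from conftest import build_gm
from oracles import scalar_weir_cockerham


class TestMakeWindows:
    def test_half_overlap_arithmetic(self):
        out = ws.make_windows({"c": 1_200_000}, ws.WindowSpec(500_000, 250_000))
        assert out["start"].tolist() == [0, 250_000, 500_000, 750_000, 1_000_000]
        assert out["end"].tolist() == [500_000, 750_000, 1_000_000, 1_200_000,
                                       1_200_000]

    def test_short_chromosome_single_clipped_window(self):
        out = ws.make_windows({"c": 400_000}, ws.WindowSpec(500_000, 250_000))
        assert len(out) == 2  # starts 0 and 250k, both clipped
        assert out.iloc[0].tolist() == ["c", 0, 400_000]

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            size = int(rng.integers(10, 1000))
            step = int(rng.integers(1, size + 1))
            length = int(rng.integers(1, 5000))
            out = ws.make_windows({"c": length}, ws.WindowSpec(size, step))
            brute = [(s, min(s + size, length))
                     for s in range(0, length, step)]
            assert list(zip(out["start"], out["end"])) == brute

    def test_every_snp_in_two_windows_under_half_overlap(self):
        spec = ws.WindowSpec(500_000, 250_000)
        windows = ws.make_windows({"c": 10_000_000}, spec)
        rng = np.random.default_rng(2)
        pos = rng.integers(250_001, 9_750_000, size=200)  # away from edges
        for p in pos:
            covering = ((windows["start"] < p) & (p <= windows["end"])).sum()
            assert covering == 2


class TestPooledHet:
    def test_symmetric_counts_reach_maximum(self):
        # 4 samples all het at every SNP: sum_maj == sum_min -> hp = 0.5
        gm = build_gm(np.full((4, 20), HET, dtype=np.int8))
        w = ws.make_windows({"chr1": 20_000}, ws.WindowSpec(20_000, 20_000))
        out = ws.pooled_het(gm, w, min_snps_per_window=10)
        assert out["hp"].iloc[0] == pytest.approx(0.5)

    def test_no_minor_alleles_gives_zero(self):
        gm = build_gm(np.zeros((4, 20), dtype=np.int8))
        w = ws.make_windows({"chr1": 20_000}, ws.WindowSpec(20_000, 20_000))
        out = ws.pooled_het(gm, w, min_snps_per_window=10)
        assert out["hp"].iloc[0] == 0.0

    def test_published_window_counts_arithmetic(self):
        """A window whose allele-count sums are 1366 major / 746 minor."""
        # 88 SNPs x 12 diploids = 2112 alleles; het count = minor count/site
        minors = np.array([9] * 42 + [8] * 46)
        assert minors.sum() == 746
        calls = np.zeros((12, 88), dtype=np.int8)
        for j, m in enumerate(minors):
            calls[:m, j] = HET
        gm = build_gm(calls, pos=np.arange(1, 89) * 5000)
        w = ws.make_windows({"chr1": 500_000}, ws.WindowSpec(500_000, 500_000))
        out = ws.pooled_het(gm, w, min_snps_per_window=10)
        assert out["sum_maj"].iloc[0] == 1366
        assert out["sum_min"].iloc[0] == 746
        assert out["hp"].iloc[0] == pytest.approx(2 * 1366 * 746 / 2112**2)

    def test_sparse_window_carries_no_hp(self):
        gm = build_gm(np.full((4, 5), HET, dtype=np.int8))
        w = ws.make_windows({"chr1": 5_000}, ws.WindowSpec(5_000, 5_000))
        out = ws.pooled_het(gm, w, min_snps_per_window=10)
        assert np.isnan(out["hp"].iloc[0])

    @given(st.integers(0, 2**32 - 1))
    def test_invariant_under_ref_alt_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(8, 40)).astype(np.int8)
        gm = build_gm(calls, pos=np.arange(1, 41) * 1000)
        flipped = build_gm((2 - calls).astype(np.int8), pos=gm.pos,
                           ref="G", alt="A")
        w = ws.make_windows({"chr1": 40_000}, ws.WindowSpec(10_000, 5_000))
        a = ws.pooled_het(gm, w, 5)
        b = ws.pooled_het(flipped, w, 5)
        assert np.allclose(a["hp"], b["hp"], equal_nan=True)
        assert a["sum_maj"].equals(b["sum_maj"])


class TestNormalizeHp:
    @staticmethod
    def _frame(hps):
        return pd.DataFrame({"chrom": "c", "start": 0, "end": 1,
                             "n_snps": 10, "hp": hps})

    def test_window_at_mean_has_zero_zhp(self):
        out, norm = ws.normalize_hp(self._frame([0.1, 0.2, 0.3]))
        assert out["zhp"].iloc[1] == pytest.approx(0.0)
        assert norm.mu_hp == pytest.approx(0.2)

    def test_hand_computed_sample_sd(self):
        # sd({0.1,0.2,0.3}, ddof=1) = 0.1, so the third window scores +1
        out, _ = ws.normalize_hp(self._frame([0.1, 0.2, 0.3]))
        assert out["zhp"].iloc[2] == pytest.approx(1.0)

    def test_identical_windows_error(self):
        with pytest.raises(ws.NormalizationError):
            ws.normalize_hp(self._frame([0.2, 0.2, 0.2]))

    def test_zhp_has_zero_mean_unit_sd(self):
        cfg = sd.SimConfig(seed=17, n_chrom=2, chrom_length=5_000_000,
                           n_snps=3000, pop_sizes=(6, 6))
        gm, _ = sd.simulate(cfg)
        w = ws.make_windows({c: int(gm.pos[sl].max())
                             for c, sl in gm.chrom_slices()}, ws.WindowSpec())
        out, _ = ws.normalize_hp(ws.pooled_het(gm, w, 10))
        z = out["zhp"].dropna()
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1.0) < 1e-9
        assert ((out["hp"].dropna() >= 0) & (out["hp"].dropna() <= 0.5)).all()


class TestSnpFst:
    def test_fixed_opposite_alleles_give_one(self, fixed_opposite_gm):
        gm = fixed_opposite_gm
        out = ws.snp_fst(gm, gm.sample_ids[:6], gm.sample_ids[6:])
        assert np.allclose(out["fst"], 1.0)

    def test_identical_groups_give_nonpositive(self):
        rng = np.random.default_rng(3)
        half = rng.integers(0, 3, size=(6, 30)).astype(np.int8)
        gm = build_gm(np.vstack([half, half]))
        out = ws.snp_fst(gm, gm.sample_ids[:6], gm.sample_ids[6:])
        assert np.all(out["fst"].dropna() <= 1e-12)

    def test_matches_scalar_wc_oracle(self):
        # pA = 0.75, pB = 0.25, n = 4 diploids each, HW heterozygote counts:
        # A: 2 hom_alt + 2 het -> p=0.75, h=0.5 ; B mirrored
        ga = np.array([[HOM_ALT], [HOM_ALT], [HET], [HET]])
        gb = np.array([[HOM_REF], [HOM_REF], [HET], [HET]])
        gm = build_gm(np.vstack([ga, gb]).astype(np.int8))
        out = ws.snp_fst(gm, gm.sample_ids[:4], gm.sample_ids[4:])
        expect = scalar_weir_cockerham(4, 0.75, 0.5, 4, 0.25, 0.5)
        assert out["fst"].iloc[0] == pytest.approx(expect, rel=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_random_sites_match_scalar_oracle_and_bound(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(12, 25)).astype(np.int8)
        gm = build_gm(calls)
        out = ws.snp_fst(gm, gm.sample_ids[:6], gm.sample_ids[6:])
        for j in range(25):
            a, b = calls[:6, j], calls[6:, j]
            p1 = (2 * (a == HOM_ALT).sum() + (a == HET).sum()) / 12
            p2 = (2 * (b == HOM_ALT).sum() + (b == HET).sum()) / 12
            h1 = (a == HET).sum() / 6
            h2 = (b == HET).sum() / 6
            try:
                expect = scalar_weir_cockerham(6, p1, h1, 6, p2, h2)
            except ZeroDivisionError:
                assert np.isnan(out["fst"].iloc[j])
                continue
            got = out["fst"].iloc[j]
            assert got == pytest.approx(expect, rel=1e-9, abs=1e-12)
            assert got <= 1.0 + 1e-12

    def test_low_sample_sites_skipped(self):
        calls = np.full((4, 3), -1, dtype=np.int8)
        calls[:, 0] = [0, 0, 2, 2]  # only site 0 has full calls
        gm = build_gm(calls)
        out = ws.snp_fst(gm, gm.sample_ids[:2], gm.sample_ids[2:])
        assert out.attrs["skipped_low_n"] == 2
        assert np.isnan(out["fst"].iloc[1]) and np.isnan(out["fst"].iloc[2])

    def test_empty_group_rejected(self, fixed_opposite_gm):
        with pytest.raises(ValueError):
            ws.snp_fst(fixed_opposite_gm, [], fixed_opposite_gm.sample_ids)


class TestWindowMfst:
    def test_all_fixed_snps_give_mfst_one(self, fixed_opposite_gm):
        gm = fixed_opposite_gm
        fst = ws.snp_fst(gm, gm.sample_ids[:6], gm.sample_ids[6:])
        w = ws.make_windows({"chr1": 500_000}, ws.WindowSpec())
        out = ws.window_mfst(gm, fst, w, 10)
        assert out["mfst"].iloc[0] == pytest.approx(1.0)
        assert bool(out["high"].iloc[0])

    def test_simple_mean(self):
        gm = build_gm(np.zeros((4, 2), dtype=np.int8) + HET,
                      pos=np.array([100, 200]))
        fst = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [100, 200],
                            "fst": [0.2, 0.4]})
        w = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        out = ws.window_mfst(gm, fst, w, min_snps_per_window=2)
        assert out["mfst"].iloc[0] == pytest.approx(0.3)

    def test_matches_bruteforce_windowed_mean(self):
        rng = np.random.default_rng(9)
        n = 300
        pos = np.sort(rng.choice(2_000_000, n, replace=False)) + 1
        vals = rng.uniform(-0.1, 1.0, n)
        gm = build_gm(np.zeros((4, n), dtype=np.int8) + HET, pos=pos)
        fst = pd.DataFrame({"chrom": ["chr1"] * n, "pos": pos, "fst": vals})
        w = ws.make_windows({"chr1": 2_000_000}, ws.WindowSpec())
        out = ws.window_mfst(gm, fst, w, 1)
        for _, row in out.iterrows():
            sel = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
            if sel.sum() == 0:
                assert np.isnan(row["mfst"])
            else:
                assert row["mfst"] == pytest.approx(vals[sel].mean())


class TestGenomeFst:
    def test_balding_nichols_parameter_recovery_single_seed(self):
        cfg = sd.SimConfig(seed=23, pop_sizes=(50, 50), n_snps=5000,
                           fst_param=0.25, n_chrom=2, chrom_length=10_000_000)
        gm, _ = sd.simulate(cfg)
        est = ws.genome_fst(gm, gm.sample_ids[:50], gm.sample_ids[50:])
        assert est == pytest.approx(0.25, abs=0.03)

    def test_equals_one_for_fixed_opposite(self, fixed_opposite_gm):
        gm = fixed_opposite_gm
        assert ws.genome_fst(gm, gm.sample_ids[:6], gm.sample_ids[6:]) == 1.0
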