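"""f4 / D / F4-ratio arithmetic, jackknife oracles and fraction fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from abcdl import coalsim as cs
from abcdl import dstats
from abcdl.demography import SimEvent, SimulatorSpec
from conftest import make_regions


def table_from_freqs(freqs: np.ndarray, pops, blocks=None,
                     ploidy: int = 2) -> dstats.AlleleCountTable:
    """Build a count table from per-site frequencies (one diploid each)."""
    derived = np.round(np.asarray(freqs) * ploidy).astype(int)
    total = np.full_like(derived, ploidy)
    if blocks is None:
        blocks = np.zeros(len(derived), dtype=int)
    return dstats.AlleleCountTable(pops, derived, total, np.asarray(blocks))


QUAD = ("W", "X", "Y", "Z")


class TestF4:
    def test_single_site_defining_product(self):
        t = table_from_freqs([[0, 1, 1, 0]], QUAD)
        _, num, n = dstats.f4(t, QUAD)
        assert num.sum() / n.sum() == -1.0

    def test_identical_w_and_x_columns_give_zero(self, rng):
        f = rng.integers(0, 3, size=(30, 4)) / 2.0
        f[:, 1] = f[:, 0]
        t = table_from_freqs(f, QUAD)
        _, num, _ = dstats.f4(t, QUAD)
        assert num.sum() == pytest.approx(0.0)

    def test_matches_brute_force_site_loop(self, rng):
        f = rng.integers(0, 3, size=(20, 4)) / 2.0
        blocks = rng.integers(0, 4, size=20)
        t = table_from_freqs(f, QUAD, blocks)
        _, num, n = dstats.f4(t, QUAD)
        brute = np.mean([(w - x) * (y - z) for w, x, y, z in f])
        assert num.sum() / n.sum() == pytest.approx(brute)


class TestPattersonD:
    def test_boundary_abba_only_gives_minus_one(self):
        f = np.tile([0.0, 1.0, 1.0, 0.0], (10, 1))[:, :3]
        t = table_from_freqs(f, ("W", "X", "Y"), blocks=np.arange(10) // 5)
        r = dstats.patterson_d(t, ("W", "X", "Y", dstats.ANCESTRAL))
        assert r.D == -1.0

    def test_balanced_abba_baba_gives_zero(self):
        f = np.array([[0, 1, 1], [1, 0, 1]] * 5, dtype=float)
        t = table_from_freqs(f, ("W", "X", "Y"))
        r = dstats.patterson_d(t, ("W", "X", "Y", dstats.ANCESTRAL))
        assert r.D == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(hnp.arrays(np.int64, st.tuples(st.integers(8, 40), st.just(4)),
                      elements=st.integers(0, 2)))
    def test_antisymmetry_property(self, derived):
        """Swapping W and X negates D exactly, for any count table with at
        least one informative site."""
        t = dstats.AlleleCountTable(list("WXYZ"), derived,
                                    np.full_like(derived, 2),
                                    np.arange(len(derived)) % 3)
        try:
            d1 = dstats.patterson_d(t, ("W", "X", "Y", "Z"))
        except ValueError:
            return  # no informative sites in this draw
        d2 = dstats.patterson_d(t, ("X", "W", "Y", "Z"))
        assert d1.D == pytest.approx(-d2.D)

    def test_antisymmetry_under_w_x_swap(self, rng):
        f = rng.integers(0, 3, size=(60, 4)) / 2.0
        t = table_from_freqs(f, QUAD, rng.integers(0, 5, 60))
        d1 = dstats.patterson_d(t, ("W", "X", "Y", "Z"))
        d2 = dstats.patterson_d(t, ("X", "W", "Y", "Z"))
        assert d1.D == pytest.approx(-d2.D)
        assert d1.SE == pytest.approx(d2.SE)

    def test_matches_brute_force_and_hand_jackknife(self, rng):
        f = rng.integers(0, 3, size=(50, 4)) / 2.0
        blocks = np.repeat(np.arange(5), 10)
        t = table_from_freqs(f, QUAD, blocks)
        r = dstats.patterson_d(t, QUAD)
        num = (f[:, 0] - f[:, 1]) * (f[:, 2] - f[:, 3])
        den = ((f[:, 0] + f[:, 1] - 2 * f[:, 0] * f[:, 1])
               * (f[:, 2] + f[:, 3] - 2 * f[:, 2] * f[:, 3]))
        assert r.D == pytest.approx(num.sum() / den.sum())
        loo = np.array([(num.sum() - num[blocks == b].sum())
                        / (den.sum() - den[blocks == b].sum()) for b in range(5)])
        # equal block sizes: textbook delete-one jackknife SE
        se = np.sqrt((5 - 1) / 5 * ((loo - loo.mean()) ** 2).sum())
        assert r.SE == pytest.approx(se)

    def test_no_informative_sites_is_an_error(self):
        t = table_from_freqs(np.ones((5, 4)) * 0.0, QUAD)
        with pytest.raises(ValueError, match="zero D denominator|no sites"):
            dstats.patterson_d(t, QUAD)


class TestWeightedBlockJackknife:
    def test_identical_blocks_have_zero_se(self):
        est, se = dstats.weighted_block_jackknife(0.3, np.full(6, 0.3),
                                                  np.full(6, 10))
        assert est == pytest.approx(0.3)
        assert se == 0.0

    def test_equal_weights_match_textbook_jackknife(self, rng):
        loo = rng.normal(size=8)
        theta = 0.1
        est, se = dstats.weighted_block_jackknife(theta, loo, np.full(8, 5))
        g = 8
        assert est == pytest.approx(g * theta - (g - 1) * loo.mean())
        assert se == pytest.approx(
            np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum()))

    def test_two_block_closed_form(self):
        # blocks of weight 3 and 1, full estimate 0.5, delete-one 0.4 / 0.8
        theta, loo, m = 0.5, np.array([0.4, 0.8]), np.array([3.0, 1.0])
        n = 4.0
        expected_est = 2 * theta - ((1 - 3 / 4) * 0.4 + (1 - 1 / 4) * 0.8)
        h = n / m
        tau = h * theta - (h - 1) * loo
        expected_se = np.sqrt(((tau - expected_est) ** 2 / (h - 1)).sum() / 2)
        est, se = dstats.weighted_block_jackknife(theta, loo, m)
        assert est == pytest.approx(expected_est)
        assert se == pytest.approx(expected_se)

    def test_single_block_rejected(self):
        with pytest.raises(ValueError, match="at least 2 blocks"):
            dstats.weighted_block_jackknife(0.1, np.array([0.1]), np.array([1.0]))

    def test_se_shrinks_like_root_blocks(self, rng):
        """log SE vs log #blocks slope is ~ -1/2 on iid block data."""
        ns, ses = [25, 100, 400, 1600], []
        for g in ns:
            loo_base = rng.normal(0, 1.0, size=g)
            # delete-one estimates of a mean of g iid blocks
            total = loo_base.sum()
            loo = (total - loo_base) / (g - 1)
            _, se = dstats.weighted_block_jackknife(total / g, loo, np.full(g, 1.0))
            ses.append(se)
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert -0.6 < slope < -0.4


class TestF4Ratio:
    def test_identity_quadruples_give_ratio_one(self, rng):
        f = rng.integers(0, 3, size=(40, 4)) / 2.0
        t = table_from_freqs(f, QUAD, rng.integers(0, 4, 40))
        r = dstats.f4_ratio(t, QUAD, QUAD)
        assert r.ratio == pytest.approx(1.0)
        assert r.SE == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.05, 0.2])
    def test_recovers_known_admixture_fraction(self, alpha):
        """Topology (((A,B),C),O) with X = alpha*B + (1-alpha)*C mixture:
        f4(A,O;X,C)/f4(A,O;B,C) = alpha exactly in expectation."""
        events = [SimEvent(200.0, "admixed_origin",
                           ("X", ("C", "B"), (1.0 - alpha, alpha))),
                  SimEvent(1500.0, "split", (("A", "B"), "AB")),
                  SimEvent(3000.0, "split", (("AB", "C"), "ABC")),
                  SimEvent(8000.0, "split", (("ABC", "OUT"), "ROOT"))]
        pops = [(p, 5000.0, 0.0, True) for p in ("A", "B", "C", "X", "OUT")]
        pops += [(p, 5000.0, 0.0, False) for p in ("AB", "ABC", "ROOT")]
        spec = SimulatorSpec("adm", pops, events)
        rng = np.random.default_rng(int(alpha * 100) + 3)
        regions = make_regions(40, 100_000)
        derived, blocks = [], []
        seeds = rng.integers(1, 2**31 - 1, size=(len(regions), 2))
        order = ["A", "OUT", "X", "C", "B"]
        for bi, (region, sp) in enumerate(zip(regions, seeds)):
            ts = cs.simulate_region(spec, region, 1.5e-8, (int(sp[0]), int(sp[1])))
            pop_ids = {p.metadata["name"]: p.id for p in ts.populations()}
            G = ts.genotype_matrix()
            counts = np.stack([G[:, ts.samples(population=pop_ids[p])].sum(axis=1)
                               for p in order], axis=1)
            derived.append(counts)
            blocks.append(np.full(len(counts), bi))
        table = dstats.AlleleCountTable(
            order, np.concatenate(derived),
            np.full_like(np.concatenate(derived), 2), np.concatenate(blocks))
        r = dstats.f4_ratio(table, ("A", "OUT", "X", "C"),
                            ("A", "OUT", "B", "C"))
        assert abs(r.ratio - alpha) < 2 * r.SE + 1e-9


class TestFitIntrogression:
    regions = make_regions(2, 100_000)

    def _pseudo_observed(self, frac, seed, n_reps=60):
        from abcdl.demography import posterior_means
        params = dict(posterior_means("A"))
        params["f_intro_n_ooa"] = frac
        d = dstats.simulate_d_vector("A", params, dstats.STANDARD_QUADS,
                                     self.regions, n_reps=n_reps, seed=seed)
        return dict(zip(map(tuple, dstats.STANDARD_QUADS), d))

    def test_monotone_in_neanderthal_fraction(self):
        """With quadruple (ASN, AFR, NEAN, Ancestral), D = sum (w-x)(y-z)/...
        grows as the Neanderthal fraction in the OOA ancestor rises (the
        Table-1 orientation (AFR, ASN, ...) would shrink symmetrically)."""
        from abcdl.demography import posterior_means
        ds = []
        for frac in (0.0, 0.02, 0.05):
            params = dict(posterior_means("A"))
            params["f_intro_n_ooa"] = frac
            # common random numbers across fractions isolate the trend
            d = dstats.simulate_d_vector(
                "A", params, [("ASN", "AFR", "NEAN", dstats.ANCESTRAL)],
                self.regions, n_reps=60, seed=55)
            ds.append(d[0])
        assert ds[0] < ds[1] < ds[2]

    def test_recovers_fraction_with_shared_noise(self):
        """With the same simulation seeds for the pseudo-observed data and
        the fitting objective, the optimizer must locate the generating
        fraction to within its own tolerance."""
        obs = self._pseudo_observed(0.03, seed=77, n_reps=30)
        fit = dstats.fit_introgression(obs, ["f_intro_n_ooa"], model_label="A",
                                       regions=self.regions, n_reps=30, seed=77)
        assert fit.objective < 1e-8
        assert fit.estimate[0] == pytest.approx(0.03, abs=0.005)

    def test_recovers_null_fraction_independent_noise(self):
        """Independent seeds: recovery within the Monte-Carlo noise of the
        desk-scale simulations (~0.025 on the fraction scale here)."""
        obs = self._pseudo_observed(0.0, seed=900)
        fit = dstats.fit_introgression(obs, ["f_intro_n_ooa"], model_label="A",
                                       regions=self.regions, n_reps=60, seed=77)
        assert fit.estimate[0] < 0.06
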