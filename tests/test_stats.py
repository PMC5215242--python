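from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import octarec as oc


# ---- independent oracles ---------------------------------------------------

def grid_search_gamma(x, n_shapes=4000):
    """Profile-likelihood grid search over the shape (scale = mean/shape)."""
    x = np.asarray(x, dtype=float)
    shapes = np.exp(np.linspace(np.log(0.02), np.log(50), n_shapes))
    best = (-np.inf, None)
    for k in shapes:
        ll = sps.gamma.logpdf(x, a=k, scale=x.mean() / k).sum()
        if ll > best[0]:
            best = (ll, k)
    return best


def exact_ks_enumeration(a, b):
    """Permutation-exact two-sample KS: D and P(D* >= D) over all splits."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)

    def ks_d(x, y):
        grid = np.unique(np.concatenate([x, y]))
        cx = np.searchsorted(np.sort(x), grid, side="right") / len(x)
        cy = np.searchsorted(np.sort(y), grid, side="right") / len(y)
        return np.abs(cx - cy).max()

    d_obs = ks_d(a, b)
    idx = range(len(pooled))
    count = total = 0
    for pick in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(pick)] = True
        d = ks_d(pooled[mask], pooled[~mask])
        count += d >= d_obs - 1e-12
        total += 1
    return d_obs, count / total


def exact_ranksum_enumeration(a, b, alternative="two-sided"):
    """Permutation-exact Mann-Whitney U (mid-ranks) and p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1, n = len(a), len(pooled)

    def u_of(pick):
        r = ranks[list(pick)].sum()
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    us = np.array([u_of(p) for p in combinations(range(n), n1)])
    mu = len(a) * len(b) / 2
    if alternative == "less":
        p = np.mean(us <= u_obs + 1e-12)
    elif alternative == "greater":
        p = np.mean(us >= u_obs - 1e-12)
    else:
        p = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
    return u_obs, p


# ---- inter-CO distances ----------------------------------------------------

class TestInterCoDistances:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["meiosis", "chrom", "type", "co_pos"])

    def test_fewer_than_two_crossovers_contribute_nothing(self):
        ev = self.frame([("m1", "c1", "CO", 100.0), ("m1", "c2", "NCO", -1.0)])
        assert len(oc.inter_co_distances(ev)) == 0

    def test_two_crossovers_give_one_gap(self):
        ev = self.frame([("m1", "c1", "CO", 100_000.0), ("m1", "c1", "CO", 300_000.0)])
        assert list(oc.inter_co_distances(ev)) == [200_000.0]

    def test_gaps_pool_across_chromosomes_and_meioses(self):
        ev = self.frame([("m1", "c1", "CO", 0.0), ("m1", "c1", "CO", 10.0),
                         ("m2", "c1", "CO", 5.0), ("m2", "c1", "CO", 25.0)])
        assert sorted(oc.inter_co_distances(ev)) == [10.0, 20.0]

    def test_simulated_interference_gap_cv(self, roundtrip_cohort):
        # pooled inter-CO gap CV approaches 1/sqrt(shape) = 0.659 at shape 2.3
        frames = []
        for k, (_, _, records) in enumerate(roundtrip_cohort):
            df = oc.events_to_frame(records)
            df["meiosis"] = f"m{k}"
            frames.append(df)
        gaps = oc.inter_co_distances(pd.concat(frames, ignore_index=True))
        cv = gaps.std(ddof=1) / gaps.mean()
        se = cv / np.sqrt(2 * len(gaps))
        # renewal gaps censored by chromosome ends: modest extra tolerance
        assert cv == pytest.approx(1 / np.sqrt(2.3), abs=3 * se + 0.05)


# ---- gamma MLE -------------------------------------------------------------

class TestGammaMLE:
    def test_exponential_sample_recovers_shape_one(self):
        rng = np.random.default_rng(21)
        fit = oc.fit_gamma_mle(rng.exponential(130_000, size=1000))
        assert 0.9 <= fit.shape <= 1.1
        assert fit.converged

    def test_interference_shape_recovery(self):
        rng = np.random.default_rng(22)
        fit = oc.fit_gamma_mle(rng.gamma(2.3, 130_000 / 2.3, size=500))
        assert fit.shape == pytest.approx(2.3, abs=0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_beats_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(rng.uniform(0.5, 5.0), rng.uniform(1e3, 1e6), size=200)
        fit = oc.fit_gamma_mle(x)
        ll_grid, k_grid = grid_search_gamma(x)
        assert fit.loglik >= ll_grid - 1e-6
        assert fit.shape == pytest.approx(k_grid, rel=0.01)

    def test_matches_independent_library_fit(self):
        rng = np.random.default_rng(30)
        x = rng.gamma(2.3, 50_000, size=400)
        fit = oc.fit_gamma_mle(x)
        k_sp, _, scale_sp = sps.gamma.fit(x, floc=0)
        assert fit.shape == pytest.approx(k_sp, rel=1e-3)
        assert fit.scale == pytest.approx(scale_sp, rel=1e-3)

    def test_scale_invariance_of_shape(self):
        rng = np.random.default_rng(23)
        x = rng.gamma(1.8, 1000, size=300)
        f1 = oc.fit_gamma_mle(x)
        f2 = oc.fit_gamma_mle(1000.0 * x)
        assert f2.shape == pytest.approx(f1.shape, rel=1e-9)
        assert f2.scale == pytest.approx(1000.0 * f1.scale, rel=1e-9)

    def test_parameter_recovery_across_interference_strengths(self):
        rng = np.random.default_rng(24)
        errors = []
        for _ in range(50):
            shape = rng.uniform(1.0, 4.0)
            x = rng.gamma(shape, 100_000 / shape, size=300)
            errors.append(abs(oc.fit_gamma_mle(x).shape - shape))
        assert np.median(errors) < 0.2

    @pytest.mark.parametrize("bad", [[], [5.0], [1.0, -2.0], [3.0, 3.0, 3.0]])
    def test_degenerate_inputs_fail_explicitly(self, bad):
        with pytest.raises(ValueError):
            oc.fit_gamma_mle(bad)


# ---- two-sample tests ------------------------------------------------------

class TestKolmogorovSmirnov:
    def test_identical_samples_have_zero_statistic(self):
        res = oc.compare_interference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0

    def test_disjoint_supports_have_unit_statistic(self):
        res = oc.compare_interference([1, 2, 3], [10, 20, 30])
        assert res.statistic == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            oc.compare_interference([], [1.0])

    @pytest.mark.parametrize("seed", range(6))
    def test_small_samples_match_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 8), rng.integers(3, 9)
        a = rng.permutation(np.arange(1.0, 40.0))[:n1]
        b = rng.permutation(np.arange(100.0, 140.0, 0.5))[:n2] \
            if seed % 2 else rng.permutation(np.arange(1.5, 41.0))[:n2]
        d_or, p_or = exact_ks_enumeration(a, b)
        res = oc.compare_interference(a, b, method="exact")
        assert res.statistic == pytest.approx(d_or, abs=1e-12)
        assert res.pvalue == pytest.approx(p_or, abs=1e-9)


class TestWilcoxonRankSum:
    def test_identical_samples_give_central_u(self):
        res = oc.compare_tract_lengths([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 4.5  # n1*n2/2 with mid-ranks
        assert res.pvalue > 0.99

    def test_fully_separated_samples_one_sided(self):
        res = oc.compare_tract_lengths([1, 2, 3], [10, 20, 30],
                                       alternative="less", method="exact")
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1 / 20)  # 1 of C(6,3)=20 orderings

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            oc.compare_tract_lengths([1.0], [])

    @pytest.mark.parametrize("seed,alternative", [
        (0, "two-sided"), (1, "two-sided"), (2, "less"), (3, "greater"),
    ])
    def test_small_samples_match_exact_enumeration(self, seed, alternative):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 8), rng.integers(3, 9)
        a = rng.permutation(np.arange(1.0, 50.0))[:n1]
        b = rng.permutation(np.arange(1.25, 50.25))[:n2]
        u_or, p_or = exact_ranksum_enumeration(a, b, alternative)
        res = oc.compare_tract_lengths(a, b, alternative=alternative,
                                       method="exact")
        assert res.statistic == pytest.approx(u_or, abs=1e-12)
        assert res.pvalue == pytest.approx(p_or, abs=1e-9)

    def test_doubled_median_is_detected_at_study_scale(self):
        # mutant-like 2x tract-length shift at the study's event counts
        rng = np.random.default_rng(40)
        p_wt = 1 - 0.5 ** (1 / 1000.0)
        p_mut = 1 - 0.5 ** (1 / 2100.0)
        wt = rng.geometric(p_wt, size=600)
        mut = rng.geometric(p_mut, size=300)
        res = oc.compare_tract_lengths(wt, mut)
        assert res.pvalue < 5e-5


# ---- summaries -------------------------------------------------------------

class TestSummarize:
    def events(self, rows):
        cols = ["genotype", "meiosis", "type", "category", "n_markers",
                "len_min", "len_mid", "len_max"]
        return pd.DataFrame(rows, columns=cols)

    def test_single_event_median_equals_mean(self):
        ev = self.events([("WT", "m1", "NCO", "SDSA_like_hDNA", 3,
                           800.0, 900.0, 1000.0)])
        s = oc.summarize(ev, "mid")
        row = s.tract_table.iloc[0]
        assert row["median_bp"] == row["mean_bp"] == 900.0

    def test_per_meiosis_count_mean_and_se(self):
        rows = [("WT", "m1", "CO", "none", 1, 1.0, 1.0, 1.0)] * 80
        rows += [("WT", "m2", "CO", "none", 1, 1.0, 1.0, 1.0)] * 100
        s = oc.summarize(self.events(rows))
        co = s.count_table[s.count_table["type"] == "CO"].iloc[0]
        assert co["mean_per_meiosis"] == 90.0
        assert co["se"] == pytest.approx(10.0)

    def test_symmetric_hdna_tallied_separately(self):
        rows = [("WT", "m1", "NCO", "symmetric_hDNA", 2, 500.0, 560.0, 620.0),
                ("WT", "m1", "NCO", "SDSA_like_hDNA", 2, 700.0, 800.0, 900.0)]
        s = oc.summarize(self.events(rows))
        sym = s.symmetric_table.iloc[0]
        assert sym["n_events"] == 1 and sym["mean_bp"] == 560.0

    def test_simulated_wild_type_median_tracks_observable_truth(self, roundtrip_cohort):
        # tracts covering no marker are invisible, so the observable tract
        # sample is length-biased; the summary median must track the median
        # of the ground-truth tracts that cover at least one marker
        frames, true_detected = [], []
        for k, (_, truth, records) in enumerate(roundtrip_cohort):
            df = oc.events_to_frame(records)
            df["genotype"] = "WT"
            df["meiosis"] = f"m{k}"
            frames.append(df)
            for e in truth.events:
                if e.kind == "CO" and e.segments and e.n_markers >= 1:
                    true_detected.append(
                        max(s.end_bp for s in e.segments)
                        - min(s.start_bp for s in e.segments) + 1)
        s = oc.summarize(pd.concat(frames, ignore_index=True), "mid")
        co = s.tract_table.query("type == 'CO'").iloc[0]
        assert co["n"] >= 300
        assert co["median_bp"] == pytest.approx(np.median(true_detected), rel=0.15)
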