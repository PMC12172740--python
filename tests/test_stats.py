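"""Effect sizes, rank tests, similarity, cluster permutation, SME, ANOVA."""

import itertools
import math

import numpy as np
import pytest

import erpbench as eb
from erpbench.core import EpochSet, ERPWaveform
from erpbench.montage import standard_montage_32
from erpbench.stats import (
    ClusterStatMap,
    _label_clusters,
    _max_cluster_mass,
    _paired_t,
    anova_sme,
    assess_normality,
    bootstrap_sme,
    cluster_permutation_test,
    cohens_d_one_sample,
    erp_similarity,
    ranksum_test,
)


class TestCohensD:
    def test_matches_mean_over_sd(self, rng):
        x = rng.normal(2.0, 5.0, size=200)
        d, (lo, hi) = cohens_d_one_sample(x)
        assert d == pytest.approx(x.mean() / x.std(ddof=1))
        assert lo < d < hi

    def test_zero_mean_gives_zero(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        d, _ = cohens_d_one_sample(x)
        assert d == 0.0

    def test_monotone_in_mean_at_fixed_sd(self, rng):
        base = rng.normal(0.0, 1.0, size=50)
        base = (base - base.mean()) / base.std(ddof=1)  # mean 0, sd 1
        ds = [cohens_d_one_sample(base + mu)[0] for mu in (0.2, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(ds, ds[1:]))

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError, match="standard deviation"):
            cohens_d_one_sample(np.full(10, 3.0))


class TestRanksum:
    def test_sample_vs_itself_p_one(self):
        x = np.arange(8.0)
        z, p = ranksum_test(x, x)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2,seed", [(4, 4, 0), (5, 7, 1), (8, 6, 2)])
    def test_against_exact_enumeration(self, n1, n2, seed):
        """Normal-approximation p stays close to the exact permutation p
        obtained by enumerating all rank assignments (no ties, n <= 8)."""
        rng = np.random.default_rng(seed)
        x = rng.normal(0.8, 1.0, n1)
        y = rng.normal(0.0, 1.0, n2)
        _, p_approx = ranksum_test(x, y)

        # exact two-sided p by enumeration of C(n1+n2, n1) rank splits
        ranks = np.arange(1, n1 + n2 + 1)
        w_obs = np.argsort(np.argsort(np.concatenate([x, y])))[:n1].sum() + n1
        mu = n1 * (n1 + n2 + 1) / 2.0
        count = 0
        total = 0
        for combo in itertools.combinations(ranks, n1):
            total += 1
            if abs(sum(combo) - mu) >= abs(w_obs - mu) - 1e-12:
                count += 1
        p_exact = count / total
        assert p_approx == pytest.approx(p_exact, abs=0.05)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            ranksum_test(np.array([]), np.array([1.0]))


class TestSimilarity:
    def _erps(self, montage, data):
        times = np.arange(-100, 500) * 2.0
        return ERPWaveform(data=data, times=times, condition="difference",
                           montage=montage)

    def test_identical_gives_one(self, montage, rng):
        data = rng.standard_normal((montage.n_channels, 600))
        a = {"s1": self._erps(montage, data)}
        b = {"s1": self._erps(montage, data.copy())}
        sim = erp_similarity(a, b)
        assert sim.per_subject["s1"] == pytest.approx(1.0)

    def test_negated_gives_minus_one(self, montage, rng):
        data = rng.standard_normal((montage.n_channels, 600))
        sim = erp_similarity({"s": self._erps(montage, data)},
                             {"s": self._erps(montage, -data)})
        assert sim.per_subject["s"] == pytest.approx(-1.0)

    def test_location_and_positive_scale_invariance(self, montage, rng):
        data = rng.standard_normal((montage.n_channels, 600))
        scaled = data * 3.7 + 11.0
        sim = erp_similarity({"s": self._erps(montage, data)},
                             {"s": self._erps(montage, scaled)})
        assert sim.per_subject["s"] == pytest.approx(1.0)

    def test_zero_variance_channel_excluded(self, montage, rng):
        data = rng.standard_normal((montage.n_channels, 600))
        flat = data.copy()
        flat[0] = 5.0
        sim = erp_similarity({"s": self._erps(montage, data)},
                             {"s": self._erps(montage, flat)})
        assert sim.n_channels_excluded == 1


class TestNormality:
    def test_large_normal_sample_passes(self, rng):
        stat, p = assess_normality(rng.normal(3.0, 2.0, size=500))
        assert 0 <= stat <= 1
        assert p > 0.05

    def test_degenerate_sample_raises(self):
        with pytest.raises(ValueError, match="identical"):
            assess_normality(np.full(10, 1.0))


def _small_montage(n=8):
    labels = ["FCz", "FC1", "FC2", "Cz", "Fz", "CP1", "CP2", "Pz"][:n]
    return standard_montage_32().subset(labels)


def _erp_dict(maps, montage):
    times = np.arange(maps.shape[-1]) * 2.0
    return {
        f"s{i}": ERPWaveform(data=maps[i], times=times, condition="difference",
                             montage=montage)
        for i in range(maps.shape[0])
    }


class TestClusterPermutation:
    def test_identical_inputs_give_no_clusters(self, rng):
        mont = _small_montage()
        maps = rng.standard_normal((6, mont.n_channels, 40))
        a = _erp_dict(maps, mont)
        b = _erp_dict(maps.copy(), mont)
        result = cluster_permutation_test(a, b, mont, n_perm=50, seed=0)
        assert result.cluster_masses.size == 0

    def test_monte_carlo_matches_full_enumeration(self, rng):
        """n=6 subjects: the sign-flip null can be enumerated exactly (64
        patterns); Monte-Carlo p must agree within binomial error."""
        mont = _small_montage()
        n_sub = 6
        diffs = rng.standard_normal((n_sub, mont.n_channels, 20)) * 0.6
        diffs += 0.9  # common offset to create clusters
        a = _erp_dict(diffs, mont)
        zeros = _erp_dict(np.zeros_like(diffs), mont)
        n_perm = 2000
        result = cluster_permutation_test(a, zeros, mont, n_perm=n_perm, seed=1)
        assert result.cluster_masses.size >= 1
        obs = np.abs(result.cluster_masses).max()

        import scipy.stats as sps

        threshold = result.threshold
        adjacency = mont.adjacency()
        count = 0
        patterns = list(itertools.product([-1.0, 1.0], repeat=n_sub))
        for flips in patterns:
            t_perm = _paired_t(diffs * np.array(flips)[:, None, None])
            if _max_cluster_mass(t_perm, threshold, adjacency) >= obs:
                count += 1
        p_exact = count / len(patterns)
        k = np.argmax(np.abs(result.cluster_masses))
        p_mc = result.cluster_p[k]
        se = math.sqrt(p_exact * (1 - p_exact) / n_perm) if 0 < p_exact < 1 else 0.0
        assert abs(p_mc - p_exact) <= max(3 * se, 2.5 / (n_perm + 1))

    def test_injected_effect_recovered(self, rng):
        """A strong effect on 5 adjacent channels x 300-500 ms yields a
        significant cluster covering >= 80% of the injected region."""
        mont = standard_montage_32()
        n_sub, n_t = 12, 300  # 0..598 ms at 500 Hz
        times = np.arange(n_t) * 2.0
        maps = rng.standard_normal((n_sub, mont.n_channels, n_t))
        chans = [mont.index(c) for c in ("FCz", "FC1", "FC2", "Cz", "Fz")]
        t_mask = (times >= 300) & (times <= 500)
        region = np.zeros((mont.n_channels, n_t), dtype=bool)
        region[np.ix_(chans, np.flatnonzero(t_mask))] = True
        maps[:, region] += 3.0
        a = _erp_dict(maps, mont)
        b = _erp_dict(np.zeros_like(maps), mont)
        result = cluster_permutation_test(a, b, mont, n_perm=200, seed=3)
        sig = result.significant_mask(alpha=0.05)
        coverage = (sig & region).sum() / region.sum()
        assert coverage >= 0.8

    def test_too_few_subjects_raises(self, rng):
        mont = _small_montage()
        maps = rng.standard_normal((2, mont.n_channels, 10))
        with pytest.raises(ValueError, match="3"):
            cluster_permutation_test(_erp_dict(maps, mont),
                                     _erp_dict(maps, mont), mont)


def _epochs_from_trials(trials, montage_1ch, fs=500.0):
    n_trials, n_samp = trials.shape
    times = np.arange(n_samp) * 1000.0 / fs  # 0 .. end, covers 200-400 ms
    return EpochSet(
        data=trials[:, None, :], times=times,
        conditions=np.array(["gain"] * n_trials), fs=fs, montage=montage_1ch,
    )


class TestBootstrapSme:
    @pytest.fixture()
    def fcz_montage(self, montage):
        return montage.subset(["FCz"])

    def test_identical_trials_give_zero(self, fcz_montage):
        trials = np.tile(np.sin(np.arange(300) / 20.0), (10, 1))
        epochs = _epochs_from_trials(trials, fcz_montage)
        assert bootstrap_sme(epochs, "gain", n_boot=200, seed=0) < 1e-12

    def test_analytic_standard_error_of_constant_trials(self, rng, fcz_montage):
        """Constant waveforms with iid N(0, σ²) amplitudes: the SME of the
        mean-based score converges to σ/√n."""
        sigma, n = 4.0, 30
        amps = rng.normal(0.0, sigma, size=n)
        trials = np.tile(amps[:, None], (1, 300))
        epochs = _epochs_from_trials(trials, fcz_montage)
        sme = bootstrap_sme(epochs, "gain", n_boot=1000, seed=7)
        expected = amps.std(ddof=0) / math.sqrt(n)
        assert sme == pytest.approx(expected, rel=0.10)

    def test_seeded_determinism(self, rng, fcz_montage):
        trials = rng.standard_normal((12, 300))
        epochs = _epochs_from_trials(trials, fcz_montage)
        s1 = bootstrap_sme(epochs, "gain", n_boot=300, seed=5)
        s2 = bootstrap_sme(epochs, "gain", n_boot=300, seed=5)
        assert s1 == s2

    def test_too_few_trials_raises(self, fcz_montage):
        epochs = _epochs_from_trials(np.zeros((1, 300)), fcz_montage)
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_sme(epochs, "gain")


class TestAnovaSme:
    def test_identical_groups_give_f_zero(self):
        g = np.array([1.0, 2.0, 3.0])
        f, (dfb, dfw), p = anova_sme({"a": g, "b": g.copy()})
        assert f == pytest.approx(0.0)
        assert (dfb, dfw) == (1, 4)

    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 25)
        f, _, p_f = anova_sme({"a": x, "b": y})
        import scipy.stats as sps

        t, p_t = sps.ttest_ind(x, y)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_df_reporting(self, rng):
        groups = {k: rng.normal(size=10) for k in "abcd"}
        _, (dfb, dfw), _ = anova_sme(groups)
        assert (dfb, dfw) == (3, 36)

    def test_degenerate_groups_raise(self):
        with pytest.raises(ValueError):
            anova_sme({"a": np.array([1.0])})
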