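"""Cross-pipeline comparison battery.

Quantifies (dis)agreement between preprocessing pipeline variants run on
the same cohort:

* one-sample Cohen's d (mean/SD across subjects) with a normal-theory CI;
* unpaired Wilcoxon rank-sum tests per feature per pipeline pair, Bonferroni
  corrected over the number of pairs;
* whole-scalp ERP similarity: per subject, Pearson r per channel averaged
  over channels, summarized as cohort mean ± SD;
* one-sample Kolmogorov-Smirnov normality check preceding Pearson use;
* channel x time cluster-based permutation test with subject-level
  sign-flip permutations and max-cluster-mass family-wise error control;
* bootstrap standardized measurement error (SME) of an ERP score, and a
  one-way ANOVA on SME across pipelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import EpochSet, ERPWaveform
from .montage import Montage

__all__ = [
    "ClusterStatMap",
    "SimilarityResult",
    "cohens_d_one_sample",
    "pairwise_ranksum",
    "erp_similarity",
    "assess_normality",
    "cluster_permutation_test",
    "bootstrap_sme",
    "anova_sme",
]


def cohens_d_one_sample(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    """One-sample Cohen's d = mean/SD with its 95% CI.

    The CI uses the normal-approximation standard error
    ``sqrt(1/n + d**2 / (2n))``.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values for an effect size")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: effect size undefined")
    d = values.mean() / sd
    se = math.sqrt(1.0 / n + d**2 / (2.0 * n))
    return float(d), (float(d - 1.96 * se), float(d + 1.96 * se))


def ranksum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum via the normal approximation with tie
    correction. Returns (z, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = ranks[:n1].sum()
    mu = n1 * (n2 + n1 + 1) / 2.0
    # tie-corrected variance of the rank sum
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / ((n * (n - 1)) if n > 1 else 1.0)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    # continuity-corrected normal approximation
    delta = max(abs(w - mu) - 0.5, 0.0)
    z = math.copysign(delta, w - mu) / math.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def pairwise_ranksum(
    feature_tables: dict[str, "pd.DataFrame"],  # noqa: F821
    metrics: tuple[str, ...] = (
        "peak_time_ms", "mean_peak_uv", "max_peak_uv", "base_to_peak_uv",
    ),
    scope: str = "difference",
    alpha: float = 0.01,
) -> "pd.DataFrame":  # noqa: F821
    """Rank-sum tests for every metric and unordered pipeline pair.

    Significance is assessed at ``alpha / m`` with ``m = C(k, 2)`` pairs
    (m = 6 for four pipelines).
    """
    import pandas as pd

    names = sorted(feature_tables)
    if len(names) < 2:
        raise ValueError("need at least two pipelines to compare")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    m = len(pairs)
    rows = []
    for metric in metrics:
        for a, b in pairs:
            ta = feature_tables[a]
            tb = feature_tables[b]
            va = ta.loc[ta["scope"] == scope, metric].to_numpy()
            vb = tb.loc[tb["scope"] == scope, metric].to_numpy()
            z, p = ranksum_test(va, vb)
            rows.append(
                {
                    "metric": metric,
                    "pipeline_a": a,
                    "pipeline_b": b,
                    "z": z,
                    "p": p,
                    "alpha_corrected": alpha / m,
                    "significant": p < alpha / m,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SimilarityResult:
    """Per-subject whole-scalp ERP similarity between two pipelines."""

    pipeline_a: str
    pipeline_b: str
    scope: str
    per_subject: dict[str, float]
    n_channels_excluded: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_subject.values())))

    @property
    def sd(self) -> float:
        return float(np.std(list(self.per_subject.values()), ddof=1))


def erp_similarity(
    erps_a: dict[str, ERPWaveform],
    erps_b: dict[str, ERPWaveform],
    scope: str = "difference",
    pipeline_a: str = "A",
    pipeline_b: str = "B",
) -> SimilarityResult:
    """Mean-over-channels Pearson correlation per shared subject.

    ``erps_a``/``erps_b`` map subject id to that subject's ERP of the given
    scope under each pipeline. Channels with zero variance under either
    pipeline are excluded from the channel average (count reported).
    """
    shared = sorted(set(erps_a) & set(erps_b))
    if not shared:
        raise ValueError("no shared subjects between the two pipelines")
    per_subject: dict[str, float] = {}
    excluded = 0
    for sid in shared:
        wa, wb = erps_a[sid], erps_b[sid]
        if wa.data.shape != wb.data.shape:
            raise ValueError(f"subject {sid}: ERP shapes differ between pipelines")
        rs = []
        for c in range(wa.data.shape[0]):
            xa, xb = wa.data[c], wb.data[c]
            if xa.std() == 0 or xb.std() == 0:
                excluded += 1
                continue
            rs.append(np.corrcoef(xa, xb)[0, 1])
        per_subject[sid] = float(np.mean(rs))
    return SimilarityResult(
        pipeline_a=pipeline_a,
        pipeline_b=pipeline_b,
        scope=scope,
        per_subject=per_subject,
        n_channels_excluded=excluded,
    )


def assess_normality(values: np.ndarray) -> tuple[float, float]:
    """One-sample KS statistic and p against N(sample mean, sample SD)."""
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 values for the KS check")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: all values identical")
    stat, p = sps.kstest(values, "norm", args=(values.mean(), sd))
    return float(stat), float(p)


@dataclass
class ClusterStatMap:
    """Result of the channel x time cluster permutation test."""

    t_map: np.ndarray  # channels x samples paired t statistic
    cluster_labels: np.ndarray  # 0 = background, 1..k cluster ids
    cluster_masses: np.ndarray  # summed t per cluster (signed)
    cluster_p: np.ndarray  # permutation p per cluster
    n_permutations: int
    threshold: float
    null_max_mass: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        mask = np.zeros_like(self.cluster_labels, dtype=bool)
        for k, p in enumerate(self.cluster_p, start=1):
            if p < alpha:
                mask |= self.cluster_labels == k
        return mask


def _label_clusters(supra: np.ndarray, adjacency: np.ndarray) -> np.ndarray:
    """Connected components over (channel, time) with temporal adjacency
    along rows and spatial adjacency across simultaneous samples."""
    n_ch, n_t = supra.shape
    labels = np.zeros((n_ch, n_t), dtype=int)
    neighbors = [np.flatnonzero(adjacency[c]) for c in range(n_ch)]
    current = 0
    for c in range(n_ch):
        for t in range(n_t):
            if not supra[c, t] or labels[c, t]:
                continue
            current += 1
            stack = [(c, t)]
            labels[c, t] = current
            while stack:
                ci, ti = stack.pop()
                if ti > 0 and supra[ci, ti - 1] and not labels[ci, ti - 1]:
                    labels[ci, ti - 1] = current
                    stack.append((ci, ti - 1))
                if ti + 1 < n_t and supra[ci, ti + 1] and not labels[ci, ti + 1]:
                    labels[ci, ti + 1] = current
                    stack.append((ci, ti + 1))
                for cj in neighbors[ci]:
                    if supra[cj, ti] and not labels[cj, ti]:
                        labels[cj, ti] = current
                        stack.append((cj, ti))
    return labels


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t over axis 0 of subjects x channels x samples differences."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _max_cluster_mass(
    t_map: np.ndarray, threshold: float, adjacency: np.ndarray
) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        supra = sign * t_map > threshold
        if not supra.any():
            continue
        labels = _label_clusters(supra, adjacency)
        for k in range(1, labels.max() + 1):
            mass = abs(t_map[labels == k].sum())
            best = max(best, mass)
    return best


def cluster_permutation_test(
    erps_a: dict[str, ERPWaveform],
    erps_b: dict[str, ERPWaveform],
    montage: Montage,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterStatMap:
    """Paired channel x time cluster permutation test between two pipelines.

    Subject-wise A−B difference maps are reduced to paired t statistics;
    samples beyond the two-tailed t threshold at ``cluster_alpha`` are
    clustered by temporal adjacency within a channel plus montage spatial
    adjacency across channels, and each cluster's mass is its summed t.
    The null is built by randomly sign-flipping whole subjects; each
    cluster's p is ``(1 + #{permutation max mass >= observed}) / (n_perm + 1)``.
    """
    shared = sorted(set(erps_a) & set(erps_b))
    if len(shared) < 3:
        raise ValueError("cluster test requires at least 3 paired subjects")
    diffs = np.stack([erps_a[s].data - erps_b[s].data for s in shared])
    n_sub = diffs.shape[0]
    threshold = float(sps.t.ppf(1 - cluster_alpha / 2, df=n_sub - 1))
    adjacency = montage.adjacency()

    t_obs = _paired_t(diffs)
    labels = np.zeros_like(t_obs, dtype=int)
    masses: list[float] = []
    next_label = 0
    for sign in (1.0, -1.0):
        supra = sign * t_obs > threshold
        if not supra.any():
            continue
        sub_labels = _label_clusters(supra, adjacency)
        for k in range(1, sub_labels.max() + 1):
            next_label += 1
            labels[sub_labels == k] = next_label
            masses.append(float(t_obs[sub_labels == k].sum()))
    masses_arr = np.array(masses)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_sub)
        t_perm = _paired_t(diffs * flips[:, None, None])
        null_max[i] = _max_cluster_mass(t_perm, threshold, adjacency)

    cluster_p = np.array(
        [
            (1 + np.sum(null_max >= abs(mass))) / (n_perm + 1)
            for mass in masses_arr
        ]
    )
    return ClusterStatMap(
        t_map=t_obs,
        cluster_labels=labels,
        cluster_masses=masses_arr,
        cluster_p=cluster_p,
        n_permutations=n_perm,
        threshold=threshold,
        null_max_mass=null_max,
    )


def bootstrap_sme(
    epochs: EpochSet,
    condition: str,
    channel: str = "FCz",
    n_boot: int = 1000,
    seed: int = 0,
    search_ms: tuple[float, float] = (200.0, 400.0),
) -> float:
    """Bootstrap standardized measurement error of the mean-peak score.

    Accepted trials of the condition are resampled with replacement (same
    n) ``n_boot`` times; each resample is averaged into an ERP whose
    mean-peak score (±46 ms around the within-window peak) is computed at
    the designated channel. The SME is the standard deviation of those
    scores.
    """
    idx = epochs.accepted_of(condition)
    if idx.size < 2:
        raise ValueError(
            f"need at least 2 accepted {condition!r} trials for the SME"
        )
    ch = epochs.montage.index(channel)
    trials = epochs.data[idx, ch, :]  # trials x samples
    times = epochs.times
    rng = np.random.default_rng(seed)
    in_window = (times >= search_ms[0]) & (times <= search_ms[1])
    win_idx = np.flatnonzero(in_window)

    scores = np.empty(n_boot)
    draws = rng.integers(0, idx.size, size=(n_boot, idx.size))
    for b in range(n_boot):
        erp = trials[draws[b]].mean(axis=0)
        peak_i = win_idx[np.argmax(erp[win_idx])]
        peak_t = times[peak_i]
        m = (times >= peak_t - 46.0) & (times <= peak_t + 46.0)
        scores[b] = erp[m].mean()
    return float(scores.std(ddof=1))


def anova_sme(sme_by_pipeline: dict[str, np.ndarray]) -> tuple[float, tuple[int, int], float]:
    """One-way fixed-effects ANOVA of per-subject SME across pipelines.

    Returns (F, (df_between, df_within), p).
    """
    groups = [np.asarray(v, dtype=float) for v in sme_by_pipeline.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 pipelines with >= 2 subjects each")
    k = len(groups)
    n_total = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else math.inf
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w)) if math.isfinite(f) else 0.0
    return float(f), (df_b, df_w), p
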