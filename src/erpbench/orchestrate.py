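"""End-to-end runs, comparison reports, and the filter-swap experiment.

``run_variant`` drives one pipeline variant over a cohort: per-subject
bad-channel detection, second pass, inclusion filter, grand averages.
``compare_variants`` joins two or more completed runs on their shared
included subjects and computes the full comparison battery: effect sizes,
pairwise rank-sum tests, whole-scalp similarity, cluster permutation maps,
and the bootstrap-SME table with its one-way ANOVA.

Outputs are plain text: per-subject JSON run records, ERPs as TSV
(time_ms + one column per channel), reports as JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EpochSet, ERPWaveform, Recording
from .features import extract_feature_table
from .filters import (
    apply_zero_phase,
    design_butterworth_bandpass,
    design_fir_hamming,
    design_fir_kaiser,
)
from .montage import Montage
from .pipeline import (
    SubjectResult,
    detect_bad_channels_two_pass,
    run_second_pass,
)
from .stats import (
    anova_sme,
    bootstrap_sme,
    cluster_permutation_test,
    cohens_d_one_sample,
    erp_similarity,
    pairwise_ranksum,
)
from .variants import VariantConfig

__all__ = [
    "VariantRun",
    "ComparisonReport",
    "run_variant",
    "compare_variants",
    "filter_swap_experiment",
    "grand_average",
    "write_erp_tsv",
    "read_erp_tsv",
    "validate_report",
]

logger = logging.getLogger(__name__)


@dataclass
class VariantRun:
    """All per-subject outcomes of one variant over one cohort."""

    variant: VariantConfig
    results: dict[str, SubjectResult]

    @property
    def included_subjects(self) -> list[str]:
        return sorted(
            s for s, r in self.results.items() if r.included and r.erps is not None
        )

    def erps_of(self, scope: str) -> dict[str, ERPWaveform]:
        return {
            s: self.results[s].erps[scope] for s in self.included_subjects
        }

    def erps_by_subject(self) -> dict[str, dict[str, ERPWaveform]]:
        return {s: self.results[s].erps for s in self.included_subjects}

    def grand_average(self, scope: str) -> ERPWaveform:
        return grand_average(list(self.erps_of(scope).values()), scope)

    def feature_table(self, channel: str = "FCz") -> pd.DataFrame:
        return extract_feature_table(self.erps_by_subject(), channel=channel)


def grand_average(erps: list[ERPWaveform], scope: str) -> ERPWaveform:
    """Mean ERP across subjects (equal subject weights)."""
    if not erps:
        raise ValueError("no ERPs to grand-average")
    ref = erps[0]
    data = np.mean([e.data for e in erps], axis=0)
    return ERPWaveform(
        data=data,
        times=ref.times.copy(),
        condition=scope,
        montage=ref.montage,
        n_trials=0,
        subject_id="grand_average",
    )


def _reduce_to_channel(epochs: EpochSet, channel: str) -> EpochSet:
    ci = epochs.montage.index(channel)
    return EpochSet(
        data=epochs.data[:, ci : ci + 1, :],
        times=epochs.times.copy(),
        conditions=epochs.conditions.copy(),
        fs=epochs.fs,
        montage=epochs.montage.subset([channel]),
        subject_id=epochs.subject_id,
        accepted=epochs.accepted.copy(),
        channel_violations=epochs.channel_violations[:, ci : ci + 1].copy(),
    )


def run_variant(
    cohort: list[Recording],
    variant: VariantConfig,
    out_dir: str | Path | None = None,
    min_trials_per_condition: int = 15,
    keep_epochs: str | bool = "fcz",
) -> VariantRun:
    """Run one variant end to end over a cohort.

    Per subject: bad-channel detection under the variant's policy, then the
    second pass from the raw recording. Stage failures are recorded per
    subject and the run continues. ``keep_epochs`` controls what trial-level
    data stay in memory: ``"fcz"`` (default) keeps only the feature channel
    (enough for the SME), ``True`` keeps everything, ``False`` drops epochs.
    """
    results: dict[str, SubjectResult] = {}
    for rec in cohort:
        try:
            if variant.policy().method == "two_pass_rejection_rate":
                bad = detect_bad_channels_two_pass(
                    rec,
                    band_filter=variant.band_filter(rec.fs),
                    notch_filter=variant.notch_filter(rec.fs),
                    criteria=variant.criteria(),
                    policy=variant.policy(),
                )
            else:
                bad = detect_bad_channels_two_pass(rec, policy=variant.policy())
            res = run_second_pass(
                rec, bad, variant, min_trials_per_condition=min_trials_per_condition
            )
        except Exception as exc:  # keep going; the run report records it
            logger.warning("%s failed under %s: %s", rec.subject_id, variant.name, exc)
            res = SubjectResult(
                subject_id=rec.subject_id,
                bad_channels=[],
                epochs=None,
                erps=None,
                included=False,
                error=str(exc),
            )
        if res.epochs is not None:
            if keep_epochs == "fcz":
                res.epochs = _reduce_to_channel(res.epochs, "FCz")
            elif not keep_epochs:
                res.epochs = None
        results[rec.subject_id] = res
        logger.info(
            "%s | %s | bad=%s accepted=%s included=%s",
            variant.name, rec.subject_id, res.bad_channels,
            res.accepted_counts, res.included,
        )
    run = VariantRun(variant=variant, results=results)
    if out_dir is not None:
        write_run(run, out_dir)
    return run


def write_erp_tsv(erp: ERPWaveform, path: str | Path) -> None:
    df = pd.DataFrame(erp.data.T, columns=list(erp.montage.channel_names))
    df.insert(0, "time_ms", erp.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_erp_tsv(path: str | Path, montage: Montage, condition: str) -> ERPWaveform:
    df = pd.read_csv(path, sep="\t")
    names = [c for c in df.columns if c != "time_ms"]
    sub = montage.subset(names)
    return ERPWaveform(
        data=df[names].to_numpy().T,
        times=df["time_ms"].to_numpy(),
        condition=condition,
        montage=sub,
        subject_id=Path(path).stem,
    )


def write_run(run: VariantRun, out_dir: str | Path) -> Path:
    """Write per-subject records and ERP TSVs under ``out_dir/<variant>``."""
    root = Path(out_dir) / run.variant.name
    root.mkdir(parents=True, exist_ok=True)
    records = {s: r.to_record() for s, r in sorted(run.results.items())}
    (root / "run_records.json").write_text(json.dumps(records, indent=2))
    for s in run.included_subjects:
        for scope, erp in run.results[s].erps.items():
            write_erp_tsv(erp, root / f"{s}_{scope}.tsv")
    for scope in ("gain", "loss", "difference"):
        if run.included_subjects:
            write_erp_tsv(run.grand_average(scope), root / f"grand_{scope}.tsv")
    return root


@dataclass
class ComparisonReport:
    """The full cross-variant comparison battery, JSON-serializable."""

    pipelines: list[str]
    n_shared_subjects: int
    effect_sizes: dict = field(default_factory=dict)
    ranksum: list = field(default_factory=list)
    similarity: list = field(default_factory=list)
    clusters: dict = field(default_factory=dict)
    sme: dict = field(default_factory=dict)
    anova: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "pipelines": self.pipelines,
            "n_shared_subjects": self.n_shared_subjects,
            "effect_sizes": self.effect_sizes,
            "ranksum": self.ranksum,
            "similarity": self.similarity,
            "clusters": self.clusters,
            "sme": self.sme,
            "anova": self.anova,
        }
        return json.dumps(payload, indent=2)


_REPORT_SCHEMA: dict[str, type] = {
    "pipelines": list,
    "n_shared_subjects": int,
    "effect_sizes": dict,
    "ranksum": list,
    "similarity": list,
    "clusters": dict,
    "sme": dict,
    "anova": dict,
}


def validate_report(payload: dict) -> None:
    """Check a serialized report against the shipped schema (key + type)."""
    for key, typ in _REPORT_SCHEMA.items():
        if key not in payload:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(payload[key], typ):
            raise ValueError(
                f"report key {key!r} has type {type(payload[key]).__name__}, "
                f"expected {typ.__name__}"
            )


def compare_variants(
    runs: dict[str, VariantRun],
    n_perm: int = 500,
    seed: int = 0,
    sme_n_boot: int = 1000,
    cluster_scopes: tuple[str, ...] = ("difference",),
    similarity_scopes: tuple[str, ...] = ("gain", "loss", "difference"),
) -> ComparisonReport:
    """Join >= 2 completed runs on shared included subjects and compare.

    Effect sizes and rank-sum tests use the four ERP features; similarity,
    cluster maps and SME work on the ERP waveforms and trial data. The
    Bonferroni factor of the rank-sum battery is the number of pipeline
    pairs (6 for four pipelines).
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to compare")
    names = sorted(runs)
    shared = set.intersection(*(set(runs[n].included_subjects) for n in names))
    if not shared:
        raise ValueError("no subject included under every pipeline variant")
    shared = sorted(shared)

    feature_tables = {}
    for n in names:
        tab = runs[n].feature_table()
        feature_tables[n] = tab[tab["subject_id"].isin(shared)].reset_index(drop=True)

    report = ComparisonReport(pipelines=names, n_shared_subjects=len(shared))

    metric_scopes = {
        "mean_peak_uv": ("gain", "loss", "difference"),
        "max_peak_uv": ("difference",),
        "base_to_peak_uv": ("difference",),
    }
    for n in names:
        tab = feature_tables[n]
        report.effect_sizes[n] = {}
        for metric, scopes in metric_scopes.items():
            for scope in scopes:
                vals = tab.loc[tab["scope"] == scope, metric].to_numpy()
                try:
                    d, ci = cohens_d_one_sample(vals)
                except ValueError:
                    continue
                report.effect_sizes[n][f"{scope}:{metric}"] = {
                    "d": d, "ci_low": ci[0], "ci_high": ci[1],
                }

    report.ranksum = pairwise_ranksum(feature_tables).to_dict(orient="records")

    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    for scope in similarity_scopes:
        for a, b in pairs:
            sim = erp_similarity(
                runs[a].erps_of(scope), runs[b].erps_of(scope),
                scope=scope, pipeline_a=a, pipeline_b=b,
            )
            report.similarity.append(
                {
                    "pipeline_a": a, "pipeline_b": b, "scope": scope,
                    "mean": sim.mean, "sd": sim.sd,
                    "n_channels_excluded": sim.n_channels_excluded,
                }
            )

    montage = next(iter(runs.values())).results[shared[0]].erps["gain"].montage
    rng = np.random.default_rng(seed)
    for scope in cluster_scopes:
        for a, b in pairs:
            cmap = cluster_permutation_test(
                runs[a].erps_of(scope), runs[b].erps_of(scope), montage,
                n_perm=n_perm, seed=int(rng.integers(0, 2**31 - 1)),
            )
            report.clusters[f"{a}|{b}|{scope}"] = {
                "n_clusters": int(cmap.cluster_masses.size),
                "masses": cmap.cluster_masses.tolist(),
                "p_values": cmap.cluster_p.tolist(),
                "min_p": float(cmap.cluster_p.min()) if cmap.cluster_p.size else None,
                "n_permutations": cmap.n_permutations,
            }

    sme_values: dict[str, dict[str, dict[str, float]]] = {}
    for n in names:
        sme_values[n] = {"gain": {}, "loss": {}}
        for s in shared:
            epochs = runs[n].results[s].epochs
            if epochs is None:
                continue
            for cond in ("gain", "loss"):
                sme_values[n][cond][s] = bootstrap_sme(
                    epochs, cond, channel="FCz", n_boot=sme_n_boot,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
    report.sme = sme_values

    pooled = {
        n: np.array(
            [v for cond in ("gain", "loss") for v in sme_values[n][cond].values()]
        )
        for n in names
    }
    if all(v.size >= 2 for v in pooled.values()):
        f_stat, (df_b, df_w), p = anova_sme(pooled)
        report.anova = {"F": f_stat, "df_between": df_b, "df_within": df_w, "p": p}

    return report


_SWAP_FAMILIES = ("butterworth_iir", "fir_hamming", "fir_kaiser")


def filter_swap_experiment(
    cohort: list[Recording],
    band_hz: tuple[float, float] = (0.1, 30.0),
    families: tuple[str, ...] = _SWAP_FAMILIES,
) -> pd.DataFrame:
    """Filter the continuous (unepoched) recordings with each band-pass
    family and report the mean per-channel Pearson correlation between each
    pair of filtered outputs, averaged over channels and subjects."""
    low, high = band_hz
    corr_sums = {}
    count = 0
    for rec in cohort:
        specs = {}
        for fam in families:
            if fam == "butterworth_iir":
                specs[fam] = design_butterworth_bandpass(low, high, 4, rec.fs)
            elif fam == "fir_hamming":
                specs[fam] = design_fir_hamming(low, high, rec.fs)
            elif fam == "fir_kaiser":
                specs[fam] = design_fir_kaiser(low, high, rec.fs)
            else:
                raise ValueError(f"unknown family {fam!r} for the filter swap")
        filtered = {fam: apply_zero_phase(rec.data, spec) for fam, spec in specs.items()}
        for i, fa in enumerate(families):
            for fb in families[i:]:
                xa, xb = filtered[fa], filtered[fb]
                rs = [
                    np.corrcoef(xa[c], xb[c])[0, 1] for c in range(xa.shape[0])
                ]
                corr_sums[(fa, fb)] = corr_sums.get((fa, fb), 0.0) + float(np.mean(rs))
        count += 1
    table = pd.DataFrame(
        np.eye(len(families)), index=list(families), columns=list(families)
    )
    for (fa, fb), total in corr_sums.items():
        table.loc[fa, fb] = total / count
        table.loc[fb, fa] = total / count
    return table
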