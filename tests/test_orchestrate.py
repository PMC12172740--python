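"""Variant registry, end-to-end runs, comparison report, filter swap, CLI."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

import erpbench as eb
from erpbench.orchestrate import (
    compare_variants,
    filter_swap_experiment,
    read_erp_tsv,
    run_variant,
    validate_report,
    write_run,
)
from erpbench.variants import (
    REGISTRY,
    get_variant,
    load_variants_yaml,
    variant_from_dict,
)


class TestVariantRegistry:
    def test_four_variants_resolve(self):
        assert set(REGISTRY) == {
            "reference", "eeglab_like", "brainstorm_like", "fieldtrip_like",
        }
        for name, variant in REGISTRY.items():
            spec = variant.band_filter(500.0)
            assert spec.fs == 500.0
            variant.criteria()
            variant.policy()
            variant.interpolation_model()

    def test_notch_only_where_enabled(self):
        assert get_variant("reference").notch_filter(500.0) is not None
        assert get_variant("brainstorm_like").notch_filter(500.0) is not None
        assert get_variant("eeglab_like").notch_filter(500.0) is None
        assert get_variant("fieldtrip_like").notch_filter(500.0) is None

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown variant config keys"):
            variant_from_dict({"name": "x", "filtre": "butterworth_iir"})

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "variants.yaml"
        path.write_text(
            "custom:\n  filter_family: fir_hamming\n  notch_enabled: false\n"
            "  gradient_uv_per_ms: null\n  minmax_uv: 200\n"
        )
        loaded = load_variants_yaml(path)
        assert loaded["custom"].minmax_uv == 200
        assert loaded["custom"].band_filter(500.0).family == "fir_hamming"

    def test_flat_policy_derivation(self):
        flat = get_variant("reference").with_flat_policy(minmax_uv=200.0)
        assert flat.bad_channel_method == "flat_detection"
        assert flat.minmax_uv == 200.0
        assert flat.name == "reference_flat_200"

    def test_unknown_variant_name(self):
        with pytest.raises(KeyError, match="registered"):
            get_variant("spm_like")


@pytest.fixture(scope="module")
def reference_small_run(small_cohort):
    cohort, _ = small_cohort
    return run_variant(cohort, get_variant("reference"),
                       min_trials_per_condition=10)


class TestRunVariant:
    def test_grand_average_difference_has_600_samples(self, reference_small_run):
        assert len(reference_small_run.included_subjects) >= 3
        ga = reference_small_run.grand_average("difference")
        assert ga.data.shape == (32, 600)

    def test_rerun_is_byte_identical(self, small_cohort, tmp_path,
                                     reference_small_run):
        cohort, _ = small_cohort
        again = run_variant(cohort, get_variant("reference"),
                            min_trials_per_condition=10)
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        write_run(reference_small_run, d1)
        write_run(again, d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_raised_minmax_never_loses_trials(self, small_cohort):
        """200 μV min-max accepts at least as many trials as 100 μV."""
        cohort, _ = small_cohort
        v100 = get_variant("fieldtrip_like")
        v200 = dataclasses.replace(v100, name="fieldtrip_200", minmax_uv=200.0)
        r100 = run_variant(cohort, v100, min_trials_per_condition=10)
        r200 = run_variant(cohort, v200, min_trials_per_condition=10)
        for sid in r100.results:
            a100 = r100.results[sid].accepted_counts
            a200 = r200.results[sid].accepted_counts
            if a100 and a200:
                assert a200["gain"] >= a100["gain"]
                assert a200["loss"] >= a100["loss"]

    def test_erp_tsv_round_trip(self, reference_small_run, tmp_path, montage):
        sid = reference_small_run.included_subjects[0]
        erp = reference_small_run.results[sid].erps["gain"]
        path = tmp_path / "erp.tsv"
        from erpbench.orchestrate import write_erp_tsv

        write_erp_tsv(erp, path)
        back = read_erp_tsv(path, montage, "gain")
        np.testing.assert_allclose(back.data, erp.data, atol=1e-5)
        np.testing.assert_allclose(back.times, erp.times)


class TestCompareVariants:
    def test_run_compared_with_itself(self, reference_small_run):
        runs = {"a": reference_small_run, "b": reference_small_run}
        report = compare_variants(runs, n_perm=100, sme_n_boot=100, seed=0)
        for entry in report.similarity:
            assert entry["mean"] == pytest.approx(1.0)
        for entry in report.ranksum:
            assert entry["p"] == pytest.approx(1.0)
        for cl in report.clusters.values():
            assert cl["n_clusters"] == 0
        validate_report(json.loads(report.to_json()))

    def test_four_variants_give_six_pairs(self, small_cohort):
        cohort, _ = small_cohort
        runs = {
            name: run_variant(cohort, get_variant(name),
                              min_trials_per_condition=10)
            for name in REGISTRY
        }
        report = compare_variants(runs, n_perm=60, sme_n_boot=100, seed=1)
        per_metric = pd.DataFrame(report.ranksum).groupby("metric").size()
        assert (per_metric == 6).all()
        diff_sims = [s for s in report.similarity if s["scope"] == "difference"]
        assert len(diff_sims) == 6
        assert len(report.clusters) == 6
        # same cohort, different pipelines: similar but not identical ERPs
        for s in diff_sims:
            assert 0.2 < s["mean"] <= 1.0
        assert report.anova["df_between"] == 3

    def test_disjoint_runs_rejected(self, reference_small_run):
        empty = eb.VariantRun(variant=reference_small_run.variant, results={})
        with pytest.raises(ValueError):
            compare_variants({"a": reference_small_run, "b": empty})


class TestFilterSwap:
    def test_table_symmetric_unit_diagonal_and_high_offdiag(self, small_cohort):
        cohort, _ = small_cohort
        table = filter_swap_experiment(cohort[:2])
        vals = table.to_numpy()
        assert np.allclose(vals, vals.T)
        assert np.allclose(np.diag(vals), 1.0)
        off = vals[~np.eye(len(table), dtype=bool)]
        assert (off > 0.8).all()
        assert (off < 1.0).all()


class TestValidateReport:
    def test_missing_key_rejected(self):
        with pytest.raises(ValueError, match="missing key"):
            validate_report({"pipelines": []})

    def test_wrong_type_rejected(self):
        payload = {k: [] for k in (
            "pipelines", "ranksum", "similarity")}
        payload.update({"n_shared_subjects": "six", "effect_sizes": {},
                        "clusters": {}, "sme": {}, "anova": {}})
        with pytest.raises(ValueError, match="n_shared_subjects"):
            validate_report(payload)


class TestCli:
    def test_simulate_and_filter_bench(self, tmp_path):
        from click.testing import CliRunner

        from erpbench.cli import main

        runner = CliRunner()
        out = tmp_path / "cohort"
        result = runner.invoke(main, [
            "simulate", "--n-subjects", "1", "--seed", "3", "--out", str(out),
        ])
        assert result.exit_code == 0, result.output
        assert (out / "manifest.json").exists()
        assert len(list(out.glob("*.vhdr"))) == 1

        bench = tmp_path / "bench.tsv"
        result = runner.invoke(main, ["filter-bench", "--out", str(bench)])
        assert result.exit_code == 0, result.output
        table = pd.read_csv(bench, sep="\t")
        assert {"freq_hz", "butterworth_iir_gain_db"} <= set(table.columns)
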