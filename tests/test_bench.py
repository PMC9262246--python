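"""Grid orchestration: completeness, determinism, resume, aggregation audit."""

import numpy as np
import pandas as pd
import pytest

from usdenoise import (
    ParameterError,
    RunConfig,
    aggregate_mean_std,
    aggregate_median,
    directional_findings,
    run_grid,
    runtime_report,
    trend_curves,
)
from usdenoise.bench import (
    cell_seed,
    load_run_config,
    read_results,
    runtime_family_ratio,
    write_results,
)


@pytest.fixture(scope="module")
def small_cfg():
    return RunConfig(
        noise_kinds=("gaussian", "speckle"),
        levels=(1, 10, 20),
        wavelets=(("daubechies", 2), ("symlet", 3)),
        decomposition_levels=(3,),
        run_seed=11,
    )


@pytest.fixture(scope="module")
def small_table(small_cfg, phantom_set):
    return run_grid(small_cfg, phantom_set[:3])


class TestRunGrid:
    def test_row_count_completeness(self, small_table):
        # 2 stages x 3 images x 2 kinds x 3 levels x 2 wavelets x 1 J
        assert len(small_table) == 2 * 3 * 2 * 3 * 2
        assert not small_table.duplicated(
            ["image_id", "noise_kind", "level_index", "family", "order", "levels", "stage"]
        ).any()

    def test_noisy_rows_identical_across_wavelets(self, small_table):
        """Every wavelet sees the same degraded image: the noisy-stage metrics
        for one (image, kind, level) cell agree across wavelet configs."""
        noisy = small_table[small_table["stage"] == "noisy"]
        for _, group in noisy.groupby(["image_id", "noise_kind", "level_index"]):
            assert group["mse"].nunique() == 1
            assert group["ssim"].nunique() == 1

    def test_cell_seed_excludes_wavelet(self):
        s1 = cell_seed(3, "img", "speckle", 5)
        assert s1 == cell_seed(3, "img", "speckle", 5)
        assert s1 != cell_seed(3, "img", "speckle", 6)
        assert s1 != cell_seed(4, "img", "speckle", 5)

    def test_rerun_is_deterministic(self, small_cfg, phantom_set, small_table):
        again = run_grid(small_cfg, phantom_set[:3])
        metrics = ["corr", "mse", "psnr", "q_index", "ssim"]
        pd.testing.assert_frame_equal(
            small_table.drop(columns=["elapsed_s"]),
            again.drop(columns=["elapsed_s"]),
        )

    def test_worker_invariance(self, phantom_set):
        cfg1 = RunConfig(
            noise_kinds=("speckle",),
            levels=(1, 2),
            wavelets=(("daubechies", 2),),
            decomposition_levels=(3,),
            run_seed=2,
            workers=1,
        )
        cfg4 = RunConfig(
            noise_kinds=("speckle",),
            levels=(1, 2),
            wavelets=(("daubechies", 2),),
            decomposition_levels=(3,),
            run_seed=2,
            workers=4,
        )
        t1 = run_grid(cfg1, phantom_set[:2]).drop(columns=["elapsed_s"])
        t4 = run_grid(cfg4, phantom_set[:2]).drop(columns=["elapsed_s"])
        pd.testing.assert_frame_equal(t1, t4)

    def test_resume_recomputes_only_missing(self, tmp_path, phantom_set):
        cfg = RunConfig(
            noise_kinds=("speckle",),
            levels=(1, 2),
            wavelets=(("daubechies", 2), ("symlet", 3)),
            decomposition_levels=(3,),
            run_seed=9,
            out_dir=str(tmp_path),
        )
        full = run_grid(cfg, phantom_set[:2])
        # drop one wavelet's rows and resume
        kept = full[~((full["family"] == "symlet") & (full["order"] == 3))]
        write_results(kept, tmp_path / "results.csv")
        resumed = run_grid(cfg, phantom_set[:2])
        metrics = ["corr", "mse", "psnr", "q_index", "ssim"]
        a = full.drop(columns=["elapsed_s"]).reset_index(drop=True)
        b = resumed.drop(columns=["elapsed_s"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_invalid_config_aborts_before_work(self):
        with pytest.raises(ParameterError):
            RunConfig(noise_kinds=("shot",))
        with pytest.raises(ParameterError):
            RunConfig(levels=(0,))
        with pytest.raises(ParameterError):
            RunConfig(wavelets=(("daubechies", 77),))

    def test_csv_roundtrip_with_literals(self, small_table, tmp_path):
        path = tmp_path / "results.csv"
        write_results(small_table, path)
        header = path.read_text().splitlines()[0]
        assert header.startswith("# usdenoise results v1:")
        loaded = read_results(path)
        assert len(loaded) == len(small_table)
        assert np.allclose(loaded["mse"].values, small_table["mse"].values)


class TestAggregation:
    def test_median_layout_and_values(self, small_table):
        summary = aggregate_median(
            small_table, family="daubechies", order=2, levels=3
        )
        assert "Mean" in summary.index
        cats = [c for c in summary.index if c != "Mean"]
        raw = small_table[
            (small_table["stage"] == "denoised")
            & (small_table["family"] == "daubechies")
            & (small_table["order"] == 2)
        ]
        for cat in cats:
            for kind in ("gaussian", "speckle"):
                expected = raw[(raw["category"] == cat) & (raw["noise_kind"] == kind)][
                    "ssim"
                ].median()
                assert summary.loc[cat, ("ssim", kind)] == pytest.approx(expected, abs=1e-12)
        # the Mean row is the arithmetic mean of the category aggregates
        col = summary.loc[cats, ("ssim", "speckle")]
        assert summary.loc["Mean", ("ssim", "speckle")] == pytest.approx(col.mean())

    def test_even_count_median_convention(self):
        assert float(pd.Series([0.2, 0.4]).median()) == pytest.approx(0.3)
        assert float(pd.Series([0.2, 0.4, 0.6]).median()) == pytest.approx(0.4)

    def test_mean_std_audit(self, small_table):
        agg = aggregate_mean_std(small_table, metric="psnr", family="daubechies", levels=3)
        raw = small_table[
            (small_table["stage"] == "denoised")
            & (small_table["family"] == "daubechies")
            & np.isfinite(small_table["psnr"])
        ]
        for row in agg.itertuples():
            vals = raw[
                (raw["order"] == row.order)
                & (raw["category"] == row.category)
                & (raw["noise_kind"] == row.noise_kind)
            ]["psnr"]
            assert row.mean == pytest.approx(vals.mean(), abs=1e-12)
            if len(vals) > 1:
                assert row.std == pytest.approx(vals.std(ddof=1), abs=1e-12)

    def test_two_point_mean_std(self):
        table = pd.DataFrame(
            {
                "stage": ["denoised"] * 2,
                "family": ["daubechies"] * 2,
                "order": [2, 2],
                "levels": [3, 3],
                "category": ["msk"] * 2,
                "noise_kind": ["speckle"] * 2,
                "psnr": [10.0, 20.0],
            }
        )
        agg = aggregate_mean_std(table)
        assert agg.loc[0, "mean"] == pytest.approx(15.0)
        assert agg.loc[0, "std"] == pytest.approx(7.0711, abs=1e-4)

    def test_single_sample_flagged(self):
        table = pd.DataFrame(
            {
                "stage": ["denoised"],
                "family": ["daubechies"],
                "order": [2],
                "levels": [3],
                "category": ["msk"],
                "noise_kind": ["speckle"],
                "psnr": [10.0],
            }
        )
        agg = aggregate_mean_std(table)
        assert agg.loc[0, "std"] == 0.0
        assert bool(agg.loc[0, "single_sample"])

    def test_empty_group_rejected(self, small_table):
        with pytest.raises(ParameterError):
            aggregate_median(small_table, family="symlet", order=29)


class TestTrendsAndRuntime:
    def test_trend_series_shape(self, small_table):
        curves = trend_curves(small_table, "ssim", "speckle", 3)
        assert list(curves.columns) == ["db2", "sym3"]
        assert curves.index.min() == 1 and curves.index.max() == 20

    def test_missing_levels_flagged(self, small_table):
        with pytest.warns(UserWarning, match="gaps"):
            trend_curves(small_table, "mse", "speckle", 3)

    def test_ssim_endpoint_dominance(self, small_table):
        """More noise, lower post-filter similarity: the level-1 SSIM beats
        the level-20 SSIM for every wavelet on the synthetic grid."""
        curves = trend_curves(small_table, "ssim", "speckle", 3)
        for col in curves.columns:
            assert curves[col].loc[1] >= curves[col].loc[20]

    def test_runtime_totals_additive(self, small_table):
        rep = runtime_report(small_table)
        assert (rep["total_s"] >= 0).all()
        den = small_table[small_table["stage"] == "denoised"]
        assert rep["total_s"].sum() == pytest.approx(den["elapsed_s"].sum())
        ratio = runtime_family_ratio(rep)
        assert ratio is None or ratio > 0

    def test_empty_runtime_report(self):
        rep = runtime_report(pd.DataFrame({"stage": [], "elapsed_s": []}))
        assert rep.empty

    def test_directional_findings_structure(self, small_table):
        findings = directional_findings(small_table)
        assert "speckle_best_db_order" in findings
        assert "ssim_endpoint_dominance" in findings
        assert isinstance(findings["speckle_db2_first"], bool)


def test_load_run_config_yaml(tmp_path):
    cfg_path = tmp_path / "run.yaml"
    cfg_path.write_text(
        """
noise_kinds: [speckle]
levels: [1, 2, 3]
wavelets: [[daubechies, 2], [symlet, 3]]
decomposition_levels: [3]
alpha: 1.5
run_seed: 42
workers: 1
"""
    )
    cfg = load_run_config(cfg_path)
    assert cfg.noise_kinds == ("speckle",)
    assert cfg.wavelets == (("daubechies", 2), ("symlet", 3))
    assert cfg.run_seed == 42
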