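"""Shared fixtures: small synthetic stands and one full pipeline run."""

from __future__ import annotations

import pytest

import lidarvol as lv
from lidarvol.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def small_truth() -> lv.PlotTruth:
    """A 30 m plot on a 5 m grid, no thinning: 36 trees."""
    return lv.generate_plot(
        lv.SpeciesParams(mean_dbh=31.57, sd_dbh=3.95, mean_height=27.30, sd_height=1.71),
        plot_size=30.0, row_spacing=5.0, col_spacing=5.0,
        thinning=0.0, seed=42,
    )


@pytest.fixture(scope="session")
def one_tree_truth() -> lv.PlotTruth:
    """A single 30-cm-DBH tree for slice/taper geometry checks."""
    tree = lv.TrueTree(
        id=0, stem_x=15.0, stem_y=15.0, height=25.0, dbh=30.0,
        crown_radius=2.5, lean_dx=0.0, lean_dy=0.0, species_tag="conifer-like",
    )
    return lv.PlotTruth(
        trees=[tree], plot_size=30.0, row_spacing=5.0, col_spacing=5.0,
        ground_coeffs=(2.0, 0.0004, 0.0), seed=0,
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory) -> dict:
    """One full plot-b-like pipeline run (simulate -> volume table), seed 11."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(out_dir=str(out), seed=11)
    report = run_pipeline(cfg)
    report["_out_dir"] = str(out)
    report["_config"] = cfg
    return report
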