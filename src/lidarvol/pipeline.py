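"""End-to-end workflow: simulate (or ingest) clouds → volume table.

One configuration drives every stage — simulation, preprocessing, ULS tree
segmentation, BLS trunk detection, coarse + fine co-registration, stem
profiling, taper fitting and model selection, volume-table compilation and
stand-volume estimation. Every stage writes plain-text artifacts (XYZ, CSV,
JSON) into the output directory so each can be inspected or re-run in
isolation, and the whole run is reproducible from the global seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bls as bls_mod
from . import preprocessing as prep
from .cloud import GROUND, PointCloud, read_xyz, write_xyz
from .metrics import detection_metrics, match_detections
from .registration import (
    RigidTransform2D,
    refine_by_tree_matching,
    registration_error,
    rigid_from_control_points,
)
from .synthetic import (
    DEFAULT_TAPER_COEFFS,
    SpeciesParams,
    control_points,
    generate_plot,
    sample_bls_cloud,
    sample_uls_cloud,
)
from .taper import (
    build_volume_table,
    fit_all_models,
    select_model,
    stand_volume,
    tree_volume,
)
from .uls import TreetopSegmenter


@dataclass
class PipelineConfig:
    """Every stage's parameters in one place (all values are defaults)."""

    out_dir: str = "lidarvol_run"
    seed: int = 0
    species: str = "conifer-like"

    # stage toggles
    run_bls: bool = True
    run_registration: bool = True
    run_taper: bool = True

    # simulation (set uls_path/bls_path to skip simulation and ingest files)
    uls_path: str | None = None
    bls_path: str | None = None
    plot: dict = field(
        default_factory=lambda: dict(
            mean_dbh=31.57, sd_dbh=3.95, mean_height=27.30, sd_height=1.71,
            plot_size=30.0, row_spacing=5.0, col_spacing=5.0, thinning=10 / 36,
        )
    )
    uls_scan: dict = field(default_factory=lambda: dict(density=84.0, noise_sigma=0.03))
    bls_scan: dict = field(
        default_factory=lambda: dict(
            pts_per_stem_slice=80.0, noise_sigma=0.01, height_cap=9.0,
            rotation_deg=3.0, tx=5.0, ty=-3.0, z_offset=0.5,
        )
    )
    taper_coeffs: tuple[float, ...] = DEFAULT_TAPER_COEFFS

    preprocessing: dict = field(
        default_factory=lambda: dict(
            knn_k=8, knn_sigma=3.0, seed_cell=5.0, max_angle=8.0,
            max_dist=0.5, dem_cell=1.0, idw_power=2.0, idw_k=12,
        )
    )
    uls_seg: dict = field(
        default_factory=lambda: dict(t1=2.0, t2=2.5, h_min=2.0, min_points=30)
    )
    bls_seg: dict = field(default_factory=lambda: dict(eps=0.2, min_pts=15))
    registration: dict = field(
        default_factory=lambda: dict(max_pair_dist=2.0, survey_sigma=0.0)
    )
    stand: dict = field(default_factory=lambda: dict(tolerance=0.05))
    taper_models: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key: {key}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(val, dict):
                current.update(val)
            elif key in ("taper_coeffs", "taper_models"):
                setattr(cfg, key, tuple(val))
            else:
                setattr(cfg, key, val)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["taper_coeffs"] = list(self.taper_coeffs)
        data["taper_models"] = list(self.taper_models)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _preprocess(cloud: PointCloud, p: dict) -> tuple[PointCloud, "prep.DEMGrid"]:
    cloud = prep.remove_outliers(cloud, k=p["knn_k"], n_sigma=p["knn_sigma"])
    cloud = prep.classify_ground(
        cloud, seed_cell=p["seed_cell"], max_angle=p["max_angle"], max_dist=p["max_dist"]
    )
    dem = prep.build_dem(
        cloud.subset(cloud.classification == GROUND),
        cell=p["dem_cell"], idw_power=p["idw_power"], idw_k=p["idw_k"],
    )
    return prep.normalize_heights(cloud, dem), dem


def _score(detected_xy, reference) -> dict:
    nt, no, nc, _ = match_detections(detected_xy, reference)
    try:
        m = detection_metrics(nt, no, nc)
        return dict(Nt=nt, No=no, Nc=nc, r=m.r, p=m.p, F=m.f)
    except ValueError:
        return dict(Nt=nt, No=no, Nc=nc, r=None, p=None, F=None)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run report.

    The report echoes per-stage parameters, detection scores against the
    simulated truth (when simulating), registration accuracy, the selected
    taper model with its coefficients, and the plot summary. It is also
    written to ``report.json`` in the output directory, alongside the stage
    artifacts listed in its ``files`` manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "species": config.species, "files": {}}
    files = report["files"]

    # ---- stage 1: simulate or ingest -------------------------------------
    truth = None
    if config.uls_path is None:
        plot = dict(config.plot)
        sp = SpeciesParams(
            mean_dbh=plot["mean_dbh"], sd_dbh=plot["sd_dbh"],
            mean_height=plot["mean_height"], sd_height=plot["sd_height"],
            species_tag=config.species,
        )
        truth = generate_plot(
            sp,
            plot_size=plot["plot_size"],
            row_spacing=plot["row_spacing"],
            col_spacing=plot["col_spacing"],
            thinning=plot["thinning"],
            taper_coeffs=config.taper_coeffs,
            seed=config.seed,
        )
        b = config.bls_scan
        true_tf = RigidTransform2D(
            rotation=np.radians(b["rotation_deg"]),
            translation=(b["tx"], b["ty"]),
            z_offset=b["z_offset"],
        )
        uls_scan = sample_uls_cloud(
            truth, density=config.uls_scan["density"],
            noise_sigma=config.uls_scan["noise_sigma"], seed=config.seed + 1,
        )
        bls_scan = sample_bls_cloud(
            truth, pts_per_stem_slice=b["pts_per_stem_slice"],
            noise_sigma=b["noise_sigma"], transform=true_tf,
            height_cap=b["height_cap"], seed=config.seed + 2,
        )
        uls_cloud, bls_cloud = uls_scan.cloud, bls_scan.cloud
        truth.to_csv(out / "truth.csv")
        write_xyz(uls_cloud, out / "uls.xyz")
        write_xyz(bls_cloud, out / "bls.xyz")
        files["truth"] = "truth.csv"
        files["uls_cloud"] = "uls.xyz"
        files["bls_cloud"] = "bls.xyz"
        report["simulation"] = {
            "n_trees": len(truth.trees),
            "uls_points": len(uls_cloud),
            "bls_points": len(bls_cloud),
            "true_transform": {
                "rotation_rad": true_tf.rotation,
                "translation": list(true_tf.translation),
                "z_offset": true_tf.z_offset,
            },
        }
    else:
        uls_cloud = read_xyz(config.uls_path)
        bls_cloud = read_xyz(config.bls_path) if config.bls_path else None
        true_tf = None

    # ---- stage 2: preprocessing ------------------------------------------
    uls_norm, uls_dem = _preprocess(uls_cloud, config.preprocessing)
    uls_dem.to_ascii(out / "uls_dem.asc")
    files["uls_dem"] = "uls_dem.asc"

    # ---- stage 3: ULS tree segmentation ----------------------------------
    veg = uls_norm.subset(uls_norm.classification != GROUND)
    seg = TreetopSegmenter(**config.uls_seg)
    seg.fit(np.column_stack([veg.x, veg.y, veg.z_norm]))
    uls_trees = seg.trees_
    tree_df = pd.DataFrame(
        [
            dict(id=t.id, x=t.apex[0], y=t.apex[1], H=t.height, crown_radius=t.crown_radius)
            for t in uls_trees
        ]
    )
    tree_df.to_csv(out / "uls_trees.csv", index=False, float_format="%.4f")
    files["uls_trees"] = "uls_trees.csv"
    report["uls_segmentation"] = {"n_detected": len(uls_trees)}
    if truth is not None and uls_trees:
        report["uls_segmentation"]["detection"] = _score(
            [t.position for t in uls_trees], truth.detection_reference()
        )

    if not config.run_bls:
        report["status"] = "stopped after ULS stage: no DBH source (BLS disabled)"
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        files["report"] = "report.json"
        return report

    # ---- stage 4: BLS trunk detection ------------------------------------
    if bls_cloud is None:
        raise ValueError("BLS stage enabled but no BLS cloud available")
    bls_norm, _ = _preprocess(bls_cloud, config.preprocessing)
    db_cfg = bls_mod.DbscanConfig(
        eps=config.bls_seg["eps"], min_pts=config.bls_seg["min_pts"]
    )
    bh_slice = bls_mod.slice_cloud(bls_norm, db_cfg.slice_center, db_cfg.slice_width)
    trunks = bls_mod.trunk_records(bh_slice, db_cfg)
    trunk_df = pd.DataFrame(
        [
            dict(id=t.id, x=t.center[0], y=t.center[1], D=t.dbh_cm, n_points=t.n_points)
            for t in trunks
        ]
    )
    trunk_df.to_csv(out / "bls_trunks.csv", index=False, float_format="%.4f")
    files["bls_trunks"] = "bls_trunks.csv"
    report["bls_segmentation"] = {"n_detected": len(trunks)}
    if truth is not None and trunks and true_tf is not None:
        stems_bls = true_tf.apply(truth.stem_positions())
        ref = [
            (float(p[0]), float(p[1]), t.crown_radius)
            for p, t in zip(stems_bls, truth.trees)
        ]
        report["bls_segmentation"]["detection"] = _score(
            [t.center for t in trunks], ref
        )

    # ---- stage 5: co-registration ----------------------------------------
    matches = []
    fine_tf = RigidTransform2D()
    if config.run_registration:
        if truth is not None and true_tf is not None:
            bls_cp, uls_cp = control_points(
                truth, true_tf,
                survey_sigma=config.registration["survey_sigma"],
                seed=config.seed + 3,
            )
            coarse_tf, coarse_rms = rigid_from_control_points(bls_cp, uls_cp)
        else:
            coarse_tf, coarse_rms = RigidTransform2D(), 0.0
        fine_tf, matches = refine_by_tree_matching(
            np.array([t.position for t in uls_trees]),
            np.array([t.center for t in trunks]),
            init=coarse_tf,
            max_pair_dist=config.registration["max_pair_dist"],
        )
        reg_report = {
            "coarse_rms_m": coarse_rms,
            "n_matches": len(matches),
            "mean_distance_cm": registration_error(matches),
            "recovered_rotation_rad": fine_tf.rotation,
            "recovered_translation": list(fine_tf.translation),
        }
        if true_tf is not None:
            inv = true_tf.inverse()
            reg_report["rotation_error_rad"] = float(
                abs(fine_tf.rotation - inv.rotation)
            )
            # recovery error as the transform's action, not raw parameters:
            # mean discrepancy between recovered and true BLS->plot mapping
            # evaluated at the detected trunk positions
            trunk_xy = np.array([t.center for t in trunks])
            reg_report["transform_error_m"] = float(
                np.mean(
                    np.hypot(*(fine_tf.apply(trunk_xy) - inv.apply(trunk_xy)).T)
                )
            )
        report["registration"] = reg_report
        pd.DataFrame(
            [
                dict(uls_id=m.uls_id, bls_id=m.bls_id, distance_cm=100 * m.distance_m)
                for m in matches
            ]
        ).to_csv(out / "matches.csv", index=False, float_format="%.4f")
        files["matches"] = "matches.csv"

    if not config.run_taper or not matches:
        report["status"] = "stopped before taper fitting"
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        files["report"] = "report.json"
        return report

    # ---- stage 6: stem profiles and taper samples ------------------------
    rows = []
    matched_dh = []
    for m in matches:
        trunk = trunks[m.bls_id]
        H = uls_trees[m.uls_id].height
        D = trunk.dbh_cm
        matched_dh.append((D, H))
        profile = bls_mod.stem_profile(bls_norm, trunk, cfg=db_cfg)
        for h, d in profile.samples:
            if h < H:
                rows.append(dict(tree_id=m.uls_id, D=D, H=H, h=h, d=d))
    samples = pd.DataFrame(rows)
    samples.to_csv(out / "taper_samples.csv", index=False, float_format="%.4f")
    files["taper_samples"] = "taper_samples.csv"

    # ---- stage 7: taper fitting and selection ----------------------------
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = fit_all_models(
            samples[["D", "H", "h", "d"]].to_numpy(), model_ids=config.taper_models
        )
    best = select_model(fits)
    # a selected form must integrate to the tip for volume work; if it
    # cannot (e.g. a variable-exponent form fitted with a divergent tip),
    # fall back to the next-best integrable fit
    ranked = sorted(fits, key=lambda f: (f.stats.rmse, -f.stats.r2, len(f.coeffs)))
    for cand in ranked:
        try:
            tree_volume(cand, float(np.median(samples["D"])), float(np.median(samples["H"])))
            best = cand
            break
        except (ValueError, RuntimeError):
            continue
    report["taper"] = {
        "n_samples": int(len(samples)),
        "fits": {f.model_id: f.to_dict() for f in fits},
        "selected": best.model_id,
    }
    (out / "taper_fits.json").write_text(
        json.dumps(report["taper"], indent=2, sort_keys=True)
    )
    files["taper_fits"] = "taper_fits.json"

    # ---- stage 8: volume table -------------------------------------------
    Ds = samples["D"].to_numpy()
    Hs = samples["H"].to_numpy()
    dbh_classes = np.arange(
        2 * np.floor(Ds.min() / 2), 2 * np.ceil(Ds.max() / 2) + 1, 2.0
    )
    height_classes = np.arange(np.floor(Hs.min()), np.ceil(Hs.max()) + 1, 1.0)
    table = build_volume_table(best, dbh_classes, height_classes, species=config.species)
    table.to_csv(out / "volume_table.csv")
    files["volume_table"] = "volume_table.csv"

    # ---- stage 9: stand volume -------------------------------------------
    plot_area = (
        truth.plot_size**2 if truth is not None else float(config.plot["plot_size"]) ** 2
    )
    summary = stand_volume(
        matched_dh, best, plot_area_m2=plot_area, tolerance=config.stand["tolerance"]
    )
    report["stand"] = {
        "Dg_cm": summary.dg_cm,
        "Hg_m": summary.hg_m,
        "n_standard_trees": len(summary.standard_tree_ids),
        "plot_volume_m3": summary.plot_volume_m3,
        "basal_area_m2": summary.basal_area_m2,
        "stand_volume_m3_ha": summary.stand_volume_m3_ha,
    }
    report["status"] = "complete"
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    files["report"] = "report.json"
    return report
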