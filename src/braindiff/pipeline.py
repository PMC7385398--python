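"""End-to-end orchestration: simulate -> features -> stats -> convergence -> mvpa.

All randomness flows from one master seed through named per-stage
substreams, so a rerun with the same config reproduces every output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import io as bio
from . import mvpa, stats
from .convergence import overlap_analysis, spatial_correlation
from .synth import (
    CohortSpec,
    ellipsoid_mask,
    generate_bold_runs,
    generate_gmv_maps,
    generate_subject_table,
    make_atlas,
)
from .types import VolumeMap

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    band_hz: tuple[float, float] = (0.01, 0.08)
    smoothing_fwhm_mm: float = 4.0
    alpha_voxel: float = 0.05
    fwe_method: str = "max_t_permutation"
    n_perm_fwe: int = 200
    alpha_edge_family: float = 0.05
    trend_p: float = 0.001
    cv_k: int = 5
    grid_steps: dict = field(
        default_factory=lambda: {"gmv": 200, "reho": 200, "fc": 10, "combined": 400}
    )
    n_perm_mvpa: int = 50
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            cohort = dict(cohort)
            for key in ("grid_shape",):
                if key in cohort:
                    cohort[key] = tuple(cohort[key])
            for key in ("gmv_effect_clusters", "reho_effect_clusters"):
                if key in cohort:
                    cohort[key] = [
                        (tuple(c), r, d_) for c, r, d_ in cohort[key]
                    ]
            if "fc_effect_edges" in cohort:
                cohort["fc_effect_edges"] = [
                    tuple(e) for e in cohort["fc_effect_edges"]
                ]
            cohort = CohortSpec(**cohort)
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        return cls(cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _nuisance_regressors(motion: pd.DataFrame, run, mask) -> np.ndarray:
    """Linear drift, 6 motion parameters, global in-mask mean signal."""
    T = run.n_timepoints
    drift = np.linspace(-1.0, 1.0, T)
    global_sig = run.values[mask].mean(axis=0)
    return np.column_stack([drift, motion.to_numpy()[:T], global_sig])


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage, write all artifacts, and return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    def _save(name: str, writer, *args) -> Path:
        path = writer(out / name, *args)
        manifest["outputs"].append(name)
        return path

    spec = config.cohort
    try:
        # --- simulate -------------------------------------------------
        table = generate_subject_table(spec)
        mask = ellipsoid_mask(spec.grid_shape)
        atlas = make_atlas(mask, spec.n_regions, spec.voxel_size_mm, spec.seed)
        gmv_maps, gmv_truth = generate_gmv_maps(spec, table, mask)
        bold_runs, func_truth, motion = generate_bold_runs(spec, table, atlas)
        _save("subjects.tsv", bio.write_table, table)
        _save("mask.nii", bio.write_volume,
              VolumeMap(mask.astype(float), mask, spec.voxel_size_mm))
        _save("atlas.nii", bio.write_volume, atlas)
        truth_payload = {
            "fc_effect_edges": [list(e) for e in func_truth.fc_effect_edges],
        }
        if gmv_truth.gmv_effect_mask is not None:
            _save("truth_gmv_mask.nii", bio.write_volume, gmv_truth.gmv_effect_mask)
        if func_truth.reho_effect_mask is not None:
            _save("truth_reho_mask.nii", bio.write_volume,
                  func_truth.reho_effect_mask)
        _save("ground_truth.json", bio.write_json, truth_payload)
        manifest["stages"]["simulate"] = {"n_subjects": int(spec.n_subjects)}

        # --- features -------------------------------------------------
        subject_ids = table["subject_id"].tolist()
        reho_maps: list[VolumeMap] = []
        fcs = []
        for i, sid in enumerate(subject_ids):
            run = bold_runs[sid]
            run = feat.bandpass_filter(run, *config.band_hz)
            run = feat.regress_nuisance(
                run, _nuisance_regressors(motion[i], run, mask)
            )
            reho = feat.compute_reho(run, mask, neighborhood=26)
            reho = feat.standardize_reho(reho)
            reho = feat.smooth_volume(reho, config.smoothing_fwhm_mm)
            reho_maps.append(reho)
            ts, labels = feat.region_timeseries(run, atlas)
            fcs.append(feat.fc_matrix(ts, labels))
        manifest["stages"]["features"] = {"n_regions": len(fcs[0].region_labels)}

        # --- stats ----------------------------------------------------
        gender = table["gender"].to_numpy()
        covs = table[["age", "education"]]
        gmv_list = [gmv_maps[sid] for sid in subject_ids]
        fwe_kwargs = dict(
            method=config.fwe_method,
            alpha=config.alpha_voxel,
            gender=gender,
            covariates=covs,
            n_perm=config.n_perm_fwe,
            seed=config.seed + 1,
        )
        tmap_gmv = stats.glm_group_tmap(gmv_list, gender, covs)
        tmap_gmv = stats.fwe_correct(tmap_gmv, maps=gmv_list, **fwe_kwargs)
        tmap_reho = stats.glm_group_tmap(reho_maps, gender, covs)
        tmap_reho = stats.fwe_correct(tmap_reho, maps=reho_maps, **fwe_kwargs)
        edges = stats.edge_group_tests(fcs, gender, covs, config.alpha_edge_family)
        degree = stats.weighted_degree(edges, spec.n_regions)
        for name, tm in [("gmv", tmap_gmv), ("reho", tmap_reho)]:
            _save(f"tmap_{name}.nii", bio.write_volume, tm.t_values)
            _save(f"pmap_{name}.nii", bio.write_volume, tm.p_values)
            _save(f"sig_{name}.nii", bio.write_volume, tm.sig_mask)
        _save("edges.tsv", bio.write_table, edges.to_frame())
        _save("degree.tsv", bio.write_table, degree)
        manifest["stages"]["stats"] = {
            "n_sig_gmv": int(tmap_gmv.sig_mask.in_mask().sum()),
            "n_sig_reho": int(tmap_reho.sig_mask.in_mask().sum()),
            "n_sig_edges": int(edges.sig_mask.sum()),
        }

        # --- convergence ---------------------------------------------
        trend_gmv = tmap_gmv.p_values.from_vector(
            (tmap_gmv.p_values.in_mask() < config.trend_p)
            | (tmap_gmv.sig_mask.in_mask() > 0)
        )
        trend_reho = tmap_reho.p_values.from_vector(
            (tmap_reho.p_values.in_mask() < config.trend_p)
            | (tmap_reho.sig_mask.in_mask() > 0)
        )
        report = overlap_analysis(
            tmap_gmv.sig_mask, tmap_reho.sig_mask, trend_gmv, trend_reho,
            tA=tmap_gmv.t_values.values, tB=tmap_reho.t_values.values,
        )
        r_spatial = spatial_correlation(tmap_gmv, tmap_reho, mask)
        conv = {"overlap": report.to_dict(), "spatial_correlation": r_spatial}
        _save("convergence.json", bio.write_json, conv)
        manifest["stages"]["convergence"] = {"spatial_correlation": r_spatial}

        # --- mvpa -----------------------------------------------------
        fm_gmv = mvpa.FeatureMatrix(
            np.stack([m.in_mask() for m in gmv_list]),
            modality="gmv", subject_ids=subject_ids,
        )
        fm_reho = mvpa.FeatureMatrix(
            np.stack([m.in_mask() for m in reho_maps]),
            modality="reho", subject_ids=subject_ids,
        )
        fm_fc = mvpa.FeatureMatrix(
            np.stack([fc.edge_vector() for fc in fcs]),
            modality="fc", subject_ids=subject_ids,
        )
        y = gender
        parts = {}
        for fm in (fm_gmv, fm_reho, fm_fc):
            fm = mvpa.residualize_features(fm, covs)
            parts[fm.modality] = mvpa.znorm_per_subject(fm)
        parts["combined"] = mvpa.concat_modalities(
            [parts["gmv"], parts["reho"], parts["fc"]]
        )
        folds = mvpa.make_folds(
            spec.n_male, spec.n_female, config.cv_k, config.seed + 2
        )
        mvpa_summary = {}
        for modality, fm in parts.items():
            grid = mvpa.make_feature_grid(
                min(config.grid_steps.get(modality, fm.n_features), fm.n_features),
                fm.n_features,
            )
            res = mvpa.cv_classify(fm, y, folds, grid)
            null = mvpa.permutation_test(
                fm, y, folds, res.best_n_features, config.n_perm_mvpa,
                res.best_mean_accuracy, seed=config.seed + 3,
                bonferroni_factor=len(grid),
            )
            _save(f"mvpa_{modality}.tsv", bio.write_table, res.to_frame())
            _save(
                f"mvpa_{modality}_null.tsv", bio.write_table,
                pd.DataFrame({"null_accuracy": null.null_accuracies}),
            )
            curve, _ = mvpa.roc_auc(
                res.decision_values[res.best_grid_point], y
            )
            _save(f"mvpa_{modality}_roc.tsv", bio.write_table, curve)
            mvpa_summary[modality] = {
                "best_n_features": res.best_n_features,
                "mean_accuracy": res.best_mean_accuracy,
                "sensitivity": float(res.sensitivity[res.best_grid_point]),
                "specificity": float(res.specificity[res.best_grid_point]),
                "auc": float(res.auc[res.best_grid_point]),
                "p_value": null.p_value,
                "p_bonferroni": null.p_bonferroni,
            }
        _save("mvpa_summary.json", bio.write_json, mvpa_summary)
        manifest["stages"]["mvpa"] = mvpa_summary
    except Exception as err:  # annotate with the failing stage
        done = set(manifest["stages"])
        order = ["simulate", "features", "stats", "convergence", "mvpa"]
        current = next((s for s in order if s not in done), "unknown")
        raise RuntimeError(f"pipeline stage '{current}' failed: {err}") from err

    bio.write_json(out / "manifest.json", manifest)
    return manifest


def write_report(out_dir: str | Path, report_name: str = "report.md") -> Path:
    """Render a markdown summary with figure panels from pipeline outputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    summary = bio.read_json(out / "mvpa_summary.json")
    conv = bio.read_json(out / "convergence.json")
    degree = bio.read_table(out / "degree.tsv")

    figs = []
    # accuracy vs grid + null distributions + ROC per modality
    for modality in summary:
        res = bio.read_table(out / f"mvpa_{modality}.tsv")
        null = bio.read_table(out / f"mvpa_{modality}_null.tsv")
        roc = bio.read_table(out / f"mvpa_{modality}_roc.tsv")
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        axes[0].plot(res["n_features"], 100 * res["mean_accuracy"], "-o", ms=3)
        axes[0].set_xlabel("# selected features")
        axes[0].set_ylabel("accuracy (%)")
        axes[0].set_title(f"{modality}: accuracy vs feature count")
        axes[1].hist(100 * null["null_accuracy"], bins=20, color="steelblue")
        axes[1].axvline(
            100 * summary[modality]["mean_accuracy"], color="red", lw=2
        )
        axes[1].set_xlabel("null accuracy (%)")
        axes[1].set_title("permutation null")
        axes[2].plot(roc["fpr"], roc["tpr"], "-")
        axes[2].plot([0, 1], [0, 1], "k--", lw=0.8)
        axes[2].set_xlabel("false positive rate")
        axes[2].set_ylabel("true positive rate")
        axes[2].set_title(f"ROC (AUC={summary[modality]['auc']:.3f})")
        fig.tight_layout()
        name = f"fig_mvpa_{modality}.png"
        fig.savefig(out / name, dpi=110)
        plt.close(fig)
        figs.append(name)

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(degree["region"] - 0.2, degree["positive_weighted_degree"], 0.4,
           label="positive", color="firebrick")
    ax.bar(degree["region"] + 0.2, degree["negative_weighted_degree"], 0.4,
           label="negative", color="navy")
    ax.set_xlabel("region")
    ax.set_ylabel("weighted degree")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "fig_degree.png", dpi=110)
    plt.close(fig)
    figs.append("fig_degree.png")

    lines = ["# Pipeline report", ""]
    lines.append("## Convergence")
    lines.append(f"- spatial correlation r = {conv['spatial_correlation']:.4f}")
    for k, v in conv["overlap"].items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append("## Classification")
    lines.append(
        "| modality | best #features | accuracy | sensitivity | "
        "specificity | AUC | p | p (Bonferroni) |"
    )
    lines.append("|---|---|---|---|---|---|---|---|")
    for modality, s in summary.items():
        lines.append(
            f"| {modality} | {s['best_n_features']} | "
            f"{100 * s['mean_accuracy']:.2f}% | {100 * s['sensitivity']:.2f}% | "
            f"{100 * s['specificity']:.2f}% | {s['auc']:.4f} | "
            f"{s['p_value']:.4g} | {s['p_bonferroni']:.4g} |"
        )
    lines.append("")
    lines.append("## Figures")
    lines.extend(f"![{f}]({f})" for f in figs)
    path = out / report_name
    path.write_text("\n".join(lines) + "\n")
    return path
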