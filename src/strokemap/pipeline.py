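"""Stage runners orchestrating the full analysis on on-disk artifacts.

Each stage reads the previous stage's files and writes plain CSV/JSON (and
NIfTI for maps) into a workspace directory:

    workdir/cohort/     simulate: lesions, atlas, battery, ground truth
    workdir/behavior/   deficit transform + PCA/PROMAX artifacts
    workdir/lsm/        ridge models, weight maps, scatter data
    workdir/vascular/   overlap vectors, clusters, ANOVA tables
    workdir/report.json consolidated report with provenance

All randomness flows from the seed recorded in the run configuration, so a
stage re-run reproduces its artifacts byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ValidationError
from .behavior import BatteryTable, PromaxPCA, deficit_transform, ordered_correlation_matrix, zscore_columns
from .images import (
    LesionCohort,
    hemisphere_of,
    lesion_volume,
    overlap_map,
    resample_nearest,
    topography_summary,
    write_mask,
)
from .lsm import (
    RidgeLesionMapper,
    apply_display_threshold,
    backproject,
    build_feature_matrix,
    postprocess_map,
    spatial_correlation,
)
from .synthetic import SimulationConfig, generate_cohort, write_cohort
from .vascular import cluster_subjects, mixed_anova, overlap_vectors, posthoc_interaction

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_simulate",
    "run_behavior",
    "run_lsm",
    "run_lsm_compare",
    "run_vascular",
    "run_report",
]


@dataclass
class RunConfig:
    """One file describing a full reproducible run."""

    workdir: str = "strokemap_run"
    n_components: int = 3
    promax_power: int = 4
    rotate: bool = True
    min_lesion_count: int = 2
    lambda_low: float = 1e-2
    lambda_high: float = 1e4
    n_lambda: int = 20
    n_permutations: int = 1000
    k_range: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    seed: int = 0
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            # the run-level seed governs the whole pipeline unless the
            # simulation block pins its own
            self.simulation.setdefault("seed", self.seed)
            self.simulation = SimulationConfig(**self.simulation)
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")
        if self.lambda_low <= 0 or self.lambda_high <= self.lambda_low:
            raise ConfigError("need 0 < lambda_low < lambda_high")
        if self.n_lambda < 5:
            raise ConfigError("lambda grid needs >= 5 values")

    def lambda_grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.lambda_low), np.log10(self.lambda_high), self.n_lambda)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["grid_shape"] = list(self.simulation.grid_shape)
        d["simulation"]["subtest_maxima"] = self.simulation.subtest_maxima.tolist()
        d["simulation"]["loading_matrix"] = self.simulation.loading_matrix.tolist()
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d.setdefault("simulation", {})
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_simulate(config: RunConfig, force: bool = False, dry_run: bool = False) -> Path:
    """Generate the synthetic cohort into workdir/cohort."""
    sim = config.simulation
    sim.validate()
    outdir = Path(config.workdir) / "cohort"
    if dry_run:
        logger.info("dry run: config valid, would write cohort to %s", outdir)
        return outdir
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ValidationError(f"{outdir} already exists; pass force to overwrite")
    cohort, battery, truth = generate_cohort(sim)
    write_cohort(cohort, battery, truth, sim, outdir)
    logger.info("simulate: wrote %d subjects to %s", len(cohort), outdir)
    return outdir


def run_behavior(
    config: RunConfig,
    battery_csv: str | Path | None = None,
    maxima_csv: str | Path | None = None,
) -> Path:
    """Deficit transform -> z-score -> PCA -> PROMAX -> scores -> correlations."""
    work = Path(config.workdir)
    battery_csv = battery_csv or work / "cohort" / "battery.csv"
    maxima_csv = maxima_csv or work / "cohort" / "maxima.csv"
    outdir = work / "behavior"
    outdir.mkdir(parents=True, exist_ok=True)

    battery = BatteryTable.from_csv(battery_csv, maxima_csv)
    deficits = deficit_transform(battery)
    dm = zscore_columns(deficits)
    model = PromaxPCA(
        n_components=config.n_components, rotate=config.rotate, power=config.promax_power
    ).fit(dm.values)

    model.loading_table(dm.subtest_names).to_csv(outdir / "loadings.csv")
    scores = pd.DataFrame(
        model.scores_, columns=[f"pc{c + 1}" for c in range(config.n_components)]
    )
    scores.insert(0, "subject_id", dm.subject_ids)
    scores.to_csv(outdir / "scores.csv", index=False)
    pd.DataFrame(
        model.phi_,
        index=[f"pc{c + 1}" for c in range(config.n_components)],
        columns=[f"pc{c + 1}" for c in range(config.n_components)],
    ).to_csv(outdir / "phi.csv")
    ordered, _ = ordered_correlation_matrix(dm.values, model.pattern_, dm.subtest_names)
    ordered.to_csv(outdir / "correlation_ordered.csv")
    _write_json(
        {
            "n_subjects": len(battery.subject_ids),
            "n_subtests": len(battery.subtest_names),
            "dropped_subtests": dm.dropped_columns,
            "eigenvalues": model.eigenvalues_all_.tolist(),
            "variance_explained": model.variance_explained_.tolist(),
            "variance_explained_pct": (100 * model.variance_explained_).tolist(),
            "seed": config.seed,
        },
        outdir / "variance.json",
    )
    logger.info(
        "behavior: n=%d, variance explained %s%%",
        len(battery.subject_ids),
        np.round(100 * model.variance_explained_, 1).tolist(),
    )
    return outdir


def run_lsm(
    config: RunConfig,
    manifest_csv: str | Path | None = None,
    scores_csv: str | Path | None = None,
) -> Path:
    """Ridge lesion-symptom mapping for every behavioural component."""
    work = Path(config.workdir)
    manifest_csv = manifest_csv or work / "cohort" / "manifest.csv"
    scores_csv = scores_csv or work / "behavior" / "scores.csv"
    outdir = work / "lsm"
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = LesionCohort.from_manifest(manifest_csv)
    scores = pd.read_csv(scores_csv)

    # cohort-level lesion summaries (overlap map, topography table)
    write_mask(
        overlap_map(cohort).astype(np.float32), cohort.affine,
        outdir / "overlap_map.nii.gz", dtype=np.float32,
    )
    cohort_dir = Path(manifest_csv).parent
    cort_p, sub_p = cohort_dir / "cortical_mask.nii.gz", cohort_dir / "subcortical_mask.nii.gz"
    if cort_p.exists() and sub_p.exists():
        import nibabel as nib

        cort = np.asarray(nib.load(str(cort_p)).dataobj) > 0
        sub = np.asarray(nib.load(str(sub_p)).dataobj) > 0
        topography_summary(cohort, cort, sub).to_csv(outdir / "topography.csv", index=False)

    fm = build_feature_matrix(cohort, min_lesion_count=config.min_lesion_count)
    scores = scores.set_index("subject_id").loc[fm.subject_ids]
    grid = config.lambda_grid()

    by_image = {im.subject_id: im for im in cohort.images}
    for c in range(config.n_components):
        y = scores[f"pc{c + 1}"].to_numpy(float)
        mapper = RidgeLesionMapper(lambda_grid=grid).fit(fm.X, y)
        raw = backproject(mapper.coef_, fm)
        processed = postprocess_map(raw)
        thresholded = apply_display_threshold(processed)
        write_mask(raw.astype(np.float32), cohort.affine, outdir / f"weights_pc{c + 1}_raw.nii.gz", dtype=np.float32)
        write_mask(processed.astype(np.float32), cohort.affine, outdir / f"weights_pc{c + 1}_processed.nii.gz", dtype=np.float32)
        write_mask(thresholded.astype(np.float32), cohort.affine, outdir / f"weights_pc{c + 1}_display.nii.gz", dtype=np.float32)
        scatter = pd.DataFrame(
            {
                "subject_id": fm.subject_ids,
                "observed": y,
                "predicted": mapper.loocv_predictions_,
                "lesion_volume_mm3": [lesion_volume(by_image[s]) for s in fm.subject_ids],
                "hemisphere": [
                    hemisphere_of(by_image[s].mask, cohort.affine) for s in fm.subject_ids
                ],
            }
        )
        scatter.to_csv(outdir / f"scatter_pc{c + 1}.csv", index=False)
        _write_json(
            {
                "component": c + 1,
                "n_subjects": len(fm.subject_ids),
                "n_voxels": int(fm.X.shape[1]),
                "min_lesion_count": config.min_lesion_count,
                "lambda": mapper.lambda_,
                "fold_lambdas": mapper.fold_lambdas_.tolist(),
                "explained_variance_loocv": mapper.explained_variance_,
                "explained_variance_pct": 100 * mapper.explained_variance_,
                "in_sample_r2": mapper.in_sample_r2_,
                "loocv_pearson_r": mapper.pearson_r_,
                "ev_definition": (
                    "squared Pearson r of LOOCV predictions vs observations; "
                    "0 when the correlation is negative"
                ),
                "seed": config.seed,
            },
            outdir / f"model_pc{c + 1}.json",
        )
        logger.info(
            "lsm pc%d: LOOCV explained variance %.1f%% (lambda %.3g)",
            c + 1,
            100 * mapper.explained_variance_,
            mapper.lambda_,
        )
    return outdir


def run_lsm_compare(
    config: RunConfig,
    other_maps: list[str | Path],
    own_maps: list[str | Path] | None = None,
    out_json: str | Path | None = None,
) -> dict:
    """Spatial correlation of this run's processed maps against another set.

    The other maps are resampled (trilinearly) onto this run's grid; the
    permutation null uses random torus translations.
    """
    work = Path(config.workdir)
    own_maps = own_maps or [
        work / "lsm" / f"weights_pc{c + 1}_processed.nii.gz" for c in range(config.n_components)
    ]
    if len(own_maps) != len(other_maps):
        raise ValidationError("need one comparison map per component map")
    import nibabel as nib

    results = {"n_permutations": config.n_permutations, "seed": config.seed, "maps": []}
    rng = np.random.default_rng(config.seed)
    for c, (own_p, other_p) in enumerate(zip(own_maps, other_maps)):
        own_img = nib.load(str(own_p))
        other_img = nib.load(str(other_p))
        own = np.asarray(own_img.dataobj, dtype=float)
        other = resample_nearest(
            np.asarray(other_img.dataobj, dtype=float),
            other_img.affine,
            own.shape,
            own_img.affine,
            order=1,
        )
        r, p = spatial_correlation(own, other, n_permutations=config.n_permutations, rng=rng)
        results["maps"].append({"component": c + 1, "r": r, "p": p})
        logger.info("compare pc%d: r=%.3f p=%.4f", c + 1, r, p)
    out_json = out_json or work / "lsm" / "comparison.json"
    _write_json(results, Path(out_json))
    return results


def run_vascular(
    config: RunConfig,
    manifest_csv: str | Path | None = None,
    atlas_nii: str | Path | None = None,
    scores_csv: str | Path | None = None,
) -> Path:
    """Territory overlap -> clustering -> mixed ANOVA -> post hoc contrasts."""
    work = Path(config.workdir)
    manifest_csv = manifest_csv or work / "cohort" / "manifest.csv"
    atlas_nii = atlas_nii or work / "cohort" / "territory_atlas.nii.gz"
    scores_csv = scores_csv or work / "behavior" / "scores.csv"
    outdir = work / "vascular"
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = LesionCohort.from_manifest(manifest_csv)
    import nibabel as nib

    labels = np.asarray(nib.load(str(atlas_nii)).dataobj).astype(int)
    overlaps = overlap_vectors(cohort, labels)
    overlaps.to_csv(outdir / "overlap.csv", index=False)

    vectors = overlaps[["deep", "anterior_superior", "posterior_inferior"]].to_numpy(float)
    clusterer = cluster_subjects(vectors, k_range=tuple(config.k_range), seed=config.seed)
    assign = overlaps[["subject_id"]].copy()
    assign["cluster"] = clusterer.labels_
    assign.to_csv(outdir / "clusters.csv", index=False)
    clusterer.k_candidates_.to_csv(outdir / "k_candidates.csv", index=False)

    scores = pd.read_csv(scores_csv).set_index("subject_id").loc[assign["subject_id"]]
    Y = scores[[f"pc{c + 1}" for c in range(config.n_components)]].to_numpy(float)
    res = mixed_anova(Y, clusterer.labels_)
    posthoc = posthoc_interaction(Y, clusterer.labels_)
    res.table.to_csv(outdir / "anova.csv")
    posthoc.to_csv(outdir / "posthoc.csv", index=False)
    _write_json(
        {
            "n_subjects": int(len(assign)),
            "chosen_k": clusterer.k_,
            "silhouette": clusterer.silhouette_,
            "davies_bouldin": clusterer.davies_bouldin_,
            "interaction_F": res.F("interaction"),
            "interaction_p": res.p("interaction"),
            "between_F": res.F("between"),
            "between_p": res.p("between"),
            "within_F": res.F("within"),
            "within_p": res.p("within"),
            "gg_epsilon": res.gg_epsilon,
            "seed": config.seed,
        },
        outdir / "anova.json",
    )
    logger.info(
        "vascular: k=%d, interaction F=%.3f p=%.4f",
        clusterer.k_,
        res.F("interaction"),
        res.p("interaction"),
    )
    return outdir


def run_report(config: RunConfig) -> dict:
    """Consolidate stage artifacts into one report (JSON + text)."""
    work = Path(config.workdir)
    required = {
        "behavior": work / "behavior" / "variance.json",
        "lsm": work / "lsm" / "model_pc1.json",
        "vascular": work / "vascular" / "anova.json",
    }
    missing = [stage for stage, p in required.items() if not p.exists()]
    if missing:
        raise ValidationError(
            f"missing artifacts for stage(s) {missing}; run those stages first"
        )

    behavior = json.loads(required["behavior"].read_text())
    lsm_models = []
    for c in range(config.n_components):
        p = work / "lsm" / f"model_pc{c + 1}.json"
        if p.exists():
            lsm_models.append(json.loads(p.read_text()))
    vascular = json.loads(required["vascular"].read_text())
    comparison_path = work / "lsm" / "comparison.json"
    comparison = json.loads(comparison_path.read_text()) if comparison_path.exists() else None

    report = {
        "provenance": {
            "config_hash": self_hash(config),
            "seed": config.seed,
            "strokemap_version": __version__,
        },
        "attrition": {
            "battery_n": behavior["n_subjects"],
            "lsm_n": lsm_models[0]["n_subjects"] if lsm_models else None,
            "vascular_n": vascular["n_subjects"],
        },
        "behavior": behavior,
        "lsm": lsm_models,
        "map_comparison": comparison,
        "vascular": vascular,
    }
    _write_json(report, work / "report.json")

    lines = [
        f"strokemap run report (config {report['provenance']['config_hash']}, seed {config.seed})",
        "",
        f"Behaviour: n={behavior['n_subjects']}, dropped subtests: {behavior['dropped_subtests'] or 'none'}",
        "  variance explained (%): "
        + ", ".join(f"PC{i + 1} {v:.1f}" for i, v in enumerate(behavior["variance_explained_pct"])),
        "Lesion-symptom mapping (LOOCV explained variance, %):",
    ]
    for m in lsm_models:
        lines.append(
            f"  PC{m['component']}: {m['explained_variance_pct']:.1f}% "
            f"(lambda {m['lambda']:.3g}, {m['n_voxels']} voxels, n={m['n_subjects']})"
        )
    if comparison:
        for m in comparison["maps"]:
            lines.append(f"  map comparison PC{m['component']}: r={m['r']:.3f} p={m['p']:.4f}")
    lines += [
        f"Vascular control: n={vascular['n_subjects']}, k={vascular['chosen_k']} "
        f"(silhouette {vascular['silhouette']:.3f})",
        f"  interaction F={vascular['interaction_F']:.3f} p={vascular['interaction_p']:.4f} "
        f"(GG epsilon {vascular['gg_epsilon']:.3f})",
    ]
    (work / "report.txt").write_text("\n".join(lines) + "\n")
    return report


def self_hash(config: RunConfig) -> str:
    return config.config_hash()
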