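"""End-to-end orchestration: synth -> featurize -> classify.

A single :class:`RunConfig` drives everything.  Inputs are either a
synthetic cohort specification (regime-labelled systems generated by
:mod:`nrtraj.synthetic`) or explicit per-system file paths.  Every stage
writes delimited-text outputs into the run directory and the final report
echoes the configuration, package version and all derived seeds, so a rerun
with the same config reproduces every file.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conformers import ligand_properties
from .core import SystemLabel, Trajectory, select_atoms
from .energetics import EnergyTable, summarize_energies
from .errors import NrtrajError
from .geometry import (HelixAnchors, angle_series, com_distance_series, rmsf,
                       superpose_trajectory)
from .interactions import InteractionCriteria, occupancy_series
from .secondary import sse_fraction
from .som import som_fit
from .stats import FeatureTable, assemble_features, autoscale, kruskal_dunn, pca
from .synthetic import (InteractionPlantSpec, agonist_params, antagonist_params,
                        plant_complex, simulate_bundle, synth_energy_table,
                        synthetic_anchors)

#: Planted occupancies per regime for the synthetic cohort (before per-system
#: jitter): agonist-like systems keep the anchoring H-bond most of the time.
COHORT_OCCUPANCY = {
    "agonist_like": {"hbond": 0.9, "hydrophobic": 0.7, "pipi": 0.5, "water_bridge": 0.3},
    "antagonist_like": {"hbond": 0.3, "hydrophobic": 0.5, "pipi": 0.2, "water_bridge": 0.1},
}
#: Mean total binding energy (kcal/mol) per regime for the synthetic cohort.
COHORT_ENERGY_MEAN = {"agonist_like": -20.0, "antagonist_like": -14.0}


@dataclass
class CohortSpec:
    """Synthetic cohort: systems per regime and per-system problem sizes."""

    n_agonist: int = 6
    n_antagonist: int = 6
    frames_per_system: int = 150
    interaction_frames: int = 100
    energy_replicas: int = 3
    energy_frames: int = 200
    energy_sd: float = 2.0


@dataclass
class SystemInput:
    """File-based system: a bundle trajectory, a complex trajectory, energies."""

    bundle_path: str
    complex_path: str
    energy_path: str
    label: SystemLabel = field(default_factory=SystemLabel)
    activity_class: str = ""


@dataclass
class RunConfig:
    cohort: CohortSpec | None = None
    inputs: list[SystemInput] = field(default_factory=list)
    anchors: HelixAnchors = field(default_factory=synthetic_anchors)
    criteria: InteractionCriteria = field(default_factory=InteractionCriteria)
    stride: int = 10
    outlier_k: float = 3.0
    n_components: int = 2
    som_epochs: int = 30
    som_grid: tuple = (10, 10)
    seed: int = 0
    output_dir: str = "nrtraj_run"


@dataclass
class SystemData:
    """In-memory bundle of everything one system contributes."""

    bundle: Trajectory
    complex_traj: Trajectory
    energy: EnergyTable
    label: SystemLabel
    activity_class: str


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems (empty means valid); never raises."""
    problems: list[str] = []
    if config.cohort is None and not config.inputs:
        problems.append("config needs either a synthetic cohort spec or file inputs")
    for span_name in ("h3b", "h10", "h12"):
        span = getattr(config.anchors, span_name)
        if len(span) < 8:
            problems.append(
                f"anchor span {span_name} has {len(span)} residues; helix axis needs >= 8")
    for sysin in config.inputs:
        for attr in ("bundle_path", "complex_path", "energy_path"):
            path = getattr(sysin, attr)
            if not Path(path).exists():
                problems.append(f"missing file: {path}")
    if config.stride < 1:
        problems.append("stride must be >= 1")
    if config.n_components < 1:
        problems.append("n_components must be >= 1")
    return problems


def _cohort_systems(spec: CohortSpec, anchors: HelixAnchors, seed: int) -> list[SystemData]:
    """Generate the regime-labelled synthetic cohort, one seed stream per system."""
    rng = np.random.default_rng(seed)
    systems = []
    plan = ([("agonist_like", i) for i in range(spec.n_agonist)]
            + [("antagonist_like", i) for i in range(spec.n_antagonist)])
    for regime, i in plan:
        sub = int(rng.integers(0, 2 ** 31 - 1))
        srng = np.random.default_rng(sub)
        maker = agonist_params if regime == "agonist_like" else antagonist_params
        params = maker(
            n_frames=spec.frames_per_system, seed=int(srng.integers(0, 2 ** 31 - 1)),
            ang1_mean=maker().ang1_mean + srng.normal(0, 2.0),
            ang2_mean=maker().ang2_mean + srng.normal(0, 3.0),
            helix_content_mean=float(np.clip(
                maker().helix_content_mean + srng.normal(0, 0.02), 0.0, 1.0)),
        )
        start = "AGO" if regime == "agonist_like" else "ANT"
        label = SystemLabel(receptor="synthetic", ligand=f"{regime[:3].upper()}{i:02d}",
                            start_conformation=start)
        bundle = simulate_bundle(params, anchors, system_label=label)
        occ = COHORT_OCCUPANCY[regime]
        specs = [InteractionPlantSpec(kind=k, presence_fraction=float(np.clip(
            p + srng.normal(0, 0.03), 0.0, 1.0))) for k, p in occ.items()]
        complex_traj = plant_complex(specs, n_frames=spec.interaction_frames,
                                     seed=int(srng.integers(0, 2 ** 31 - 1)),
                                     system_label=label)
        energy = synth_energy_table(
            n_replicas=spec.energy_replicas, frames_per_replica=spec.energy_frames,
            mean=COHORT_ENERGY_MEAN[regime] + srng.normal(0, 1.0), sd=spec.energy_sd,
            hac=int(srng.integers(15, 31)), seed=int(srng.integers(0, 2 ** 31 - 1)))
        activity = "agonist" if regime == "agonist_like" else "antagonist"
        systems.append(SystemData(bundle=bundle, complex_traj=complex_traj,
                                  energy=energy, label=label, activity_class=activity))
    return systems


def featurize_system(system: SystemData, anchors: HelixAnchors,
                     criteria: InteractionCriteria, stride: int = 10,
                     outlier_k: float = 3.0) -> dict:
    """The standard descriptor registry for one system.

    Columns: interaction occupancies per pocket residue/kind, per-helix RMSF
    medians, inter-helix distance medians, Ang1/Ang2 medians and SDs, H12
    SSE%, mean ligand efficiency and lipophilic/Coulomb terms, and ligand
    shape properties (HAC, Rg, molecular surface).
    """
    bundle = system.bundle
    top = bundle.topology
    desc: dict[str, float] = {}

    occ = occupancy_series(system.complex_traj, criteria)
    for kind in ("hbond", "hydrophobic", "pipi", "water_bridge"):
        sel = occ[occ["kind"] == kind]
        desc[f"occ_{kind}"] = float(sel["fraction"].max()) if len(sel) else 0.0

    backbone = select_atoms(top, role="backbone")
    aligned = superpose_trajectory(bundle, backbone)
    for key, span in (("h3b", anchors.h3b), ("h10", anchors.h10), ("h12", anchors.h12)):
        ca = select_atoms(top, span=span, role="c_alpha")
        desc[f"rmsf_{key}_median"] = float(rmsf(aligned, ca).median())

    for key, (a, b) in (("h12_h3b", (anchors.h12, anchors.h3b)),
                        ("h12_h10", (anchors.h12, anchors.h10)),
                        ("h10_h3b", (anchors.h10, anchors.h3b))):
        desc[f"dist_{key}_median"] = float(np.median(
            com_distance_series(bundle, a, b).values))

    angles = angle_series(bundle, anchors)
    desc["ang1_median"] = float(np.median(angles.ang1))
    desc["ang1_sd"] = float(np.std(angles.ang1, ddof=1))
    desc["ang2_median"] = float(np.median(angles.ang2))
    desc["ang2_sd"] = float(np.std(angles.ang2, ddof=1))

    desc["sse_h12"] = sse_fraction(bundle, anchors.h12).mean_fraction

    summary = summarize_energies(system.energy, subsample=True, stride=stride,
                                 outlier_k=outlier_k)
    desc["le_mean"] = float(summary.pooled["le_mean"])
    desc["dg_lipo_mean"] = float(summary.pooled["dg_lipo_mean"])
    desc["dg_coulomb_mean"] = float(summary.pooled["dg_coulomb_mean"])

    ctop = system.complex_traj.topology
    lig_heavy = select_atoms(ctop, role=["ligand", "heavy"])
    props = ligand_properties(system.complex_traj.frames[0], ctop, lig_heavy,
                              n_points=240)
    desc["hac"] = float(system.energy.hac)
    desc["rg"] = props.radius_of_gyration
    desc["mol_surface"] = props.molecular_surface
    return desc


def classify(features: FeatureTable, n_components: int = 2,
             som_epochs: int = 30, som_grid: tuple = (10, 10), seed: int = 0) -> dict:
    """Autoscale, then PCA + SOM; returns all result objects."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        scaled = autoscale(features)
    n_components = min(n_components, scaled.n_systems - 1, scaled.data.shape[1])
    pca_res = pca(scaled, n_components)
    som_res = som_fit(scaled, grid=som_grid, epochs=som_epochs, seed=seed)
    return {"scaled": scaled, "pca": pca_res, "som": som_res,
            "warnings": [str(w.message) for w in caught]}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.output_dir``.

    Returns the report dict.  Raises on the first stage failure, after
    writing a FAILED marker naming the stage into the run directory.
    """
    problems = validate_config(config)
    if problems:
        raise NrtrajError("invalid config: " + "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "synth"
    try:
        if config.cohort is not None:
            systems = _cohort_systems(config.cohort, config.anchors, config.seed)
        else:
            from .io import read_energy_table, read_structure  # local: optional stage
            systems = []
            for sysin in config.inputs:
                systems.append(SystemData(
                    bundle=read_structure(sysin.bundle_path, system_label=sysin.label),
                    complex_traj=read_structure(sysin.complex_path,
                                                system_label=sysin.label),
                    energy=read_energy_table(sysin.energy_path),
                    label=sysin.label, activity_class=sysin.activity_class))

        stage = "featurize"
        descriptors, labels = {}, {}
        for k, system in enumerate(systems):
            descriptors[k] = featurize_system(system, config.anchors, config.criteria,
                                              config.stride, config.outlier_k)
            labels[k] = {"receptor": system.label.receptor,
                         "ligand": system.label.ligand,
                         "start_conformation": system.label.start_conformation,
                         "activity_class": system.activity_class}
        features = assemble_features(descriptors, labels)
        feat_out = pd.concat([features.labels, features.data], axis=1)
        feat_out.to_csv(out / "features.csv", index=False)

        stage = "classify"
        results = classify(features, config.n_components, config.som_epochs,
                           config.som_grid, config.seed)
        pd.concat([features.labels, results["pca"].scores], axis=1).to_csv(
            out / "pca_scores.csv", index=False)
        results["pca"].loadings.to_csv(out / "pca_loadings.csv")
        som_df = features.labels.copy()
        som_df[["som_row", "som_col"]] = results["som"].assignments
        som_df.to_csv(out / "som_assignments.csv", index=False)

        stage = "stats"
        classes = features.labels["activity_class"]
        stats_rows = []
        for column in ("ang2_median", "dist_h12_h10_median", "le_mean", "sse_h12"):
            if column not in features.data.columns:
                continue
            groups = [features.data.loc[classes == c, column].to_numpy()
                      for c in sorted(classes.unique()) if (classes == c).sum() > 0]
            if len(groups) >= 2:
                res = kruskal_dunn(groups)
                stats_rows.append({"descriptor": column, "H": res.h_statistic,
                                   "p": res.p_value})
        pd.DataFrame(stats_rows).to_csv(out / "group_tests.csv", index=False)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise

    scores = results["pca"].scores["PC1"]
    report = {
        "version": __version__,
        "seed": config.seed,
        "n_systems": len(systems),
        "config": _config_echo(config),
        "explained_fraction": [float(x) for x in results["pca"].explained_fraction],
        "pc1_by_class": {c: [float(v) for v in scores[classes == c]]
                         for c in sorted(classes.unique())},
        "som_quantization_error": results["som"].quantization_error,
        "warnings": results["warnings"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [enc(x) for x in obj]
        return obj
    return enc(config)


def pc1_separation(report: dict, class_a: str = "agonist",
                   class_b: str = "antagonist") -> int:
    """Misclassification count of the best threshold on PC1 between two classes."""
    a = np.asarray(report["pc1_by_class"].get(class_a, []))
    b = np.asarray(report["pc1_by_class"].get(class_b, []))
    if len(a) == 0 or len(b) == 0:
        raise NrtrajError("both classes need PC1 scores")
    cuts = np.sort(np.concatenate([a, b, [np.inf]]))
    best = len(a) + len(b)
    for cut in cuts:
        err1 = np.sum(a >= cut) + np.sum(b < cut)
        err2 = np.sum(b >= cut) + np.sum(a < cut)
        best = min(best, int(err1), int(err2))
    return best
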