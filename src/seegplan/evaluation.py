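"""Apparent-versus-true risk evaluation across vessel-model fidelities.

The core experiment: implantations are planned against each modality's
vessel model, the trajectories are then frozen and re-scored against the
other models — in particular against the gold standard, giving each
electrode an "apparent" risk (the value the planner saw) and a "true"
risk (what the gold-standard vasculature implies for the same path).
A diameter sweep prunes the gold model at 1-4 mm and re-scores the same
trajectories, locating the diameter at which a degraded modality becomes
equivalent to the pruned gold standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid
from .mesh import SurfaceMesh, MeshDistanceQuery
from .models import (
    extract_sulcal_model,
    prune_by_diameter,
    segment_vessels,
)
from .phantom import Phantom, make_phantom, tree_to_mesh
from .planner import (
    Plan,
    RiskConfig,
    node_distances,
    min_distance,
    risk_score,
    plan_implantation,
    PlanningResult,
)
from .stats import paired_compare, pearson_r2
from .config import StudyConfig

TABLE_COLUMNS = [
    "phantom_seed",
    "electrode",
    "planning_model",
    "evaluation_model",
    "prune_mm",
    "rs",
    "md",
]


def recompute_plan_metrics(
    plan: Plan,
    vessels: SurfaceMesh,
    sulci: SurfaceMesh | None = None,
    risk_cfg: RiskConfig | None = None,
    evaluation_model: str = "",
    prune_mm: float | None = None,
    phantom_seed: int | None = None,
) -> list[dict]:
    """Re-score a frozen plan against an alternative critical-structure model.

    Trajectories are not re-planned; only RS and MD are recomputed, which
    is exactly the apparent-vs-true comparison.
    """
    risk_cfg = risk_cfg or RiskConfig()
    critical = [vessels] + ([sulci] if sulci is not None else [])
    queries = [MeshDistanceQuery(m) for m in critical if not m.is_empty]
    rows = []
    for name, traj, _ in plan.electrodes:
        d = node_distances(traj, critical, queries)
        rows.append(
            {
                "phantom_seed": phantom_seed,
                "electrode": name,
                "planning_model": plan.critical_model_id,
                "evaluation_model": evaluation_model,
                "prune_mm": prune_mm,
                "rs": risk_score(d, risk_cfg),
                "md": min_distance(d),
            }
        )
    return rows


def diameter_sweep(
    plan: Plan,
    gold: SurfaceMesh,
    thresholds_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0),
    sulci: SurfaceMesh | None = None,
    risk_cfg: RiskConfig | None = None,
    phantom_seed: int | None = None,
) -> list[dict]:
    """Re-score a frozen plan against the gold model pruned at each diameter."""
    if gold.vertex_radius is None:
        raise ValueError("diameter sweep requires gold-model vertex radii")
    rows = []
    for t in thresholds_mm:
        pruned = prune_by_diameter(gold, t)
        rows.extend(
            recompute_plan_metrics(
                plan, pruned, sulci, risk_cfg,
                evaluation_model=f"gold_pruned",
                prune_mm=float(t),
                phantom_seed=phantom_seed,
            )
        )
    return rows


def classify_vessel_regions(
    vessels: SurfaceMesh,
    sulcal_mask: np.ndarray,
    gm_mask: np.ndarray,
    intracranial_mask: np.ndarray,
    grid: Grid,
    reference: SurfaceMesh | None = None,
    reference_tol_mm: float = 1.0,
) -> dict[str, float]:
    """Vertex-count proportions of vessels by anatomical region.

    Each vertex is labelled, with precedence: present in the reference
    model (within ``reference_tol_mm`` of its surface), inside the sulcal
    mask, in the superficial gray-matter ribbon (cortical surface), else
    intracerebral.  Proportions sum to 1.
    """
    n = vessels.n_vertices
    if n == 0:
        return {k: 0.0 for k in
                ("present_in_reference", "sulcal", "cortical_surface", "intracerebral")}
    labels = np.full(n, "intracerebral", dtype=object)
    pts = vessels.vertices
    in_sulcal = grid.contains_points(np.asarray(sulcal_mask, bool), pts)
    ribbon = np.asarray(gm_mask, bool) & ~np.asarray(sulcal_mask, bool)
    in_ribbon = grid.contains_points(ribbon, pts)
    labels[in_ribbon] = "cortical_surface"
    labels[in_sulcal] = "sulcal"
    if reference is not None and not reference.is_empty:
        d = MeshDistanceQuery(reference).distances(pts)
        labels[d <= reference_tol_mm] = "present_in_reference"
    out = {}
    for k in ("present_in_reference", "sulcal", "cortical_surface", "intracerebral"):
        out[k] = float(np.mean(labels == k))
    return out


# ---------------------------------------------------------------------------
# Cohort study
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    table: pd.DataFrame
    stats: dict
    config: StudyConfig
    seed: int
    # per-phantom artifacts: {"seed", "models": {name: mesh}, "results":
    # {name: PlanningResult}} — kept so plans can be re-validated externally
    artifacts: list[dict] = field(default_factory=list)


def build_models(
    phantom: Phantom, config: StudyConfig
) -> dict[str, SurfaceMesh]:
    """One critical-structure vessel model per modality.

    ``imaging`` runs the full chain (vesselness, masking, isosurface,
    cleanup, centreline radii) on the rendered volumes; ``analytic``
    builds tube meshes straight from the truth tree at each modality's
    visibility floor, with true radii — the noiseless geometric limit of
    the imaging chain.
    """
    out: dict[str, SurfaceMesh] = {}
    if config.model_source == "analytic":
        for prof in phantom.config.profiles:
            out[prof.name] = tree_to_mesh(phantom.tree, prof.min_visible_diameter)
        return out
    for prof in phantom.config.profiles:
        out[prof.name] = segment_vessels(
            phantom.modality_images[prof.name],
            phantom.grid,
            phantom.intracranial_mask,
            params=config.vesselness,
            min_component_vertices=config.min_component_vertices,
            compute_radii=True,
        )
    return out


def _gold_name(config: StudyConfig) -> str:
    profs = config.phantom.profiles
    return min(profs, key=lambda p: p.min_visible_diameter).name


def evaluate_phantom(
    phantom: Phantom, config: StudyConfig, seed: int
) -> tuple[list[dict], tuple[dict[str, SurfaceMesh], dict[str, PlanningResult]]]:
    """Plan per modality model, cross-evaluate on gold, sweep diameters."""
    models = build_models(phantom, config)
    gold_name = _gold_name(config)
    sulci = None
    if config.use_sulci:
        # target nuclei are implantation targets, not avoidance structures:
        # drop them from the gray matter before building the sulcal model
        sulcal_gm = phantom.gm_mask & (phantom.target_rois == 0)
        sulci = extract_sulcal_model(
            sulcal_gm, phantom.intracranial_mask, phantom.grid,
            config.sulcal_erosion_mm,
        )
    rows = []
    results: dict[str, PlanningResult] = {}
    for name, mesh in models.items():
        res = plan_implantation(
            phantom.skull_mesh,
            phantom.target_rois,
            phantom.gm_mask,
            phantom.grid,
            [mesh] + ([sulci] if sulci is not None else []),
            seed=seed,
            electrode=config.electrode,
            constraints=config.constraints,
            risk_cfg=config.risk,
            weights=config.weights,
            settings=config.planner,
            critical_model_id=name,
        )
        results[name] = res
        # apparent: the model the plan was made on
        rows.extend(
            recompute_plan_metrics(
                res.plan, mesh, sulci, config.risk,
                evaluation_model=name, phantom_seed=phantom.seed,
            )
        )
        # true: the gold model
        if name != gold_name:
            rows.extend(
                recompute_plan_metrics(
                    res.plan, models[gold_name], sulci, config.risk,
                    evaluation_model=gold_name, phantom_seed=phantom.seed,
                )
            )
        # sweep: gold pruned at each diameter threshold
        if models[gold_name].vertex_radius is not None:
            rows.extend(
                diameter_sweep(
                    res.plan, models[gold_name], config.prune_thresholds_mm,
                    sulci, config.risk, phantom_seed=phantom.seed,
                )
            )
    return rows, (models, results)


def run_study(
    seed: int,
    config: StudyConfig | None = None,
    out_dir=None,
    keep_artifacts: bool = False,
) -> StudyReport:
    """Full synthetic cohort: phantoms, per-modality plans, cross-scoring,
    diameter sweep and the gated statistics.

    Deterministic in (seed, config).  Phantom i uses seed*1000 + i.
    """
    config = config or StudyConfig()
    config.validate()
    all_rows: list[dict] = []
    artifacts: list[dict] = []
    for i in range(config.n_phantoms):
        ph_seed = seed * 1000 + i
        phantom = make_phantom(ph_seed, config.phantom)
        rows, (models, results) = evaluate_phantom(phantom, config, seed=ph_seed)
        all_rows.extend(rows)
        if keep_artifacts:
            artifacts.append(
                {"seed": ph_seed, "models": models, "results": results}
            )
    table = pd.DataFrame(all_rows, columns=TABLE_COLUMNS)
    stats = compute_study_stats(table, config)
    report = StudyReport(
        table=table, stats=stats, config=config, seed=seed, artifacts=artifacts
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def compute_study_stats(table: pd.DataFrame, config: StudyConfig) -> dict:
    """Cohort statistics: true-risk direction, per-threshold equivalence
    tests and apparent/true correlation per degraded modality."""
    gold_name = _gold_name(config)
    degraded = [
        p.name for p in config.phantom.profiles if p.name != gold_name
    ]
    key = ["phantom_seed", "electrode"]
    stats: dict = {"gold_model": gold_name, "models": {}}

    gold_self = table[
        (table.planning_model == gold_name)
        & (table.evaluation_model == gold_name)
        & table.prune_mm.isna()
    ].set_index(key)
    stats["median_true_rs"] = {gold_name: float(gold_self.rs.median())}
    stats["median_true_md"] = {gold_name: float(gold_self.md.median())}

    for name in degraded:
        sub = table[table.planning_model == name]
        apparent = sub[(sub.evaluation_model == name) & sub.prune_mm.isna()]
        true = sub[(sub.evaluation_model == gold_name) & sub.prune_mm.isna()]
        apparent = apparent.set_index(key).sort_index()
        true = true.set_index(key).sort_index()
        common = apparent.index.intersection(true.index)
        a_rs = apparent.loc[common, "rs"].to_numpy()
        t_rs = true.loc[common, "rs"].to_numpy()
        a_md = apparent.loc[common, "md"].to_numpy()
        t_md = true.loc[common, "md"].to_numpy()

        entry: dict = {
            "n_electrodes": int(len(common)),
            "median_apparent_rs": float(np.median(a_rs)),
            "median_true_rs": float(np.median(t_rs)),
            "median_apparent_md": float(np.median(a_md)),
            "median_true_md": float(np.median(t_md)),
            "apparent_le_true_fraction": float(np.mean(a_rs <= t_rs + 1e-12)),
        }
        stats["median_true_rs"][name] = entry["median_true_rs"]
        stats["median_true_md"][name] = entry["median_true_md"]
        try:
            entry["r2_apparent_true_rs"] = pearson_r2(a_rs, t_rs)
        except ValueError:
            entry["r2_apparent_true_rs"] = float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cmp_rs = paired_compare(
                a_rs, t_rs, f"{name}: apparent vs true RS",
                config.alpha_family, config.n_comparisons,
            )
        entry["apparent_vs_true_rs_p"] = cmp_rs.p
        entry["apparent_vs_true_rs_test"] = cmp_rs.test_used

        # equivalence sweep: apparent (this model) vs gold pruned at t
        entry["equivalence"] = {}
        for t in config.prune_thresholds_mm:
            pruned = sub[
                (sub.evaluation_model == "gold_pruned") & (sub.prune_mm == t)
            ].set_index(key).sort_index()
            pc = pruned.index.intersection(common)
            if len(pc) < 3:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp_t = paired_compare(
                    apparent.loc[pc, "rs"].to_numpy(),
                    pruned.loc[pc, "rs"].to_numpy(),
                    f"{name}: apparent vs gold pruned at {t} mm",
                    config.alpha_family, config.n_comparisons,
                )
                cmp_md = paired_compare(
                    apparent.loc[pc, "md"].to_numpy(),
                    pruned.loc[pc, "md"].to_numpy(),
                    f"{name}: apparent MD vs gold pruned at {t} mm",
                    config.alpha_family, config.n_comparisons,
                )
            entry["equivalence"][float(t)] = {
                "rs_p": cmp_t.p,
                "rs_significant": cmp_t.significant,
                "md_p": cmp_md.p,
                "md_significant": cmp_md.significant,
                "adjusted_alpha": cmp_t.adjusted_alpha,
            }
        stats["models"][name] = entry
    return stats


def write_report(report: StudyReport, out_dir) -> None:
    """CSV table, JSON stats, YAML config echo and summary figures."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(out / "evaluation_table.csv", index=False)
    (out / "stats.json").write_text(json.dumps(report.stats, indent=2, default=float))
    (out / "config.yaml").write_text(report.config.to_yaml())
    (out / "seed.txt").write_text(str(report.seed))
    _plot_report(report, out)


def _plot_report(report: StudyReport, out) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = report.table
    gold = report.stats["gold_model"]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    models = sorted(table.planning_model.unique())
    true_rs = [
        table[
            (table.planning_model == m)
            & (table.evaluation_model == gold)
            & table.prune_mm.isna()
        ].rs
        for m in models
    ]
    axes[0].boxplot(true_rs, tick_labels=models)
    axes[0].set_ylabel("true risk score (vs gold model)")
    apparent_rs = [
        table[
            (table.planning_model == m)
            & (table.evaluation_model == m)
            & table.prune_mm.isna()
        ].rs
        for m in models
    ]
    axes[1].boxplot(apparent_rs, tick_labels=models)
    axes[1].set_ylabel("apparent risk score (planning model)")
    fig.tight_layout()
    fig.savefig(out / "risk_scores.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for m in models:
        sweep = table[
            (table.planning_model == m) & (table.evaluation_model == "gold_pruned")
        ]
        med = sweep.groupby("prune_mm").rs.median()
        ax.plot(med.index, med.values, marker="o", label=m)
    ax.set_xlabel("pruning diameter (mm)")
    ax.set_ylabel("median RS vs pruned gold model")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "diameter_sweep.png", dpi=120)
    plt.close(fig)
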