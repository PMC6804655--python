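"""Computer-assisted multi-electrode trajectory planning.

Candidate target points are drawn from deep target regions at a safety
margin from critical structures; entry points are sampled on the skull.
Hard constraints (intracerebral length, drilling angle to the skull
normal, collision with critical meshes) prune the candidate pairs, and a
per-plan optimiser picks one trajectory per electrode so that all
trajectories stay >= 10 mm apart while minimising a cost that trades off
risk score, gray-matter contact ratio and length.

The risk score (RS) of a trajectory with N sampled nodes and node-to-
critical-structure distances Dist(i) (electrode radius already deducted,
floored at zero, clamped above at 10 mm) is

    RS = sum_i (10 - Dist(i)) / (N * (10 - 3))            if min_i Dist > 3
    RS = 1 + sum_{i: Dist(i) <= 3} (3 - Dist(i)) / (3 N)  otherwise

so RS is 0 for a trajectory never nearer than 10 mm, 1 when it rides the
3 mm safety margin, and 2 when every node touches a critical structure.
The regime is chosen per trajectory: one sub-margin node puts the whole
trajectory in the risky branch.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

from .grids import Grid
from .mesh import (
    SurfaceMesh,
    MeshDistanceQuery,
    surface_distance,
    segment_intersects_mesh,
    segment_segment_distance,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeSpec:
    """Generic depth-electrode geometry (any manufacturer)."""

    diameter_mm: float = 1.3
    n_contacts: int = 10
    contact_length_mm: float = 2.4
    contact_spacing_mm: float = 5.0

    def __post_init__(self) -> None:
        if min(
            self.diameter_mm, self.n_contacts,
            self.contact_length_mm, self.contact_spacing_mm,
        ) <= 0:
            raise ValueError("electrode spec fields must be positive")

    @property
    def radius_mm(self) -> float:
        return 0.5 * self.diameter_mm


@dataclass(frozen=True)
class RiskConfig:
    """Constants of the risk-score equation."""

    safety_distance_mm: float = 10.0
    margin_mm: float = 3.0
    n_nodes: int = 128

    def __post_init__(self) -> None:
        if not (self.safety_distance_mm > self.margin_mm > 0):
            raise ValueError("require safety_distance > margin > 0")


@dataclass(frozen=True)
class PlanConstraints:
    """Hard feasibility constraints on a single trajectory and on the plan."""

    max_length_mm: float = 90.0
    max_angle_to_normal_deg: float = 30.0
    min_target_margin_mm: float = 3.0
    min_pairwise_mm: float = 10.0

    def __post_init__(self) -> None:
        if min(
            self.max_length_mm, self.max_angle_to_normal_deg,
            self.min_target_margin_mm, self.min_pairwise_mm,
        ) <= 0:
            raise ValueError("constraints must be positive")


@dataclass(frozen=True)
class CostWeights:
    """Per-candidate cost = w_rs*RS - w_gm*gm_ratio + w_len*(length/max)."""

    w_rs: float = 1.0
    w_gm: float = 0.3
    w_len: float = 0.1


@dataclass
class Trajectory:
    """Straight electrode path from skull entry to deep target."""

    entry: np.ndarray
    target: np.ndarray
    electrode: ElectrodeSpec = field(default_factory=ElectrodeSpec)
    n_nodes: int = 128

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float).reshape(3)
        self.target = np.asarray(self.target, dtype=float).reshape(3)

    @property
    def nodes(self) -> np.ndarray:
        """N points uniformly spaced from entry to target (inclusive)."""
        t = np.linspace(0.0, 1.0, self.n_nodes)[:, None]
        return self.entry[None, :] * (1 - t) + self.target[None, :] * t

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.target - self.entry))

    @property
    def direction(self) -> np.ndarray:
        d = self.target - self.entry
        return d / max(np.linalg.norm(d), 1e-12)


@dataclass
class TrajectoryMetrics:
    rs: float
    md: float
    length: float
    angle_deg: float
    gm_ratio: float
    collision: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.rs <= 2.0):
            raise ValueError("risk score out of [0, 2]")


@dataclass
class Plan:
    """One trajectory per electrode plus the model the plan was made on."""

    electrodes: list[tuple[str, Trajectory, TrajectoryMetrics]]
    critical_model_id: str = ""

    def min_pairwise_distance(self) -> float:
        if len(self.electrodes) < 2:
            return np.inf
        best = np.inf
        for (_, a, _), (_, b, _) in itertools.combinations(self.electrodes, 2):
            best = min(
                best,
                segment_segment_distance(a.entry, a.target, b.entry, b.target),
            )
        return best


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def node_distances(
    t: Trajectory, critical: list[SurfaceMesh],
    queries: list[MeshDistanceQuery] | None = None,
) -> np.ndarray:
    """Dist(i): surface distance of each node minus the electrode radius.

    Floored at zero (a node whose clearance is consumed by the electrode
    body counts as touching).  All-empty critical sets give +inf so a
    trajectory with nothing to avoid scores RS = 0 downstream.
    """
    if queries is None:
        queries = [MeshDistanceQuery(m) for m in critical if not m.is_empty]
    pts = t.nodes
    d = np.full(len(pts), np.inf)
    for q in queries:
        d = np.minimum(d, q.distances(pts))
    return np.maximum(d - t.electrode.radius_mm, 0.0)


def risk_score(distances: np.ndarray, cfg: RiskConfig | None = None) -> float:
    """Piecewise cumulative-proximity risk score in [0, 2]."""
    cfg = cfg or RiskConfig()
    d = np.asarray(distances, dtype=float)
    if len(d) != cfg.n_nodes:
        raise ValueError(
            f"expected {cfg.n_nodes} node distances, got {len(d)}"
        )
    s, m, n = cfg.safety_distance_mm, cfg.margin_mm, cfg.n_nodes
    if np.min(d) > m:
        clamped = np.minimum(d, s)
        return float(np.sum(s - clamped) / (n * (s - m)))
    risky = d <= m
    return float(1.0 + np.sum(m - d[risky]) / (m * n))


def _risk_scores_batch(D: np.ndarray, cfg: RiskConfig) -> np.ndarray:
    """Vectorised risk scores for a (n_trajectories, n_nodes) distance matrix."""
    s, m, n = cfg.safety_distance_mm, cfg.margin_mm, cfg.n_nodes
    min_d = D.min(axis=1)
    safe = np.sum(s - np.minimum(D, s), axis=1) / (n * (s - m))
    risky = 1.0 + np.sum((m - D) * (D <= m), axis=1) / (m * n)
    return np.where(min_d > m, safe, risky)


def min_distance(distances: np.ndarray) -> float:
    """Minimum node distance (MD) of a trajectory."""
    d = np.asarray(distances, dtype=float)
    if len(d) == 0:
        raise ValueError("empty distance vector")
    return float(np.min(d))


def gm_contact_ratio(t: Trajectory, gm_mask: np.ndarray, grid: Grid) -> float:
    """Fraction of electrode contact centres lying in gray matter.

    Contacts are placed from the target backwards along the trajectory at
    the spec's centre-to-centre spacing; contacts beyond the entry count
    as outside.
    """
    e = t.electrode
    offsets = e.contact_length_mm / 2.0 + np.arange(e.n_contacts) * e.contact_spacing_mm
    back = -t.direction  # from target toward entry
    centers = t.target[None, :] + offsets[:, None] * back[None, :]
    valid = offsets <= t.length
    inside = np.zeros(e.n_contacts, dtype=bool)
    if valid.any():
        inside[valid] = grid.contains_points(gm_mask, centers[valid])
    return float(inside.mean())


def trajectory_metrics(
    t: Trajectory,
    critical: list[SurfaceMesh],
    gm_mask: np.ndarray,
    grid: Grid,
    entry_normal: np.ndarray | None = None,
    cfg: RiskConfig | None = None,
    queries: list[MeshDistanceQuery] | None = None,
) -> TrajectoryMetrics:
    cfg = cfg or RiskConfig()
    d = node_distances(t, critical, queries)
    angle = 0.0
    if entry_normal is not None:
        inward = -np.asarray(entry_normal, dtype=float)
        inward = inward / max(np.linalg.norm(inward), 1e-12)
        cosang = np.clip(t.direction @ inward, -1.0, 1.0)
        angle = float(np.degrees(np.arccos(cosang)))
    return TrajectoryMetrics(
        rs=risk_score(d, cfg),
        md=min_distance(d),
        length=t.length,
        angle_deg=angle,
        gm_ratio=gm_contact_ratio(t, gm_mask, grid),
        collision=bool(np.min(d) <= 0.0),
    )


# ---------------------------------------------------------------------------
# Candidate generation and filtering
# ---------------------------------------------------------------------------

def sample_target_candidates(
    roi_mask: np.ndarray,
    grid: Grid,
    critical: list[SurfaceMesh],
    margin_mm: float = 3.0,
    electrode: ElectrodeSpec | None = None,
) -> np.ndarray:
    """ROI voxel centres at >= margin + electrode radius from all critical
    surfaces."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty target ROI")
    electrode = electrode or ElectrodeSpec()
    pts = grid.voxel_to_world(np.array(np.nonzero(roi_mask)).T)
    d = surface_distance(pts, critical)
    keep = d >= margin_mm + electrode.radius_mm
    if not keep.any():
        warnings.warn("no target candidate satisfies the safety margin")
    return pts[keep]


def sample_entry_candidates(
    skull: SurfaceMesh, spacing_mm: float = 5.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Approximately uniform skull-surface samples with outward unit normals.

    The sample count is area / spacing^2; points are drawn area-weighted
    over faces, normals taken from the sampled face and oriented away from
    the mesh centroid.
    """
    if skull.is_empty:
        raise ValueError("empty skull mesh")
    tm = _trimesh.Trimesh(
        vertices=skull.vertices, faces=skull.faces, process=False
    )
    count = max(1, int(round(tm.area / spacing_mm**2)))
    pts, face_idx = _trimesh.sample.sample_surface(tm, count, seed=seed)
    normals = np.asarray(tm.face_normals[face_idx], dtype=float)
    centroid = skull.vertices.mean(axis=0)
    flip = np.einsum("ij,ij->i", normals, pts - centroid) < 0
    normals[flip] *= -1
    return np.asarray(pts, dtype=float), normals


@dataclass
class CandidatePairs:
    """Entry/target pair set for one electrode, as index arrays."""

    entries: np.ndarray        # (n_e, 3)
    normals: np.ndarray        # (n_e, 3)
    targets: np.ndarray        # (n_t, 3)
    entry_idx: np.ndarray      # (n_pairs,)
    target_idx: np.ndarray     # (n_pairs,)

    @classmethod
    def all_pairs(cls, entries, normals, targets) -> "CandidatePairs":
        n_e, n_t = len(entries), len(targets)
        ei, ti = np.meshgrid(np.arange(n_e), np.arange(n_t), indexing="ij")
        return cls(entries, normals, targets, ei.ravel(), ti.ravel())

    @property
    def n_pairs(self) -> int:
        return len(self.entry_idx)


def filter_candidates(
    pairs: CandidatePairs,
    constraints: PlanConstraints,
    critical: list[SurfaceMesh],
    electrode: ElectrodeSpec | None = None,
    entry_roi_mask: np.ndarray | None = None,
    grid: Grid | None = None,
    n_nodes: int = 128,
    queries: list[MeshDistanceQuery] | None = None,
) -> np.ndarray:
    """Boolean survivor mask over the candidate pairs.

    Survivors satisfy: length <= max, drilling angle to the inward skull
    normal <= max, entry inside the entry ROI (when given), and no
    traversal of a critical structure with the electrode modelled as a
    cylinder of its diameter (clearance checked at every node).
    """
    electrode = electrode or ElectrodeSpec()
    e = pairs.entries[pairs.entry_idx]
    nrm = pairs.normals[pairs.entry_idx]
    t = pairs.targets[pairs.target_idx]

    vec = t - e
    length = np.linalg.norm(vec, axis=1)
    ok = length <= constraints.max_length_mm
    ok &= length > 1e-9

    direction = vec / np.maximum(length, 1e-12)[:, None]
    inward = -nrm / np.maximum(np.linalg.norm(nrm, axis=1), 1e-12)[:, None]
    cosang = np.clip(np.einsum("ij,ij->i", direction, inward), -1.0, 1.0)
    ok &= np.degrees(np.arccos(cosang)) <= constraints.max_angle_to_normal_deg

    if entry_roi_mask is not None:
        if grid is None:
            raise ValueError("entry ROI filtering requires the grid")
        ok &= grid.contains_points(entry_roi_mask, e)

    # collision: cylinder clearance at the sampled nodes
    if queries is None:
        queries = [MeshDistanceQuery(m) for m in critical if not m.is_empty]
    idx = np.flatnonzero(ok)
    if len(idx) and queries:
        frac = np.linspace(0.0, 1.0, n_nodes)
        for i in idx:
            nodes = e[i][None, :] * (1 - frac[:, None]) + t[i][None, :] * frac[:, None]
            d = np.full(n_nodes, np.inf)
            for q in queries:
                d = np.minimum(d, q.distances(nodes))
            if np.min(d) <= electrode.radius_mm:
                ok[i] = False
    return ok


# ---------------------------------------------------------------------------
# Per-plan optimisation
# ---------------------------------------------------------------------------

def candidate_cost(
    m: TrajectoryMetrics, constraints: PlanConstraints, weights: CostWeights
) -> float:
    return (
        weights.w_rs * m.rs
        - weights.w_gm * m.gm_ratio
        + weights.w_len * m.length / constraints.max_length_mm
    )


def _pairwise_ok(a: Trajectory, b: Trajectory, min_mm: float) -> bool:
    return (
        segment_segment_distance(a.entry, a.target, b.entry, b.target) >= min_mm
    )


def optimize_plan(
    per_electrode_candidates: dict[str, list[tuple[Trajectory, TrajectoryMetrics]]],
    constraints: PlanConstraints | None = None,
    weights: CostWeights | None = None,
    critical_model_id: str = "",
    exhaustive_limit: int = 4096,
) -> Plan:
    """Pick one candidate per electrode subject to pairwise spacing.

    Small instances (candidate-combination count <= ``exhaustive_limit``)
    are solved exactly by enumeration of feasible combinations, minimising
    total cost; larger instances use greedy assignment in ascending order
    of candidate count with depth-first backtracking.  Ties break toward
    the earlier candidate, so results are deterministic for a fixed input
    order.  Raises naming the first unsatisfiable electrode.
    """
    constraints = constraints or PlanConstraints()
    weights = weights or CostWeights()
    names = list(per_electrode_candidates.keys())
    for name in names:
        cands = [
            (t, m) for (t, m) in per_electrode_candidates[name] if not m.collision
        ]
        if not cands:
            raise ValueError(f"electrode {name!r} has no feasible candidate")
        per_electrode_candidates = {**per_electrode_candidates, name: cands}

    counts = [len(per_electrode_candidates[n]) for n in names]
    total = int(np.prod([float(c) for c in counts]))

    costs = {
        n: [candidate_cost(m, constraints, weights)
            for (_, m) in per_electrode_candidates[n]]
        for n in names
    }

    # pairwise compatibility matrices, computed once (vectorised)
    from .mesh import segment_segment_distance_matrix

    ends = {
        n: (
            np.array([t.entry for t, _ in per_electrode_candidates[n]]),
            np.array([t.target for t, _ in per_electrode_candidates[n]]),
        )
        for n in names
    }
    compat: dict[tuple[str, str], np.ndarray] = {}
    for na, nb in itertools.combinations(names, 2):
        d = segment_segment_distance_matrix(
            ends[na][0], ends[na][1], ends[nb][0], ends[nb][1]
        )
        compat[(na, nb)] = d >= constraints.min_pairwise_mm
        compat[(nb, na)] = compat[(na, nb)].T

    if 0 < total <= exhaustive_limit:
        best_combo, best_cost = None, np.inf
        for combo in itertools.product(*(range(c) for c in counts)):
            feasible = all(
                compat[(na, nb)][ia, ib]
                for (na, ia), (nb, ib) in itertools.combinations(
                    zip(names, combo), 2
                )
            )
            if not feasible:
                continue
            c = sum(costs[n][i] for n, i in zip(names, combo))
            if c < best_cost - 1e-12:
                best_combo, best_cost = combo, c
        if best_combo is None:
            raise ValueError(
                f"no pairwise-compatible combination exists "
                f"(first unsatisfiable electrode: {names[0]!r})"
            )
        chosen = {n: i for n, i in zip(names, best_combo)}
    else:
        order = sorted(names, key=lambda n: (len(per_electrode_candidates[n]), n))
        chosen = _greedy_backtrack(order, costs, compat)

    electrodes = [
        (n, per_electrode_candidates[n][chosen[n]][0],
         per_electrode_candidates[n][chosen[n]][1])
        for n in names
    ]
    return Plan(electrodes=electrodes, critical_model_id=critical_model_id)


def _greedy_backtrack(
    order: list[str],
    costs: dict[str, list[float]],
    compat: dict[tuple[str, str], np.ndarray],
    budget: int = 500_000,
) -> dict[str, int]:
    """Greedy depth-first assignment with forward checking.

    At each level the most-constrained unassigned electrode is expanded,
    candidates in ascending cost; choosing a candidate prunes the
    remaining electrodes' candidate masks through the precomputed
    compatibility bits, so dead branches are cut early.  A step budget
    guards against pathological instances; exhaustion or a complete
    failed search raises, naming the blocking electrode.
    """
    cost_arr = {n: np.asarray(costs[n]) for n in order}
    assignment: dict[str, int] = {}
    steps = 0
    blocker = order[0]

    def rec(masks: dict[str, np.ndarray]) -> bool:
        nonlocal steps, blocker
        if not masks:
            return True
        name = min(masks, key=lambda n: (int(masks[n].sum()), n))
        avail = np.flatnonzero(masks[name])
        if len(avail) == 0:
            blocker = name
            return False
        for i in avail[np.argsort(cost_arr[name][avail], kind="stable")]:
            steps += 1
            if steps > budget:
                blocker = name
                return False
            new_masks = {}
            dead = False
            for other, m in masks.items():
                if other == name:
                    continue
                nm = m & compat[(other, name)][:, i]
                if not nm.any():
                    dead = True
                    blocker = other
                    break
                new_masks[other] = nm
            if dead:
                continue
            assignment[name] = int(i)
            if rec(new_masks):
                return True
            del assignment[name]
        return False

    init = {n: np.ones(len(costs[n]), dtype=bool) for n in order}
    if not rec(init):
        raise ValueError(
            f"no pairwise-compatible combination found "
            f"(first unsatisfiable electrode: {blocker!r})"
        )
    return assignment


# ---------------------------------------------------------------------------
# End-to-end planning for one critical-structure model
# ---------------------------------------------------------------------------

@dataclass
class PlannerSettings:
    """Desk-scale caps on the candidate sets fed to the optimiser.

    The raw entry x target product runs well past 10^5 pairs; after the
    cheap geometric filters a seeded subsample of at most
    ``max_pairs_per_electrode`` pairs gets the expensive collision and
    metric evaluation.
    """

    entry_spacing_mm: float = 5.0
    max_targets_per_roi: int = 12
    max_pairs_per_electrode: int = 30
    n_nodes: int = 128


@dataclass
class PlanningResult:
    plan: Plan
    n_raw_pairs: int            # before any filtering (candidate explosion)
    n_filtered_pairs: int       # survivors of the hard constraints


def plan_implantation(
    skull_mesh: SurfaceMesh,
    target_rois: np.ndarray,
    gm_mask: np.ndarray,
    grid: Grid,
    critical: list[SurfaceMesh],
    seed: int = 0,
    electrode: ElectrodeSpec | None = None,
    constraints: PlanConstraints | None = None,
    risk_cfg: RiskConfig | None = None,
    weights: CostWeights | None = None,
    settings: PlannerSettings | None = None,
    roi_labels: list[int] | None = None,
    critical_model_id: str = "",
) -> PlanningResult:
    """Plan one electrode per target ROI against a critical-structure model."""
    electrode = electrode or ElectrodeSpec()
    constraints = constraints or PlanConstraints()
    risk_cfg = risk_cfg or RiskConfig()
    weights = weights or CostWeights()
    settings = settings or PlannerSettings()
    rng = np.random.default_rng(seed)

    queries = [MeshDistanceQuery(m) for m in critical if not m.is_empty]
    entries, normals = sample_entry_candidates(
        skull_mesh, settings.entry_spacing_mm, seed=seed
    )

    labels = roi_labels
    if labels is None:
        labs = np.unique(np.asarray(target_rois))
        labels = [int(l) for l in labs if l > 0]

    per_electrode: dict[str, list[tuple[Trajectory, TrajectoryMetrics]]] = {}
    n_raw = 0
    n_filtered = 0
    for lab in labels:
        name = f"E{lab}"
        roi_mask = np.asarray(target_rois) == lab
        targets = sample_target_candidates(
            roi_mask, grid, critical, constraints.min_target_margin_mm, electrode
        )
        n_raw += len(entries) * int(roi_mask.sum())
        if len(targets) == 0:
            raise ValueError(f"electrode {name!r} has no feasible candidate")
        if len(targets) > settings.max_targets_per_roi:
            pick = rng.choice(len(targets), settings.max_targets_per_roi, replace=False)
            targets = targets[np.sort(pick)]

        pairs = CandidatePairs.all_pairs(entries, normals, targets)
        # cheap geometric prefilter before subsampling
        e = pairs.entries[pairs.entry_idx]
        nrm = pairs.normals[pairs.entry_idx]
        t = pairs.targets[pairs.target_idx]
        vec = t - e
        length = np.linalg.norm(vec, axis=1)
        pre = (length <= constraints.max_length_mm) & (length > 1e-9)
        direction = vec / np.maximum(length, 1e-12)[:, None]
        inward = -nrm / np.maximum(np.linalg.norm(nrm, axis=1), 1e-12)[:, None]
        cosang = np.clip(np.einsum("ij,ij->i", direction, inward), -1.0, 1.0)
        pre &= np.degrees(np.arccos(cosang)) <= constraints.max_angle_to_normal_deg
        prefiltered = np.flatnonzero(pre)
        # seeded subsample with escalation: if every sampled pair collides,
        # widen the sample before declaring the electrode infeasible
        cands: list[tuple[Trajectory, TrajectoryMetrics]] = []
        tried = np.zeros(len(prefiltered), dtype=bool)
        cap = settings.max_pairs_per_electrode
        while True:
            untried = np.flatnonzero(~tried)
            if len(untried) == 0:
                break
            take = untried
            if len(take) > cap:
                take = take[np.sort(rng.choice(len(take), cap, replace=False))]
            tried[take] = True
            keep = prefiltered[take]
            ent = e[keep]
            tgt = t[keep]
            nrm_k = nrm[keep]
            # batched node distances for all sampled pairs at once
            frac = np.linspace(0.0, 1.0, risk_cfg.n_nodes)
            nodes = (
                ent[:, None, :] * (1 - frac)[None, :, None]
                + tgt[:, None, :] * frac[None, :, None]
            ).reshape(-1, 3)
            d = np.full(len(nodes), np.inf)
            for q in queries:
                d = np.minimum(d, q.distances(nodes))
            D = np.maximum(
                d.reshape(len(keep), risk_cfg.n_nodes) - electrode.radius_mm, 0.0
            )
            collide = D.min(axis=1) <= 0.0
            n_filtered += int((~collide).sum())
            rs_all = _risk_scores_batch(D, risk_cfg)
            for i in np.flatnonzero(~collide):
                traj = Trajectory(ent[i], tgt[i], electrode, risk_cfg.n_nodes)
                inward = -nrm_k[i] / max(np.linalg.norm(nrm_k[i]), 1e-12)
                ang = float(np.degrees(np.arccos(
                    np.clip(traj.direction @ inward, -1.0, 1.0)
                )))
                metrics = TrajectoryMetrics(
                    rs=float(rs_all[i]),
                    md=float(D[i].min()),
                    length=traj.length,
                    angle_deg=ang,
                    gm_ratio=gm_contact_ratio(traj, gm_mask, grid),
                    collision=False,
                )
                cands.append((traj, metrics))
            if cands:
                break
            cap *= 4
        if not cands:
            raise ValueError(f"electrode {name!r} has no feasible candidate")
        per_electrode[name] = cands

    plan = optimize_plan(per_electrode, constraints, weights, critical_model_id)
    return PlanningResult(plan=plan, n_raw_pairs=n_raw, n_filtered_pairs=n_filtered)


# ---------------------------------------------------------------------------
# Independent plan checker (used by validity tests, not by the optimiser)
# ---------------------------------------------------------------------------

def check_plan(
    plan: Plan,
    critical: list[SurfaceMesh],
    constraints: PlanConstraints | None = None,
) -> list[str]:
    """Re-validate a plan from scratch; returns a list of violations.

    Checks pairwise spacing (exact segment-segment distances), collisions
    (segment/triangle intersection plus cylinder clearance by brute-force
    surface distance) and the target safety margin.  Empty list = valid.
    """
    constraints = constraints or PlanConstraints()
    problems: list[str] = []
    for (na, ta, _), (nb, tb, _) in itertools.combinations(plan.electrodes, 2):
        d = segment_segment_distance(ta.entry, ta.target, tb.entry, tb.target)
        if d < constraints.min_pairwise_mm - 1e-9:
            problems.append(f"pairwise {na}/{nb}: {d:.2f} mm < minimum")
    for name, t, m in plan.electrodes:
        r = t.electrode.radius_mm
        for mesh in critical:
            if mesh.is_empty:
                continue
            if segment_intersects_mesh(t.entry, t.target, mesh):
                problems.append(f"{name}: trajectory crosses a critical surface")
                break
        d = surface_distance(t.nodes, critical)
        if np.min(d) <= r:
            problems.append(f"{name}: cylinder clearance violated")
        dt = surface_distance(t.target[None, :], critical)[0]
        if dt < constraints.min_target_margin_mm + r - 1e-9:
            problems.append(f"{name}: target margin {dt:.2f} mm too small")
        if t.length > constraints.max_length_mm + 1e-9:
            problems.append(f"{name}: length {t.length:.1f} mm exceeds maximum")
        if m.collision:
            problems.append(f"{name}: collision flag set")
    return problems
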