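"""Study configuration: one object that pins every tunable of the pipeline.

The defaults reproduce the canonical synthetic study: a 10-phantom cohort
on 96^3 mm grids, three modality fidelities (all vessels / >= 2 mm /
>= 4 mm), eight electrodes per phantom, diameter sweep thresholds
1-4 mm and Bonferroni n = 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .phantom import PhantomConfig, BranchParams, ModalityProfile
from .planner import (
    ElectrodeSpec,
    PlanConstraints,
    RiskConfig,
    CostWeights,
    PlannerSettings,
)
from .vesselness import VesselnessParams


@dataclass
class StudyConfig:
    n_phantoms: int = 10
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    electrode: ElectrodeSpec = field(default_factory=ElectrodeSpec)
    constraints: PlanConstraints = field(default_factory=PlanConstraints)
    risk: RiskConfig = field(default_factory=RiskConfig)
    weights: CostWeights = field(default_factory=CostWeights)
    planner: PlannerSettings = field(default_factory=PlannerSettings)
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    prune_thresholds_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    model_source: str = "imaging"   # "imaging" (full chain) or "analytic"
    use_sulci: bool = False
    sulcal_erosion_mm: float = 5.0
    alpha_family: float = 0.05
    n_comparisons: int = 3
    min_component_vertices: int = 30

    def validate(self) -> None:
        if self.model_source not in ("imaging", "analytic"):
            raise ValueError("model_source must be 'imaging' or 'analytic'")
        if self.n_phantoms < 1:
            raise ValueError("n_phantoms must be >= 1")
        self.phantom.validate()

    # -- serialisation (YAML round-trip for reproducible reports) -------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["phantom"]["grid"] = {
            "shape": list(self.phantom.grid.shape),
            "spacing": list(self.phantom.grid.spacing),
            "origin": list(self.phantom.grid.origin),
        }
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        from .grids import Grid

        d = dict(d)
        ph = dict(d.pop("phantom", {}))
        if "grid" in ph:
            g = ph["grid"]
            ph["grid"] = Grid(
                tuple(g["shape"]), tuple(g["spacing"]), tuple(g["origin"])
            )
        if "branch" in ph:
            ph["branch"] = BranchParams(**ph["branch"])
        if "profiles" in ph:
            ph["profiles"] = tuple(
                p if isinstance(p, ModalityProfile) else ModalityProfile(**p)
                for p in ph["profiles"]
            )
        out = cls(
            phantom=PhantomConfig(**ph),
            electrode=ElectrodeSpec(**d.pop("electrode", {})),
            constraints=PlanConstraints(**d.pop("constraints", {})),
            risk=RiskConfig(**d.pop("risk", {})),
            weights=CostWeights(**d.pop("weights", {})),
            planner=PlannerSettings(**d.pop("planner", {})),
            vesselness=VesselnessParams(
                **{
                    k: tuple(v) if k == "scales" else v
                    for k, v in d.pop("vesselness", {}).items()
                }
            ),
            **{
                k: tuple(v) if k == "prune_thresholds_mm" else v
                for k, v in d.items()
            },
        )
        return out

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(text))
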