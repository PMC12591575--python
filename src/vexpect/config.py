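"""Generator configuration: group sizes, effect parameters, variance components.

The bundled per-experiment defaults encode the study conditions the synthetic
data emulate: two groups (neurotypical NT and cerebellar-ataxia CA), additive
group / expectancy / complexity effects with participant random intercepts
for the two verification tasks, and an equal-variance signal-detection model
(per group-by-similarity d' and criterion) for the grammar-judgment task.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import yaml

__all__ = ["GeneratorConfig", "default_config"]


@dataclass
class GeneratorConfig:
    """Parameters of the trial-level data-generating process.

    RT effects are in milliseconds and additive on the cell-mean scale;
    ``family`` chooses the residual distribution ("lognormal" draws are
    mean/sd-matched on the ms scale, "normal" gives closed-form recovery).
    ``dprime``/``criterion`` hold the grammar-judgment truths per
    group x similarity cell.
    """

    experiment: int = 1
    n_per_group: int = 15
    groups: tuple[str, str] = ("NT", "CA")
    baseline_ms: float = 2000.0
    group_offset_ms: float = 304.0
    expectancy_ms: dict = field(default_factory=lambda: {"NT": 238.0, "CA": 398.0})
    complexity_ms: dict = field(default_factory=lambda: {"NT": 831.0, "CA": 910.0})
    intercept_sd_ms: float = 350.0
    residual_sd_ms: float = 300.0
    family: str = "lognormal"
    deadline_ms: float | None = 5000.0
    accuracy: dict = field(default_factory=lambda: {"NT": 0.91, "CA": 0.88})
    dprime: dict = field(default_factory=dict)
    criterion: dict = field(default_factory=dict)
    agl_rt_mean_ms: dict = field(default_factory=lambda: {"NT": 2568.0, "CA": 2815.0})
    agl_rt_sd_ms: float = 700.0
    lapse_rate: float = 0.0
    probe_fail_prob: float = 0.0
    exclusion_rules: tuple[str, ...] = ("below-chance", "probe-failure")
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.intercept_sd_ms <= 0 or self.residual_sd_ms <= 0:
            raise ValueError("variance components must be positive")
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"unknown RT family {self.family!r}")
        for p in self.accuracy.values():
            if not 0.0 < p < 1.0:
                raise ValueError("accuracy probabilities must lie in (0, 1)")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse rate must lie in [0, 1)")
        for g, d in self.dprime.items():
            for v in d.values():
                if not abs(v) < 20:
                    raise ValueError(f"d' for {g} not finite/sane: {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = list(self.groups)
        d["exclusion_rules"] = list(self.exclusion_rules)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        raw = dict(raw)
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        if "exclusion_rules" in raw:
            raw["exclusion_rules"] = tuple(raw["exclusion_rules"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(experiment: int) -> GeneratorConfig:
    """Load the bundled default generator configuration for one experiment."""
    ref = resources.files("vexpect.data").joinpath(f"experiment{experiment}.yaml")
    return GeneratorConfig.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))
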