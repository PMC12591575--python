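"""Reproducible pipeline: generate -> simulate -> exclude -> score -> fit -> report.

A single master seed spawns one child seed per stage (numpy SeedSequence;
the spawn index of every stage is recorded in the manifest), so each stage
is individually reproducible.  The run directory is never silently
overwritten, and the manifest lists versions, seeds, trial counts, and a
SHA-256 checksum of every file the run wrote.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GeneratorConfig, default_config
from .grammar import default_grammar, load_grammar
from .inference import effect_score, fit_lme
from .io import write_sdt, write_stimuli, write_trials
from .sdt import score_sdt
from .simulate import apply_exclusions, simulate_agl_experiment, simulate_rt_experiment
from .stimuli import assemble_agl_session, gen_subtraction_set, gen_transform_set, make_rt_session

__all__ = ["RunConfig", "run_pipeline"]

ALL_STAGES = ("stimuli", "simulate", "exclude", "score", "fit", "report")


@dataclass
class RunConfig:
    experiment: int
    seed: int
    out_dir: Path
    grammar_path: Path | None = None
    config_path: Path | None = None
    stages: tuple[str, ...] = ALL_STAGES
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.experiment not in (1, 2, 3):
            raise ValueError("experiment must be 1, 2, or 3")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages and return the run directory."""
    out = cfg.out_dir
    if out.exists() and any(out.iterdir()):
        raise FileExistsError(f"output directory {out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("vexpect.pipeline")
    log.setLevel(cfg.log_level)
    log.handlers.clear()
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out / "run.log"),
    ):
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)

    gen_cfg = (
        GeneratorConfig.from_yaml(cfg.config_path)
        if cfg.config_path
        else default_config(cfg.experiment)
    )
    grammar = load_grammar(cfg.grammar_path) if cfg.grammar_path else default_grammar()

    children = np.random.SeedSequence(cfg.seed).spawn(len(ALL_STAGES))
    stage_rng = {name: np.random.default_rng(children[i]) for i, name in enumerate(ALL_STAGES)}

    manifest: dict = {
        "package_version": __version__,
        "experiment": cfg.experiment,
        "seed": cfg.seed,
        "stage_spawn_index": {name: i for i, name in enumerate(ALL_STAGES)},
        "stages_run": list(cfg.stages),
        "generator_config": gen_cfg.to_dict(),
        "counts": {},
        "checksums": {},
    }

    session = None
    records = kept = exclusions = None

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if "stimuli" in cfg.stages:
        log.info("stage stimuli: experiment %d", cfg.experiment)
        try:
            rng = stage_rng["stimuli"]
            if cfg.experiment == 1:
                problems = gen_subtraction_set(rng=rng)
                session = make_rt_session(problems, 1, rng)
                write_stimuli(problems, out / "stimuli.csv")
            elif cfg.experiment == 2:
                problems = gen_transform_set(rng=rng)
                session = make_rt_session(problems, 2, rng)
                write_stimuli(problems, out / "stimuli.csv")
            else:
                session = assemble_agl_session(grammar, rng=rng)
                tr = session.trials
                manifest["counts"]["training_trials"] = int((tr["phase"] == "training").sum())
                manifest["counts"]["test_trials"] = int((tr["phase"] == "test").sum())
            session.trials.to_csv(out / "session.csv", index=False)
            manifest["counts"]["session_trials"] = int(session.n_trials)
        except Exception as exc:
            fail("stimuli", exc)

    if "simulate" in cfg.stages:
        if session is None:
            raise RuntimeError("stage 'simulate' needs stage 'stimuli'")
        log.info("stage simulate: %d per group", gen_cfg.n_per_group)
        try:
            rng = stage_rng["simulate"]
            sim = simulate_agl_experiment if cfg.experiment == 3 else simulate_rt_experiment
            records = sim(gen_cfg, session, rng)
            write_trials(records, out / "trials.csv")
            manifest["counts"]["trials"] = int(len(records))
        except Exception as exc:
            fail("simulate", exc)

    if "exclude" in cfg.stages and records is not None:
        try:
            kept, exclusions = apply_exclusions(records, rules=gen_cfg.exclusion_rules)
            write_trials(kept, out / "trials_kept.csv")
            exclusions.to_csv(out / "exclusions.csv", index=False)
            manifest["counts"]["excluded_participants"] = int(len(exclusions))
            log.info("stage exclude: %d participants removed", len(exclusions))
        except Exception as exc:
            fail("exclude", exc)

    data = kept if kept is not None else records
    scores = None
    if "score" in cfg.stages and data is not None:
        try:
            if cfg.experiment == 3:
                scores = score_sdt(data)
                write_sdt(scores, out / "sdt.csv")
            else:
                rows = []
                for pid in sorted(data["participant"].unique()):
                    grp = data.loc[data["participant"] == pid, "group"].iloc[0]
                    rows.append(
                        {
                            "participant": pid,
                            "group": grp,
                            "expectancy_effect_ms": effect_score(data, pid, "expectancy"),
                            "complexity_effect_ms": effect_score(data, pid, "complexity"),
                        }
                    )
                scores = pd.DataFrame(rows)
                scores.to_csv(out / "scores.csv", index=False)
            log.info("stage score: %d rows", len(scores))
        except Exception as exc:
            fail("score", exc)

    estimates = None
    if "fit" in cfg.stages and data is not None:
        try:
            if cfg.experiment == 3:
                sdt_table = scores if scores is not None else score_sdt(data)
                estimates = fit_lme(sdt_table, ["group", "similarity"], outcome="dprime")
            else:
                estimates = fit_lme(data, ["group", "expectancy", "complexity"], outcome="rt")
            estimates.to_csv(out / "estimates.csv", index=False)
            log.info("stage fit: %d terms", len(estimates))
        except Exception as exc:
            fail("fit", exc)

    if "report" in cfg.stages:
        lines = [
            f"vexpect run (experiment {cfg.experiment}, seed {cfg.seed})",
            "",
        ]
        for key, val in manifest["counts"].items():
            lines.append(f"{key}: {val}")
        if estimates is not None:
            lines.append("")
            lines.append("estimates:")
            for _, r in estimates.iterrows():
                lines.append(
                    f"  {r['term']:>24s}  est={r['estimate']:10.3f}  "
                    f"se={r['se']:8.3f}  p={r['p']:.4g}"
                )
        (out / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    for f in sorted(out.iterdir()):
        if f.name not in ("manifest.json", "run.log"):
            manifest["checksums"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    log.info("run complete: %s", out)
    return out
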