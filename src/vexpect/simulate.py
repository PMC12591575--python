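"""Synthetic trial-level behavioral data with the statistical structure the analyses assume.

Verification tasks (Experiments 1-2): latent RT per trial is
baseline + group offset + per-group expectancy and complexity effects
+ participant random intercept + residual noise (lognormal by default,
mean/sd matched on the ms scale; plain normal available for closed-form
recovery checks), right-censored at the task deadline (censored trials are
non-responses).  Correctness is Bernoulli per group, independent of RT.

Grammar-judgment task (Experiment 3): equal-variance signal detection.
P(respond "grammatical") is Phi(d'/2 - c) for grammatical strings and
Phi(-d'/2 - c) for nongrammatical strings, with d' and c read from the
participant's group x similarity cell; lapse trials respond uniformly.

Exclusion rules mirror the study: whole participants are dropped for
below-chance (<50%) overall accuracy or any failed attention probe.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneratorConfig
from .stimuli import SessionPlan

__all__ = [
    "simulate_rt_experiment",
    "simulate_agl_experiment",
    "apply_exclusions",
    "TRIAL_COLUMNS",
]

# Tidy trial CSV dialect (header mandatory; missing RT written empty).
TRIAL_COLUMNS = [
    "participant",
    "group",
    "experiment",
    "expectancy",
    "complexity",
    "similarity",
    "grammatical",
    "rt_ms",
    "response",
    "correct",
    "probe",
    "excluded_reason",
]


def _participants(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for g in config.groups:
        for i in range(config.n_per_group):
            rows.append({"participant": f"{g}{i + 1:02d}", "group": g})
    return pd.DataFrame(rows)


def _draw_rt(mean: np.ndarray, sd: float, family: str, rng: np.random.Generator) -> np.ndarray:
    if family == "normal":
        rt = rng.normal(mean, sd)
    else:  # lognormal matched to the requested mean and sd on the ms scale
        mean = np.maximum(mean, 1.0)
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2
        rt = np.exp(rng.normal(mu, np.sqrt(sigma2)))
    return np.maximum(rt, 1.0)


def _probe_rows(config: GeneratorConfig, parts: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for _, p in parts.iterrows():
        passed = rng.random(3) >= config.probe_fail_prob
        for ok in passed:
            rows.append(
                {
                    "participant": p.participant,
                    "group": p.group,
                    "experiment": config.experiment,
                    "rt_ms": np.nan,
                    "response": "",
                    "correct": bool(ok),
                    "probe": True,
                }
            )
    return pd.DataFrame(rows)


def simulate_rt_experiment(
    config: GeneratorConfig, session: SessionPlan, rng=None
) -> pd.DataFrame:
    """Simulate one verification-task dataset (one row per trial, plus probe rows)."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    parts = _participants(config)
    trials = session.trials
    n_p, n_t = len(parts), len(trials)

    intercepts = rng.normal(0.0, config.intercept_sd_ms, size=n_p)
    is_ca = (parts["group"] == config.groups[1]).to_numpy()
    unexp = (trials["expectancy"] == "unexpected").to_numpy()
    high = (trials["complexity"] == "high").to_numpy()

    exp_eff = np.where(
        is_ca[:, None],
        config.expectancy_ms[config.groups[1]],
        config.expectancy_ms[config.groups[0]],
    )
    cpx_eff = np.where(
        is_ca[:, None],
        config.complexity_ms[config.groups[1]],
        config.complexity_ms[config.groups[0]],
    )
    mean = (
        config.baseline_ms
        + config.group_offset_ms * is_ca[:, None]
        + exp_eff * unexp[None, :]
        + cpx_eff * high[None, :]
        + intercepts[:, None]
    )
    rt = _draw_rt(mean, config.residual_sd_ms, config.family, rng)

    acc = np.where(
        is_ca, config.accuracy[config.groups[1]], config.accuracy[config.groups[0]]
    )
    correct = rng.random((n_p, n_t)) < acc[:, None]
    if config.lapse_rate > 0:
        lapse = rng.random((n_p, n_t)) < config.lapse_rate
        correct = np.where(lapse, rng.random((n_p, n_t)) < 0.5, correct)

    deadline = config.deadline_ms
    censored = np.zeros_like(correct) if deadline is None else rt >= deadline

    correct_key = trials["correct_response"].to_numpy()
    other_key = np.where(correct_key == "Z", "M", "Z")
    response = np.where(correct, correct_key[None, :], other_key[None, :])

    df = pd.DataFrame(
        {
            "participant": np.repeat(parts["participant"].to_numpy(), n_t),
            "group": np.repeat(parts["group"].to_numpy(), n_t),
            "experiment": config.experiment,
            "expectancy": np.tile(trials["expectancy"].to_numpy(), n_p),
            "complexity": np.tile(trials["complexity"].to_numpy(), n_p),
            "similarity": "",
            "grammatical": "",
            "rt_ms": rt.ravel(),
            "response": response.ravel(),
            "correct": correct.ravel(),
            "probe": False,
            "excluded_reason": "",
        }
    )
    cen = censored.ravel()
    df.loc[cen, ["rt_ms", "response"]] = (np.nan, "")
    df.loc[cen, "correct"] = False

    out = pd.concat([df, _probe_rows(config, parts, rng)], ignore_index=True)
    return out.reindex(columns=TRIAL_COLUMNS).fillna({"excluded_reason": ""})


def simulate_agl_experiment(
    config: GeneratorConfig, session: SessionPlan, rng=None
) -> pd.DataFrame:
    """Simulate grammar-judgment test-phase responses from the SDT model."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    parts = _participants(config)
    tests = session.trials[session.trials["phase"] == "test"].reset_index(drop=True)
    n_p, n_t = len(parts), len(tests)

    gram = tests["grammatical"].to_numpy(dtype=bool)
    sim = np.where(
        tests["cell"].str.endswith("high").to_numpy(), "high", "low"
    )
    is_ca = (parts["group"] == config.groups[1]).to_numpy()

    d = np.empty((n_p, n_t))
    c = np.empty((n_p, n_t))
    for gi, g in enumerate(config.groups):
        mask_p = is_ca == (gi == 1)
        for s in ("high", "low"):
            mask_t = sim == s
            d[np.ix_(mask_p, mask_t)] = config.dprime[g][s]
            c[np.ix_(mask_p, mask_t)] = config.criterion[g][s]

    p_gram = stats.norm.cdf(np.where(gram[None, :], d / 2 - c, -d / 2 - c))
    say_gram = rng.random((n_p, n_t)) < p_gram
    if config.lapse_rate > 0:
        lapse = rng.random((n_p, n_t)) < config.lapse_rate
        say_gram = np.where(lapse, rng.random((n_p, n_t)) < 0.5, say_gram)
    correct = say_gram == gram[None, :]

    rt_mean = np.where(
        is_ca,
        config.agl_rt_mean_ms[config.groups[1]],
        config.agl_rt_mean_ms[config.groups[0]],
    )
    rt = _draw_rt(
        np.broadcast_to(rt_mean[:, None], (n_p, n_t)).copy(),
        config.agl_rt_sd_ms,
        config.family,
        rng,
    )

    df = pd.DataFrame(
        {
            "participant": np.repeat(parts["participant"].to_numpy(), n_t),
            "group": np.repeat(parts["group"].to_numpy(), n_t),
            "experiment": 3,
            "expectancy": np.tile(
                np.where(gram, "expected", "unexpected"), n_p
            ),
            "complexity": "",
            "similarity": np.tile(sim, n_p),
            "grammatical": np.tile(gram, n_p),
            "rt_ms": rt.ravel(),
            "response": np.where(
                say_gram.ravel(), "grammatical", "nongrammatical"
            ),
            "correct": correct.ravel(),
            "probe": False,
            "excluded_reason": "",
        }
    )
    out = pd.concat([df, _probe_rows(config, parts, rng)], ignore_index=True)
    return out.reindex(columns=TRIAL_COLUMNS).fillna({"excluded_reason": ""})


def apply_exclusions(
    records: pd.DataFrame,
    rules: tuple[str, ...] = ("below-chance", "probe-failure"),
    chance: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove whole participants who score below chance or fail any attention probe.

    Returns the kept records and an exclusion log (participant, rule, value).
    """
    log_rows = []
    excluded: set[str] = set()
    scored = records[~records["probe"]]
    if "below-chance" in rules:
        acc = scored.groupby("participant")["correct"].mean()
        for pid, a in acc.items():
            if a < chance:
                excluded.add(pid)
                log_rows.append(
                    {"participant": pid, "rule": "below-chance", "value": float(a)}
                )
    if "probe-failure" in rules:
        probes = records[records["probe"]]
        fails = probes.groupby("participant")["correct"].agg(lambda x: (~x).sum())
        for pid, nf in fails.items():
            if nf > 0 and pid not in excluded:
                excluded.add(pid)
                log_rows.append(
                    {"participant": pid, "rule": "probe-failure", "value": int(nf)}
                )
    kept = records[~records["participant"].isin(excluded)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["participant", "rule", "value"])
    return kept, log
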