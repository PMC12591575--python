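"""Group-level statistics: effect scores, linear mixed models, effect sizes, power.

The central model is a linear mixed-effects model with the full factorial
fixed-effect design and participant-level random intercepts, fitted by REML
(delegated to statsmodels MixedLM).  Factors are effect-coded at +/-1/2 so a
main-effect coefficient is the marginal level difference and a simple effect
within one group is a linear contrast of the fixed-effect vector; p-values
use the large-sample normal approximation (recorded in the result metadata).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "effect_score",
    "fit_lme",
    "cohens_d",
    "power_n_per_group",
    "EFFECT_CODES",
]

# Effect coding: the second level of each pair is the "higher" one, so a
# positive coefficient means slower/"larger" at unexpected, high complexity,
# CA group, or low similarity (the easier, more discriminable condition).
EFFECT_CODES = {
    "group": {"NT": -0.5, "CA": +0.5},
    "expectancy": {"expected": -0.5, "unexpected": +0.5},
    "complexity": {"low": -0.5, "high": +0.5},
    "similarity": {"high": -0.5, "low": +0.5},
}


def effect_score(records: pd.DataFrame, participant: str, factor: str) -> float:
    """Per-participant expectancy or complexity effect score in ms.

    Mean correct-trial RT at the higher factor level minus the lower level
    (unexpected - expected, or high - low complexity); probes and
    non-responses are excluded.
    """
    if factor not in ("expectancy", "complexity"):
        raise ValueError("factor must be 'expectancy' or 'complexity'")
    hi_level = "unexpected" if factor == "expectancy" else "high"
    lo_level = "expected" if factor == "expectancy" else "low"
    sub = records[
        (records["participant"] == participant)
        & (~records["probe"])
        & records["correct"].astype(bool)
        & records["rt_ms"].notna()
    ]
    hi = sub.loc[sub[factor] == hi_level, "rt_ms"]
    lo = sub.loc[sub[factor] == lo_level, "rt_ms"]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError(
            f"participant {participant!r} has no correct responses in some "
            f"{factor} level"
        )
    return float(hi.mean() - lo.mean())


def _design_matrix(df: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    coded = {}
    for f in factors:
        coded[f] = df[f].map(EFFECT_CODES[f]).to_numpy(dtype=float)
        cols.append(coded[f])
        names.append(f)
    # all interactions, in order of increasing order
    from itertools import combinations

    for k in range(2, len(factors) + 1):
        for combo in combinations(factors, k):
            cols.append(np.prod([coded[f] for f in combo], axis=0))
            names.append(":".join(combo))
    return np.column_stack(cols), names


def _simple_effect_contrasts(factors: list[str], names: list[str]) -> dict[str, np.ndarray]:
    """Contrasts for each within factor at each level of 'group'."""
    out: dict[str, np.ndarray] = {}
    if "group" not in factors:
        return out
    others = [f for f in factors if f != "group"]
    for f in others:
        for level, code in EFFECT_CODES["group"].items():
            c = np.zeros(len(names))
            c[names.index(f)] = 1.0
            c[names.index(_iname(names, "group", f))] = code
            out[f"{f}|{level}"] = c
    # group simple effects within each level of the first within factor
    if others:
        f = others[0]
        for level, code in EFFECT_CODES[f].items():
            c = np.zeros(len(names))
            c[names.index("group")] = 1.0
            c[names.index(_iname(names, "group", f))] = code
            out[f"group|{level}"] = c
    return out


def _iname(names: list[str], a: str, b: str) -> str:
    for cand in (f"{a}:{b}", f"{b}:{a}"):
        if cand in names:
            return cand
    raise KeyError(f"no interaction term for {a} x {b}")


def _fe_covariance_gls(fit, exog: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Model-based fixed-effect covariance at the REML variance estimates.

    For a random-intercept model, V_i = sigma^2 I + tau^2 11' per participant,
    so X' V^{-1} X accumulates in closed form; this stays well-defined even
    when the numerical Hessian of the profiled likelihood is ill-conditioned.
    """
    sigma2 = float(fit.scale)
    tau2 = float(np.asarray(fit.cov_re).ravel()[0])
    k = exog.shape[1]
    xtvx = np.zeros((k, k))
    for g in pd.unique(groups):
        xg = exog[groups == g]
        n_i = len(xg)
        shrink = tau2 / (sigma2 + n_i * tau2)
        colsum = xg.sum(axis=0)
        xtvx += (xg.T @ xg - shrink * np.outer(colsum, colsum)) / sigma2
    return np.linalg.inv(xtvx)


def fit_lme(
    records: pd.DataFrame,
    design: list[str] = ("group", "expectancy", "complexity"),
    outcome: str = "rt",
    covariates: list[str] = (),
) -> pd.DataFrame:
    """REML linear mixed model with participant random intercepts.

    ``outcome`` selects the analysis: "rt" fits correct-response RTs at the
    trial level; "accuracy" fits per-participant percent correct per cell;
    "dprime"/"criterion" fit a per-participant SDT table (from
    :func:`vexpect.sdt.score_sdt`).  Returns an estimate table with main
    effects, interactions, and simple-effect contrasts; ``.attrs`` records
    the outcome, convergence and p-value method.
    """
    design = list(design)
    if outcome == "rt":
        df = records[
            (~records["probe"])
            & records["correct"].astype(bool)
            & records["rt_ms"].notna()
        ].copy()
        endog = df["rt_ms"].to_numpy(dtype=float)
    elif outcome == "accuracy":
        scored = records[~records["probe"]]
        within = [f for f in design if f != "group"]
        grouped = scored.groupby(["participant", "group", *within], as_index=False)[
            "correct"
        ].mean()
        grouped["pct"] = 100.0 * grouped["correct"]
        df = grouped
        endog = df["pct"].to_numpy(dtype=float)
    elif outcome in ("dprime", "criterion"):
        df = records.copy()
        endog = df[outcome].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    if df["participant"].nunique() < 4:
        raise ValueError("mixed model needs >= 2 participants per group")

    exog, names = _design_matrix(df, design)
    for cov in covariates:
        x = df[cov].to_numpy(dtype=float)
        exog = np.column_stack([exog, x - x.mean()])
        names = names + [cov]

    groups_arr = df["participant"].to_numpy()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.MixedLM(endog, exog, groups=groups_arr)
        fit = None
        for method in ("bfgs", "powell"):
            try:
                cand = model.fit(reml=True, method=method)
            except Exception:
                continue
            if cand.converged and np.isfinite(cand.llf):
                fit = cand
                break
        if fit is None:
            raise RuntimeError("mixed model failed to converge")
        singular = any("singular" in str(w.message).lower() for w in caught)

    beta = fit.fe_params
    cov_fe = _fe_covariance_gls(fit, exog, groups_arr)
    singular = singular or float(np.asarray(fit.cov_re).ravel()[0]) <= 1e-10 * fit.scale

    rows = []
    for i, name in enumerate(names):
        est, se = float(beta[i]), float(np.sqrt(cov_fe[i, i]))
        z = est / se if se > 0 else np.nan
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": se,
                "p": float(2 * stats.norm.sf(abs(z))),
            }
        )
    for name, c in _simple_effect_contrasts(design, names).items():
        est = float(c @ beta[: len(names)])
        se = float(np.sqrt(c @ cov_fe @ c))
        z = est / se if se > 0 else np.nan
        rows.append(
            {
                "term": name,
                "estimate": est,
                "se": se,
                "p": float(2 * stats.norm.sf(abs(z))),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs.update(
        outcome=outcome,
        design=design,
        p_method="wald-normal (residual approximation)",
        reml=True,
        singular=singular,
        n_obs=int(len(endog)),
        n_participants=int(df["participant"].nunique()),
    )
    table["singular"] = singular
    return table


def cohens_d(a, b) -> float:
    """Two-sample Cohen's d: (mean(a) - mean(b)) / pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled SD: groups are degenerate")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def power_n_per_group(
    d: float,
    alpha: float = 0.05,
    power: float = 0.95,
    tails: int = 2,
    family: str = "t",
    n_max: int = 1_000_000,
) -> int:
    """Smallest per-group n for a two-sample test to reach the target power.

    Iterates over the noncentral-t distribution (``family="t"``) or the
    normal approximation (``family="z"``).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if d <= 0:
        raise ValueError("effect size must be positive")
    for n in range(2, n_max + 1):
        nc = d * np.sqrt(n / 2)
        if family == "t":
            df = 2 * n - 2
            tcrit = stats.t.ppf(1 - alpha / tails, df)
            pw = stats.nct.sf(tcrit, df, nc)
            if tails == 2:
                pw += stats.nct.cdf(-tcrit, df, nc)
        elif family == "z":
            zcrit = stats.norm.ppf(1 - alpha / tails)
            pw = stats.norm.sf(zcrit - nc)
            if tails == 2:
                pw += stats.norm.cdf(-zcrit - nc)
        else:
            raise ValueError(f"unknown family {family!r}")
        if pw >= power:
            return n
    raise RuntimeError("target power unreachable within the search range")
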