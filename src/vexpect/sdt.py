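"""Equal-variance signal-detection scoring of grammaticality judgments.

A *hit* is a "grammatical" response to a grammatical string; a *false alarm*
is a "grammatical" response to a nongrammatical string.  Sensitivity is
d' = z(H) - z(F) and response bias is c = -(z(H) + z(F))/2, with z the
standard-normal quantile.

Raw proportions of 0 or 1 make z infinite, so rates are corrected before the
transform.  The default is the log-linear rule (k + 0.5)/(N + 1) applied to
every cell, which besides keeping z finite substantially reduces the
finite-sample bias of d' at the per-condition trial counts used here; the
replacement rule (0 -> 1/(2N), 1 -> 1 - 1/(2N), other cells untouched) is
available via ``correction="replace"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MissingCellError",
    "hit_fa_rates",
    "dprime",
    "criterion",
    "percent_correct",
    "score_sdt",
]


class MissingCellError(ValueError):
    """A participant/condition cell has no trials of a required class."""


def _corrected_rate(k: int, n: int, correction: str) -> float:
    if correction == "loglinear":
        return (k + 0.5) / (n + 1)
    if correction == "replace":
        r = k / n
        if r == 0.0:
            return 1.0 / (2 * n)
        if r == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return r
    raise ValueError(f"unknown correction {correction!r}")


def hit_fa_rates(
    records: pd.DataFrame,
    participant: str,
    condition: str | None = None,
    correction: str = "loglinear",
) -> tuple[float, float, dict]:
    """Corrected hit and false-alarm rates for one participant (and similarity condition).

    Returns ``(hit_rate, fa_rate, counts)`` where counts holds the raw hits,
    false alarms, and per-class trial numbers.
    """
    sub = records[(records["participant"] == participant) & (~records["probe"])]
    if condition is not None:
        sub = sub[sub["similarity"] == condition]
    gram = sub[sub["grammatical"].astype(bool)]
    nong = sub[~sub["grammatical"].astype(bool)]
    if len(gram) == 0 or len(nong) == 0:
        raise MissingCellError(
            f"participant {participant!r}, condition {condition!r}: "
            f"{len(gram)} grammatical / {len(nong)} nongrammatical trials"
        )
    hits = int((gram["response"] == "grammatical").sum())
    fas = int((nong["response"] == "grammatical").sum())
    n_g, n_ng = len(gram), len(nong)
    counts = {"hits": hits, "fas": fas, "n_g": n_g, "n_ng": n_ng}
    return (
        _corrected_rate(hits, n_g, correction),
        _corrected_rate(fas, n_ng, correction),
        counts,
    )


def _check_rates(hit_rate: float, fa_rate: float) -> None:
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError(
            "rates must lie strictly in (0, 1); apply an extreme-proportion "
            "correction first"
        )


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Sensitivity: z(hit rate) - z(false-alarm rate)."""
    _check_rates(hit_rate, fa_rate)
    return float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))


def criterion(hit_rate: float, fa_rate: float) -> float:
    """Response bias: -(z(hit rate) + z(false-alarm rate)) / 2."""
    _check_rates(hit_rate, fa_rate)
    return float(-(stats.norm.ppf(hit_rate) + stats.norm.ppf(fa_rate)) / 2)


def percent_correct(
    records: pd.DataFrame, participant: str, condition: str | None = None
) -> float:
    """100 x correct / scored trials for one participant cell, probes excluded."""
    sub = records[(records["participant"] == participant) & (~records["probe"])]
    if condition is not None:
        sub = sub[sub["similarity"] == condition]
    if len(sub) == 0:
        raise MissingCellError(
            f"participant {participant!r}, condition {condition!r}: no trials"
        )
    return 100.0 * float(sub["correct"].mean())


def score_sdt(records: pd.DataFrame, correction: str = "loglinear") -> pd.DataFrame:
    """Per-participant, per-similarity SDT table (counts, rates, d', criterion)."""
    scored = records[~records["probe"]]
    rows = []
    for (pid, cond), _ in scored.groupby(["participant", "similarity"], sort=True):
        group = scored.loc[scored["participant"] == pid, "group"].iloc[0]
        h, f, counts = hit_fa_rates(scored, pid, cond, correction=correction)
        rows.append(
            {
                "participant": pid,
                "group": group,
                "similarity": cond,
                **counts,
                "hit_rate": h,
                "fa_rate": f,
                "dprime": dprime(h, f),
                "criterion": criterion(h, f),
            }
        )
    return pd.DataFrame(rows)
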