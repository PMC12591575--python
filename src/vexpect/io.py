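"""Tidy CSV readers/writers for trials, stimuli, string sets, and SDT tables.

Trial dialect (header mandatory, UTF-8, missing RT written empty):
participant,group,experiment,expectancy,complexity,similarity,grammatical,
rt_ms,response,correct,probe,excluded_reason
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grammar import LetterString
from .simulate import TRIAL_COLUMNS

__all__ = [
    "write_trials",
    "read_trials",
    "write_string_set",
    "read_string_set",
    "write_stimuli",
    "write_sdt",
]

_BOOL = {"True": True, "False": False, "true": True, "false": False, "": None}


def write_trials(records: pd.DataFrame, path) -> None:
    df = records.reindex(columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "participant": str,
            "group": str,
            "expectancy": str,
            "complexity": str,
            "similarity": str,
            "response": str,
            "excluded_reason": str,
        },
        keep_default_na=False,
        na_values={"rt_ms": [""]},
        encoding="utf-8",
    )
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial file {path} missing columns {sorted(missing)}")
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    for col in ("correct", "probe"):
        df[col] = df[col].astype(str).map(_BOOL).astype(bool)
    df["grammatical"] = df["grammatical"].astype(str).map(_BOOL)
    df["experiment"] = df["experiment"].astype(int)
    return df.reindex(columns=TRIAL_COLUMNS)


def write_string_set(strings: list[LetterString], path) -> None:
    pd.DataFrame(
        {
            "string": [s.letters for s in strings],
            "grammatical": [s.grammatical for s in strings],
            "similarity": [s.similarity for s in strings],
            "cell": [s.cell for s in strings],
        }
    ).to_csv(path, index=False, encoding="utf-8")


def read_string_set(path) -> list[LetterString]:
    df = pd.read_csv(path, keep_default_na=False, na_values={"similarity": [""]})
    out = []
    for _, r in df.iterrows():
        gram = _BOOL.get(str(r["grammatical"]), None)
        sim = None if pd.isna(r["similarity"]) else float(r["similarity"])
        out.append(LetterString(str(r["string"]), gram, sim, str(r["cell"])))
    return out


def write_stimuli(problems, path) -> None:
    """Export a subtraction or transformation stimulus set (one row per problem)."""
    rows = []
    for i, p in enumerate(problems):
        rows.append(
            {
                "id": i,
                "expectancy": p.expectancy,
                "complexity": p.complexity,
                "display": p.display,
                "correct_answer": getattr(p, "correct_answer", None)
                if hasattr(p, "correct_answer")
                else None,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def write_sdt(table: pd.DataFrame, path) -> None:
    cols = [
        "participant",
        "group",
        "similarity",
        "hits",
        "fas",
        "n_g",
        "n_ng",
        "hit_rate",
        "fa_rate",
        "dprime",
        "criterion",
    ]
    table.reindex(columns=cols).to_csv(path, index=False, encoding="utf-8")
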