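"""Stimulus construction for the three violation-of-expectations tasks.

Experiment 1: single-digit subtraction verification (64 unique equations,
expectancy x complexity balanced).  Experiment 2: alphabet-letter
transformation verification (96 unique problems, +1/+2 rules).  Experiment 3:
artificial-grammar sessions (23 training strings x 4 presentations, 32
categorized test strings x 3 repetitions).

An *expected* stimulus shows the correct solution; an *unexpected* stimulus
shows a lure (correct +/- 1 digit or alphabet position), producing a
violation of the participant's expectation.  Complexity is the number of
operations (one vs two subtrahends; one vs two letters).
"""

from __future__ import annotations

import string as _string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grammar import (
    GrammarSpec,
    LetterString,
    build_chunk_table,
    categorize_test_set,
    enumerate_strings,
    generate_nongrammatical,
    generate_strings,
)

__all__ = [
    "SubtractionProblem",
    "TransformProblem",
    "SessionPlan",
    "GenerationError",
    "gen_subtraction_set",
    "verify_subtraction",
    "apply_rule",
    "gen_transform_set",
    "make_rt_session",
    "assemble_agl_session",
]

ALPHABET = _string.ascii_uppercase

# Timing defaults (ms), stored per experiment rather than hard-coded at use sites.
TIMING = {
    1: {"fixation_ms": 1000, "deadline_ms": 5000, "feedback_ms": 500},
    2: {"fixation_ms": 1000, "deadline_ms": 10000, "feedback_ms": 1000},
    3: {"fixation_ms": 500, "train_display_ms": 3000, "deadline_ms": None},
}


class GenerationError(RuntimeError):
    """Stimulus constraint space exhausted or balancing impossible."""


@dataclass(frozen=True)
class SubtractionProblem:
    minuend: int
    subtrahends: tuple[int, ...]
    shown_solution: int
    expectancy: str  # "expected" | "unexpected"

    def __post_init__(self) -> None:
        if len(self.subtrahends) not in (1, 2):
            raise ValueError("subtraction problems use one or two subtrahends")
        r = self.minuend
        if not 0 <= r <= 9:
            raise ValueError("minuend must be a single digit")
        for s in self.subtrahends:
            r -= s
            if not 0 <= r <= 9:
                raise ValueError("all intermediate results must stay in 0-9")
        if not 0 <= self.shown_solution <= 9:
            raise ValueError("shown solution must be a single digit")
        if (self.shown_solution == r) != (self.expectancy == "expected"):
            raise ValueError("expectancy label inconsistent with shown solution")

    @property
    def correct_answer(self) -> int:
        r = self.minuend
        for s in self.subtrahends:
            r -= s
        return r

    @property
    def complexity(self) -> str:
        return "low" if len(self.subtrahends) == 1 else "high"

    @property
    def display(self) -> str:
        lhs = "-".join(str(x) for x in (self.minuend, *self.subtrahends))
        return f"{lhs}={self.shown_solution}"


def verify_subtraction(p: SubtractionProblem) -> str:
    """Re-evaluate the left-to-right chain difference and label the expectancy."""
    return "expected" if p.correct_answer == p.shown_solution else "unexpected"


def apply_rule(letters: Sequence[str], rule: int) -> tuple[str, ...]:
    """Advance each letter ``rule`` positions along the alphabet, independently."""
    if rule not in (1, 2):
        raise ValueError("rule must be +1 or +2")
    out = []
    for ch in letters:
        idx = ALPHABET.index(ch) + rule
        if idx >= len(ALPHABET):
            raise ValueError(f"rule +{rule} passes the final alphabet letter from {ch!r}")
        out.append(ALPHABET[idx])
    return tuple(out)


@dataclass(frozen=True)
class TransformProblem:
    source_letters: tuple[str, ...]
    rule: int  # +1 or +2
    shown_letters: tuple[str, ...]
    expectancy: str

    def __post_init__(self) -> None:
        if len(self.source_letters) not in (1, 2):
            raise ValueError("transform problems use one or two letters")
        if len(self.shown_letters) != len(self.source_letters):
            raise ValueError("shown letters must match source count")
        shown_all = (*self.source_letters, *self.shown_letters)
        if len(set(shown_all)) != len(shown_all):
            raise ValueError("each letter may appear only once in a problem")
        correct = apply_rule(self.source_letters, self.rule)
        if (self.shown_letters == correct) != (self.expectancy == "expected"):
            raise ValueError("expectancy label inconsistent with shown letters")

    @property
    def complexity(self) -> str:
        return "low" if len(self.source_letters) == 1 else "high"

    @property
    def display(self) -> str:
        return (
            " ".join(self.source_letters)
            + f" | +{self.rule} | "
            + " ".join(self.shown_letters)
        )


def gen_subtraction_set(
    per_cell: int = 16,
    rng=None,
    minuend_range: tuple[int, int] = (2, 9),
) -> list[SubtractionProblem]:
    """Build the subtraction set: ``per_cell`` problems in each expectancy x complexity cell.

    Left-hand sides are unique across the whole set (each equation appears
    once); all partial results stay in 0-9; unexpected lures are correct +/- 1
    with signs balanced, flipping sign when the lure would leave 0-9.
    """
    rng = np.random.default_rng(rng)
    if per_cell == 0:
        return []
    lo, hi = minuend_range
    low_lhs = [
        (a, (b,))
        for a in range(lo, hi + 1)
        for b in range(1, 10)
        if 0 <= a - b <= 9
    ]
    high_lhs = [
        (a, (b, c))
        for a in range(lo, hi + 1)
        for b in range(1, 10)
        for c in range(1, 10)
        if 0 <= a - b <= 9 and 0 <= a - b - c <= 9
    ]
    problems: list[SubtractionProblem] = []
    for lhs_pool in (low_lhs, high_lhs):
        need = 2 * per_cell
        if need > len(lhs_pool):
            raise GenerationError(
                f"need {need} unique left-hand sides but only {len(lhs_pool)} satisfy "
                "the single-digit chain constraint"
            )
        idx = rng.choice(len(lhs_pool), size=need, replace=False)
        chosen = [lhs_pool[i] for i in idx]
        expected, unexpected = chosen[:per_cell], chosen[per_cell:]
        for a, subs in expected:
            correct = a - sum(subs)
            problems.append(SubtractionProblem(a, subs, correct, "expected"))
        # Assign lure signs needs-based: problems whose correct answer sits at
        # a range boundary are forced (0 -> +1, 9 -> -1); the remaining
        # flexible problems absorb whatever keeps the totals balanced.
        need = {+1: per_cell // 2, -1: per_cell - per_cell // 2}
        signs: list[int] = []
        for a, subs in unexpected:
            correct = a - sum(subs)
            feasible = [s for s in (+1, -1) if 0 <= correct + s <= 9]
            sign = max(feasible, key=lambda s: (need[s], -s))
            need[sign] -= 1
            signs.append(sign)
        for (a, subs), sign in zip(unexpected, signs):
            correct = a - sum(subs)
            problems.append(SubtractionProblem(a, subs, correct + sign, "unexpected"))
    return problems


def gen_transform_set(
    per_cell: int = 24,
    rng=None,
    rules: Sequence[int] = (1, 2),
) -> list[TransformProblem]:
    """Build the letter-transformation set: ``per_cell`` problems per expectancy x complexity cell.

    Letters are sampled randomly with no letter repeated within a problem
    (sources and shown letters all distinct) and no rule application past 'Z'.
    Rules are balanced within each cell; lures shift one shown letter +/- 1.
    """
    rng = np.random.default_rng(rng)
    if per_cell == 0:
        return []
    problems: list[TransformProblem] = []
    seen: set[tuple] = set()

    def lure_candidates(sources, correct, sign):
        """All single-letter +/-1 perturbations of the shown row for one sign."""
        out = []
        for which in range(len(correct)):
            pos = ALPHABET.index(correct[which]) + sign
            if not 0 <= pos < len(ALPHABET):
                continue
            shown = list(correct)
            shown[which] = ALPHABET[pos]
            shown = tuple(shown)
            if shown == correct:
                continue
            if len(set(sources) | set(shown)) != 2 * len(sources):
                continue
            out.append(shown)
        return out

    for n_letters, expectancy in (
        (1, "expected"),
        (1, "unexpected"),
        (2, "expected"),
        (2, "unexpected"),
    ):
        rule_pool = [rules[i % len(rules)] for i in range(per_cell)]
        rng.shuffle(rule_pool)
        # lure signs: +1-rule problems can only take a +1 lure (a -1 lure
        # reproduces a source letter), so signs are balanced greedily by
        # remaining need rather than from a fixed pool
        need = {1: per_cell // 2, -1: per_cell - per_cell // 2}
        made = 0
        tries = 0
        while made < per_cell:
            tries += 1
            if tries > 50000:
                raise GenerationError(
                    f"exhausted sampling for cell ({n_letters} letters, {expectancy})"
                )
            rule = rule_pool[made]
            max_idx = len(ALPHABET) - rule - 1
            src_idx = rng.choice(max_idx + 1, size=n_letters, replace=False)
            sources = tuple(ALPHABET[i] for i in src_idx)
            correct = apply_rule(sources, rule)
            if len(set(sources) | set(correct)) != 2 * n_letters:
                continue
            if expectancy == "expected":
                shown = correct
            else:
                feasible = {
                    s: lure_candidates(sources, correct, s)
                    for s in (1, -1)
                    if lure_candidates(sources, correct, s)
                }
                if not feasible:
                    continue
                # prefer the sign with larger remaining need; flexible
                # problems break ties toward -1 to offset forced +1 lures
                sign = max(feasible, key=lambda s: (need[s], -s))
                cands = feasible[sign]
                shown = cands[int(rng.integers(len(cands)))]
                need[sign] -= 1
            key = (sources, rule, shown)
            if key in seen:
                if expectancy == "unexpected":
                    need[sign] += 1
                continue
            seen.add(key)
            problems.append(TransformProblem(sources, rule, shown, expectancy))
            made += 1
    return problems


@dataclass
class SessionPlan:
    """An ordered trial plan for one experiment, with timing and probe metadata."""

    experiment: int
    trials: pd.DataFrame
    timing: dict
    probe_positions: tuple[str, ...] = ("before", "during", "after")
    break_positions: tuple[int, ...] = ()

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def make_rt_session(
    problems: Sequence[SubtractionProblem] | Sequence[TransformProblem],
    experiment: int,
    rng=None,
) -> SessionPlan:
    """Randomize problem order and package timing/probe/break structure."""
    rng = np.random.default_rng(rng)
    rows = []
    for i, p in enumerate(problems):
        rows.append(
            {
                "stimulus_id": i,
                "expectancy": p.expectancy,
                "complexity": p.complexity,
                "display": p.display,
                "correct_response": "Z" if p.expectancy == "expected" else "M",
            }
        )
    df = pd.DataFrame(rows)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    breaks = (len(df) // 2,) if experiment == 1 else ()
    return SessionPlan(
        experiment=experiment,
        trials=df,
        timing=dict(TIMING[experiment]),
        break_positions=breaks,
    )


def assemble_agl_session(
    grammar: GrammarSpec,
    rng=None,
    n_training: int = 23,
    training_reps: int = 4,
    n_test_per_class: int = 16,
    test_reps: int = 3,
    length_range: tuple[int, int] = (2, 6),
    chunk_mode: str = "unique-strings",
) -> SessionPlan:
    """Assemble a full artificial-grammar session.

    Training: ``n_training`` unique grammatical strings, each shown
    ``training_reps`` times, shuffled.  Test: ``n_test_per_class`` novel
    grammatical plus as many nongrammatical strings, categorized into the 2x2
    grammaticality-by-similarity design from the training chunk table, each
    repeated ``test_reps`` times, shuffled.
    """
    rng = np.random.default_rng(rng)
    training = generate_strings(grammar, length_range, n_training, rng)
    train_set = {t.letters for t in training}
    novel = [s for s in enumerate_strings(grammar, length_range) if s not in train_set]
    if len(novel) < n_test_per_class:
        raise GenerationError(
            f"grammar yields only {len(novel)} novel grammatical strings; "
            f"{n_test_per_class} needed"
        )
    idx = rng.choice(len(novel), size=n_test_per_class, replace=False)
    gram_tests = [LetterString(novel[i], grammatical=True) for i in idx]
    nong_tests = generate_nongrammatical(
        grammar, n_test_per_class, rng, length_range=length_range
    )
    weights = training_reps if chunk_mode == "presentation-weighted" else None
    table = build_chunk_table(
        [t.letters for t in training], weights=weights, mode=chunk_mode
    )
    tests = categorize_test_set(gram_tests + nong_tests, grammar, table)

    train_rows = [
        {
            "phase": "training",
            "string": t.letters,
            "grammatical": True,
            "similarity": np.nan,
            "cell": "training",
            "repetition": rep,
        }
        for t in training
        for rep in range(training_reps)
    ]
    rng.shuffle(train_rows)
    test_rows = [
        {
            "phase": "test",
            "string": t.letters,
            "grammatical": t.grammatical,
            "similarity": t.similarity,
            "cell": t.cell,
            "repetition": rep,
        }
        for t in tests
        for rep in range(test_reps)
    ]
    rng.shuffle(test_rows)
    df = pd.DataFrame(train_rows + test_rows)
    df.insert(0, "trial", np.arange(len(df)))
    return SessionPlan(experiment=3, trials=df, timing=dict(TIMING[3]))
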