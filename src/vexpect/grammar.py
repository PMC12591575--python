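"""Finite-state artificial grammar: definition, generation, and chunk-strength scoring.

The grammar is a Markovian rule system: a set of states connected by lettered
transitions.  A string is *grammatical* when some entry-to-exit path emits
exactly its letters (acceptance is nondeterministic; all paths are searched).
Test strings are scored for *chunk strength* — the average training-set
frequency of their contiguous bigrams and trigrams — and categorized into a
2x2 grammaticality-by-similarity design by a within-grammaticality median
split.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "GrammarSpec",
    "LetterString",
    "ChunkTable",
    "GrammarError",
    "accepts",
    "enumerate_strings",
    "generate_strings",
    "generate_nongrammatical",
    "build_chunk_table",
    "chunk_strength",
    "categorize_test_set",
    "load_grammar",
    "default_grammar",
]

CELLS = (
    "grammatical-high",
    "grammatical-low",
    "nongrammatical-high",
    "nongrammatical-low",
    "unassigned",
)


class GrammarError(ValueError):
    """Malformed grammar specification or invalid grammar input."""


@dataclass(frozen=True)
class GrammarSpec:
    """A finite-state Markovian grammar.

    Parameters
    ----------
    states : frozenset of state names.
    transitions : tuple of (source, target, letter) triples.
    entries : tuple of (target, letter) pairs usable as the first step from
        a virtual start node.
    exits : frozenset of states at which a string may terminate.
    alphabet : frozenset of uppercase letters.
    """

    states: frozenset[str]
    transitions: tuple[tuple[str, str, str], ...]
    entries: tuple[tuple[str, str], ...]
    exits: frozenset[str]
    alphabet: frozenset[str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.entries:
            raise GrammarError("grammar must declare at least one entry")
        if not self.exits:
            raise GrammarError("grammar must declare at least one exit")
        for src, dst, letter in self.transitions:
            if src not in self.states or dst not in self.states:
                raise GrammarError(
                    f"transition ({src}, {dst}, {letter}) references unknown state"
                )
            if letter not in self.alphabet:
                raise GrammarError(
                    f"transition letter {letter!r} not in alphabet {sorted(self.alphabet)}"
                )
        for dst, letter in self.entries:
            if dst not in self.states:
                raise GrammarError(f"entry targets unknown state {dst!r}")
            if letter not in self.alphabet:
                raise GrammarError(f"entry letter {letter!r} not in alphabet")
        for st in self.exits:
            if st not in self.states:
                raise GrammarError(f"exit {st!r} is not a declared state")
        # reachability: every state reachable from an entry and able to reach an exit
        fwd: dict[str, set[str]] = {s: set() for s in self.states}
        bwd: dict[str, set[str]] = {s: set() for s in self.states}
        for src, dst, _ in self.transitions:
            fwd[src].add(dst)
            bwd[dst].add(src)
        reached = set()
        frontier = [dst for dst, _ in self.entries]
        while frontier:
            s = frontier.pop()
            if s in reached:
                continue
            reached.add(s)
            frontier.extend(fwd[s])
        if reached != self.states:
            raise GrammarError(f"unreachable states: {sorted(self.states - reached)}")
        reaches_exit = set()
        frontier = list(self.exits)
        while frontier:
            s = frontier.pop()
            if s in reaches_exit:
                continue
            reaches_exit.add(s)
            frontier.extend(bwd[s])
        if reaches_exit != self.states:
            raise GrammarError(
                f"states that cannot reach an exit: {sorted(self.states - reaches_exit)}"
            )

    @property
    def transition_map(self) -> dict[str, tuple[tuple[str, str], ...]]:
        out: dict[str, list[tuple[str, str]]] = {s: [] for s in self.states}
        for src, dst, letter in self.transitions:
            out[src].append((dst, letter))
        return {s: tuple(v) for s, v in out.items()}


def load_grammar(path) -> GrammarSpec:
    """Load a grammar from a YAML file with keys states/entries/transitions/exits/alphabet."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _grammar_from_mapping(raw, source=str(path))


def _grammar_from_mapping(raw: dict, source: str = "<mapping>") -> GrammarSpec:
    required = {"states", "entries", "transitions", "exits", "alphabet"}
    missing = required - set(raw)
    if missing:
        raise GrammarError(f"{source}: missing keys {sorted(missing)}")
    try:
        return GrammarSpec(
            states=frozenset(map(str, raw["states"])),
            transitions=tuple((str(a), str(b), str(c)) for a, b, c in raw["transitions"]),
            entries=tuple((str(a), str(b)) for a, b in raw["entries"]),
            exits=frozenset(map(str, raw["exits"])),
            alphabet=frozenset(map(str, raw["alphabet"])),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, GrammarError):
            raise
        raise GrammarError(f"{source}: malformed grammar ({exc})") from exc


def default_grammar() -> GrammarSpec:
    """The bundled default five-state grammar over {X, V, J, T}."""
    ref = resources.files("vexpect.data").joinpath("grammar_default.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _grammar_from_mapping(raw, source="grammar_default.yaml")


@dataclass
class LetterString:
    """A letter string with optional grammaticality, chunk strength, and design cell."""

    letters: str
    grammatical: bool | None = None
    similarity: float | None = None
    cell: str = "unassigned"

    def __post_init__(self) -> None:
        if self.similarity is not None and self.similarity < 0:
            raise ValueError("similarity must be non-negative")
        if self.cell not in CELLS:
            raise ValueError(f"unknown cell {self.cell!r}")


def _check_letters(grammar: GrammarSpec, s: str) -> None:
    bad = set(s) - set(grammar.alphabet)
    if bad:
        raise GrammarError(f"letters {sorted(bad)} outside grammar alphabet")


def accepts(grammar: GrammarSpec, s: str | Sequence[str]) -> bool:
    """True iff some entry-to-exit path emits exactly the letters of ``s``.

    Implemented as nondeterministic state-set simulation, equivalent to an
    exhaustive search over all paths.  The empty string is never grammatical
    (no zero-length entry-to-exit path exists).
    """
    s = "".join(s)
    _check_letters(grammar, s)
    if not s:
        return False
    tmap = grammar.transition_map
    current = {dst for dst, letter in grammar.entries if letter == s[0]}
    for ch in s[1:]:
        current = {dst for st in current for dst, letter in tmap[st] if letter == ch}
        if not current:
            return False
    return bool(current & grammar.exits)


def enumerate_strings(grammar: GrammarSpec, length_range: tuple[int, int] = (2, 6)) -> list[str]:
    """All distinct grammatical strings with lengths in ``length_range``, sorted."""
    lo, hi = length_range
    if lo < 1:
        raise ValueError("minimum length must be >= 1")
    tmap = grammar.transition_map
    out: set[str] = set()

    def walk(state: str, s: str) -> None:
        if state in grammar.exits and lo <= len(s) <= hi:
            out.add(s)
        if len(s) >= hi:
            return
        for dst, letter in tmap[state]:
            walk(dst, s + letter)

    for dst, letter in grammar.entries:
        walk(dst, letter)
    return sorted(out)


def generate_strings(
    grammar: GrammarSpec,
    length_range: tuple[int, int] = (2, 6),
    n: int = 23,
    rng=None,
    unique: bool = True,
) -> list[LetterString]:
    """Draw ``n`` grammatical strings in the length range, deterministically per seed.

    With ``unique`` (the default) strings are sampled without replacement from
    the full enumeration; requesting more than exist raises an exhaustion error.
    """
    import numpy as np

    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(rng)
    universe = enumerate_strings(grammar, length_range)
    if unique:
        if n > len(universe):
            raise GrammarError(
                f"requested {n} unique grammatical strings but only "
                f"{len(universe)} exist in length range {length_range}"
            )
        idx = rng.choice(len(universe), size=n, replace=False)
    else:
        idx = rng.choice(len(universe), size=n, replace=True)
    return [LetterString(universe[i], grammatical=True) for i in idx]


def generate_nongrammatical(
    grammar: GrammarSpec,
    n: int,
    rng=None,
    length_range: tuple[int, int] = (2, 6),
    seeds: Iterable[str] | None = None,
) -> list[LetterString]:
    """Construct ``n`` distinct nongrammatical strings by single-letter perturbation.

    Each candidate replaces one letter of a grammatical string with another
    alphabet letter; candidates that remain grammatical are discarded, so every
    output violates the rule system while sharing its surface statistics.
    """
    import numpy as np

    rng = np.random.default_rng(rng)
    pool = list(seeds) if seeds is not None else enumerate_strings(grammar, length_range)
    letters = sorted(grammar.alphabet)
    out: list[str] = []
    seen: set[str] = set()
    for _ in range(20000):
        if len(out) >= n:
            break
        base = pool[rng.integers(len(pool))]
        pos = int(rng.integers(len(base)))
        sub = letters[rng.integers(len(letters))]
        cand = base[:pos] + sub + base[pos + 1 :]
        if cand == base or cand in seen:
            continue
        if not accepts(grammar, cand):
            seen.add(cand)
            out.append(cand)
    if len(out) < n:
        raise GrammarError(f"could not construct {n} distinct nongrammatical strings")
    return [LetterString(s, grammatical=False) for s in out]


@dataclass
class ChunkTable:
    """Bigram/trigram counts over a training corpus.

    ``counts`` maps each contiguous bigram or trigram to the number of times
    it occurred across the training items; with presentation weighting each
    item's contribution is multiplied by its presentation count.
    """

    counts: dict[str, float]
    weighting: str = "unique-strings"
    source_size: int = 0

    def __getitem__(self, chunk: str) -> float:
        return self.counts.get(chunk, 0.0)


def _chunks(s: str) -> list[str]:
    bi = [s[i : i + 2] for i in range(len(s) - 1)]
    tri = [s[i : i + 3] for i in range(len(s) - 2)]
    return bi + tri


def build_chunk_table(
    training: Sequence[str | LetterString],
    weights: Sequence[int] | int | None = None,
    mode: str = "unique-strings",
) -> ChunkTable:
    """Count every contiguous bigram and trigram across the training strings."""
    if mode not in ("unique-strings", "presentation-weighted"):
        raise ValueError(f"unknown weighting mode {mode!r}")
    items = [(s.letters if isinstance(s, LetterString) else s) for s in training]
    if not items:
        raise ValueError("training set must be non-empty")
    if weights is None:
        w = [1] * len(items)
    elif isinstance(weights, int):
        w = [weights] * len(items)
    else:
        w = list(weights)
        if len(w) != len(items):
            raise ValueError("weights must match training set length")
    if any(wi < 1 for wi in w):
        raise ValueError("weights must all be >= 1")
    counts: Counter[str] = Counter()
    for s, wi in zip(items, w):
        mult = wi if mode == "presentation-weighted" else 1
        for c in _chunks(s):
            counts[c] += mult
    return ChunkTable(counts=dict(counts), weighting=mode, source_size=len(items))


def chunk_strength(s: str | LetterString, table: ChunkTable) -> float:
    """Average training-set count of the string's contiguous bigrams and trigrams.

    The denominator is (len-1) + max(len-2, 0); chunks absent from training
    count zero.  Strings shorter than 2 letters have no chunks and are rejected.
    """
    s = s.letters if isinstance(s, LetterString) else s
    if len(s) < 2:
        raise ValueError("chunk strength requires at least 2 letters")
    cs = _chunks(s)
    return sum(table[c] for c in cs) / len(cs)


def categorize_test_set(
    tests: Sequence[LetterString],
    grammar: GrammarSpec,
    table: ChunkTable,
) -> list[LetterString]:
    """Assign each test string to the 2x2 grammaticality-by-similarity design.

    Grammaticality comes from :func:`accepts`; similarity is the chunk
    strength, split high/low at the within-grammaticality median.  The split
    is a stable sort by (similarity, letters) followed by an exact half/half
    assignment, so cells are always balanced and ties resolve
    deterministically.
    """
    scored = [
        replace(
            t,
            grammatical=accepts(grammar, t.letters),
            similarity=chunk_strength(t.letters, table),
        )
        for t in tests
    ]
    gram = [t for t in scored if t.grammatical]
    nong = [t for t in scored if not t.grammatical]
    if len(gram) != len(nong) or len(gram) % 2 != 0:
        raise GrammarError(
            "balanced 2x2 categorization needs equal, even counts of grammatical "
            f"and nongrammatical strings (got {len(gram)} vs {len(nong)})"
        )
    out: list[LetterString] = []
    for group, label in ((gram, "grammatical"), (nong, "nongrammatical")):
        ordered = sorted(group, key=lambda t: (t.similarity, t.letters))
        half = len(ordered) // 2
        for i, t in enumerate(ordered):
            t.cell = f"{label}-{'low' if i < half else 'high'}"
            out.append(t)
    return out
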