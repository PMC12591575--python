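"""Grammar acceptance, string generation, chunk tables, and 2x2 categorization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vexpect.grammar import (
    GrammarError,
    GrammarSpec,
    LetterString,
    accepts,
    build_chunk_table,
    categorize_test_set,
    chunk_strength,
    enumerate_strings,
    generate_nongrammatical,
    generate_strings,
)


def dfs_accepts(grammar, s):
    """Independent oracle: exhaustive depth-first enumeration of all paths."""
    if not s:
        return False

    def walk(state, i):
        if i == len(s):
            return state in grammar.exits
        return any(
            walk(dst, i + 1)
            for dst, letter in grammar.transition_map[state]
            if letter == s[i]
        )

    return any(walk(dst, 1) for dst, letter in grammar.entries if letter == s[0])


class TestAccepts:
    def test_reference_strings(self, grammar):
        assert accepts(grammar, "XVJ")
        assert accepts(grammar, "XVXJ")
        assert not accepts(grammar, "XVXT")

    def test_empty_string_rejected(self, grammar):
        assert not accepts(grammar, "")

    def test_letter_outside_alphabet_raises(self, grammar):
        with pytest.raises(GrammarError):
            accepts(grammar, "XQZ")

    @pytest.mark.parametrize("length", range(1, 7))
    def test_matches_exhaustive_dfs_oracle(self, grammar, length):
        letters = sorted(grammar.alphabet)
        for tup in itertools.product(letters, repeat=length):
            s = "".join(tup)
            assert accepts(grammar, s) == dfs_accepts(grammar, s), s


class TestGenerateStrings:
    def test_outputs_all_grammatical_by_oracle(self, grammar):
        out = generate_strings(grammar, (2, 6), 23, rng=42)
        assert len(out) == 23
        assert all(dfs_accepts(grammar, s.letters) for s in out)
        assert all(2 <= len(s.letters) <= 6 for s in out)

    def test_zero_count_gives_empty_list(self, grammar):
        assert generate_strings(grammar, (2, 6), 0, rng=0) == []

    def test_deterministic_per_seed(self, grammar):
        a = [s.letters for s in generate_strings(grammar, (2, 6), 10, rng=7)]
        b = [s.letters for s in generate_strings(grammar, (2, 6), 10, rng=7)]
        assert a == b

    def test_unique_mode_exhaustion_error(self, grammar):
        total = len(enumerate_strings(grammar, (2, 6)))
        with pytest.raises(GrammarError, match="unique"):
            generate_strings(grammar, (2, 6), total + 1, rng=0)

    def test_nongrammatical_generator_violates_grammar(self, grammar):
        out = generate_nongrammatical(grammar, 16, rng=3)
        assert len({s.letters for s in out}) == 16
        assert not any(dfs_accepts(grammar, s.letters) for s in out)


class TestChunkTable:
    def test_hand_enumeration_bigrams_only(self):
        t = build_chunk_table(["XV", "VX"])
        assert t.counts == {"XV": 1, "VX": 1}

    def test_presentation_weighted_hand_enumeration(self):
        t = build_chunk_table(["XVJ"], weights=4, mode="presentation-weighted")
        assert t.counts == {"XV": 4, "VJ": 4, "XVJ": 4}

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            build_chunk_table([])

    @given(
        st.lists(
            st.text(alphabet="XVJT", min_size=2, max_size=6), min_size=1, max_size=12
        ),
        st.lists(st.integers(min_value=1, max_value=5), min_size=12, max_size=12),
    )
    def test_mass_conservation(self, training, weights):
        w = weights[: len(training)]
        t = build_chunk_table(training, weights=w, mode="presentation-weighted")
        bi_mass = sum(v for k, v in t.counts.items() if len(k) == 2)
        tri_mass = sum(v for k, v in t.counts.items() if len(k) == 3)
        assert bi_mass == sum(wi * (len(s) - 1) for s, wi in zip(training, w))
        assert tri_mass == sum(wi * max(len(s) - 2, 0) for s, wi in zip(training, w))


class TestChunkStrength:
    def test_hand_example(self):
        t = build_chunk_table(["XV", "VX"])
        # XVX: bigrams XV (1), VX (1); trigram XVX (0) -> 2/3
        assert chunk_strength("XVX", t) == pytest.approx(2 / 3)

    def test_unseen_chunks_score_zero(self):
        t = build_chunk_table(["XV", "VX"])
        assert chunk_strength("JT", t) == 0.0

    def test_too_short_rejected(self):
        t = build_chunk_table(["XV"])
        with pytest.raises(ValueError):
            chunk_strength("X", t)

    @given(st.permutations(["XVJ", "TVJ", "XVXJ", "TTV", "XJ"]))
    def test_invariant_to_training_order(self, perm):
        base = chunk_strength("XVXJ", build_chunk_table(["XVJ", "TVJ", "XVXJ", "TTV", "XJ"]))
        assert chunk_strength("XVXJ", build_chunk_table(list(perm))) == pytest.approx(base)

    @given(st.integers(min_value=1, max_value=6))
    def test_scales_linearly_with_uniform_weight(self, m):
        training = ["XVJ", "TVJ", "XJ"]
        t1 = build_chunk_table(training, weights=1, mode="presentation-weighted")
        tm = build_chunk_table(training, weights=m, mode="presentation-weighted")
        assert chunk_strength("XVJ", tm) == pytest.approx(m * chunk_strength("XVJ", t1))


class TestCategorizeTestSet:
    def _tests(self, grammar, rng):
        gram = generate_strings(grammar, (2, 6), 16, rng=rng)
        nong = generate_nongrammatical(grammar, 16, rng=rng)
        return gram + nong

    def test_four_balanced_cells_of_eight(self, grammar):
        table = build_chunk_table(
            [s.letters for s in generate_strings(grammar, (2, 6), 23, rng=5)]
        )
        out = categorize_test_set(self._tests(grammar, 6), grammar, table)
        cells = {}
        for s in out:
            cells[s.cell] = cells.get(s.cell, 0) + 1
        assert cells == {
            "grammatical-high": 8,
            "grammatical-low": 8,
            "nongrammatical-high": 8,
            "nongrammatical-low": 8,
        }

    def test_high_mean_similarity_exceeds_low(self, grammar):
        table = build_chunk_table(
            [s.letters for s in generate_strings(grammar, (2, 6), 23, rng=5)]
        )
        out = categorize_test_set(self._tests(grammar, 6), grammar, table)
        hi = np.mean([s.similarity for s in out if s.cell.endswith("high")])
        lo = np.mean([s.similarity for s in out if s.cell.endswith("low")])
        assert hi > lo

    def test_all_equal_similarity_ties_balanced_deterministically(self, grammar):
        # a table none of whose chunks occur in the test strings -> all zeros
        table = build_chunk_table(["JJ"])
        tests = self._tests(grammar, 6)
        out1 = categorize_test_set(tests, grammar, table)
        out2 = categorize_test_set(tests, grammar, table)
        assert [s.cell for s in out1] == [s.cell for s in out2]
        assert sum(s.cell.endswith("high") for s in out1) == 16

    def test_imbalanced_classes_rejected(self, grammar):
        table = build_chunk_table(["XV"])
        gram = generate_strings(grammar, (2, 6), 4, rng=0)
        nong = generate_nongrammatical(grammar, 2, rng=0)
        with pytest.raises(GrammarError, match="balanced"):
            categorize_test_set(gram + nong, grammar, table)


class TestGrammarValidation:
    def test_unreachable_state_rejected(self):
        with pytest.raises(GrammarError, match="unreachable"):
            GrammarSpec(
                states=frozenset({"A", "B"}),
                transitions=(("A", "A", "X"),),
                entries=(("A", "X"),),
                exits=frozenset({"A", "B"}),
                alphabet=frozenset({"X"}),
            )

    def test_transition_letter_outside_alphabet_rejected(self):
        with pytest.raises(GrammarError, match="alphabet"):
            GrammarSpec(
                states=frozenset({"A"}),
                transitions=(("A", "A", "Q"),),
                entries=(("A", "X"),),
                exits=frozenset({"A"}),
                alphabet=frozenset({"X"}),
            )
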