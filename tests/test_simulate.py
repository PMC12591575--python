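"""Trial-level data generator: RT model, SDT responses, censoring, exclusions."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vexpect.config import default_config
from vexpect.simulate import (
    TRIAL_COLUMNS,
    apply_exclusions,
    simulate_agl_experiment,
    simulate_rt_experiment,
)
from vexpect.stimuli import assemble_agl_session, gen_subtraction_set, make_rt_session


@pytest.fixture(scope="module")
def exp1_session():
    return make_rt_session(gen_subtraction_set(rng=0), 1, rng=0)


@pytest.fixture(scope="module")
def agl_session(grammar):
    return assemble_agl_session(grammar, rng=0)


class TestRtSimulation:
    def test_shape_and_columns(self, exp1_session):
        cfg = default_config(1)
        rec = simulate_rt_experiment(cfg, exp1_session, rng=1)
        n_p = 2 * cfg.n_per_group
        assert list(rec.columns) == TRIAL_COLUMNS
        assert len(rec) == n_p * (64 + 3)  # trials plus 3 probes each
        assert rec["probe"].sum() == 3 * n_p
        assert rec["participant"].nunique() == n_p
        assert set(rec["group"]) == {"NT", "CA"}

    def test_deterministic_per_seed(self, exp1_session):
        cfg = default_config(1)
        a = simulate_rt_experiment(cfg, exp1_session, rng=7)
        b = simulate_rt_experiment(cfg, exp1_session, rng=7)
        pd.testing.assert_frame_equal(a, b)

    def test_cell_means_recover_generating_effects(self, exp1_session):
        # huge sample via many participants, normal family, no censoring
        cfg = replace(
            default_config(1),
            n_per_group=150,
            family="normal",
            deadline_ms=None,
            intercept_sd_ms=50.0,
            residual_sd_ms=50.0,
        )
        rec = simulate_rt_experiment(cfg, exp1_session, rng=3)
        nt = rec[(rec["group"] == "NT") & ~rec["probe"]]
        cell = nt.groupby("expectancy")["rt_ms"].mean()
        assert cell["unexpected"] - cell["expected"] == pytest.approx(238, abs=25)
        cpx = nt.groupby("complexity")["rt_ms"].mean()
        assert cpx["high"] - cpx["low"] == pytest.approx(831, abs=25)

    def test_lognormal_family_matches_requested_moments(self, exp1_session):
        cfg = replace(
            default_config(1),
            n_per_group=200,
            intercept_sd_ms=1.0,
            deadline_ms=None,
        )
        rec = simulate_rt_experiment(cfg, exp1_session, rng=5)
        low_exp = rec[
            (rec["group"] == "NT")
            & (rec["expectancy"] == "expected")
            & (rec["complexity"] == "low")
            & ~rec["probe"]
        ]["rt_ms"]
        assert low_exp.mean() == pytest.approx(cfg.baseline_ms, rel=0.02)
        assert low_exp.std() == pytest.approx(cfg.residual_sd_ms, rel=0.10)
        assert (rec.loc[~rec["probe"], "rt_ms"] > 0).all()

    def test_deadline_censors_slow_trials(self, exp1_session):
        cfg = replace(default_config(1), deadline_ms=2000.0)
        rec = simulate_rt_experiment(cfg, exp1_session, rng=2)
        trials = rec[~rec["probe"]]
        censored = trials["rt_ms"].isna()
        assert censored.any()
        assert (trials.loc[censored, "response"] == "").all()
        assert not trials.loc[censored, "correct"].any()
        assert (trials.loc[~censored, "rt_ms"] < 2000.0).all()

    def test_accuracy_matches_generating_probability(self, exp1_session):
        cfg = replace(default_config(1), n_per_group=100, deadline_ms=None)
        rec = simulate_rt_experiment(cfg, exp1_session, rng=4)
        trials = rec[~rec["probe"]]
        for g, p in cfg.accuracy.items():
            acc = trials.loc[trials["group"] == g, "correct"].mean()
            assert acc == pytest.approx(p, abs=0.01)


class TestAglSimulation:
    def test_shape_and_columns(self, agl_session):
        cfg = default_config(3)
        rec = simulate_agl_experiment(cfg, agl_session, rng=1)
        n_p = 2 * cfg.n_per_group
        assert list(rec.columns) == TRIAL_COLUMNS
        assert len(rec) == n_p * (96 + 3)
        trials = rec[~rec["probe"]]
        assert set(trials["response"]) <= {"grammatical", "nongrammatical"}
        assert set(trials["similarity"]) == {"high", "low"}

    def test_response_rates_follow_sdt_cells(self, agl_session):
        cfg = replace(default_config(3), n_per_group=400)
        rec = simulate_agl_experiment(cfg, agl_session, rng=2)
        trials = rec[~rec["probe"]]
        for g in cfg.groups:
            for sim in ("high", "low"):
                d, c = cfg.dprime[g][sim], cfg.criterion[g][sim]
                cell = trials[(trials["group"] == g) & (trials["similarity"] == sim)]
                h = (
                    cell.loc[cell["grammatical"].astype(bool), "response"]
                    == "grammatical"
                ).mean()
                f = (
                    cell.loc[~cell["grammatical"].astype(bool), "response"]
                    == "grammatical"
                ).mean()
                assert h == pytest.approx(stats.norm.cdf(d / 2 - c), abs=0.01)
                assert f == pytest.approx(stats.norm.cdf(-d / 2 - c), abs=0.01)

    def test_correctness_consistent_with_response(self, agl_session):
        rec = simulate_agl_experiment(default_config(3), agl_session, rng=3)
        trials = rec[~rec["probe"]]
        said_gram = trials["response"] == "grammatical"
        assert (trials["correct"] == (said_gram == trials["grammatical"].astype(bool))).all()


class TestExclusions:
    def _records(self):
        rows = []
        for pid, acc, probe_ok in (
            ("p1", 0.9, True),
            ("p2", 0.3, True),  # below chance
            ("p3", 0.9, False),  # fails a probe
        ):
            for i in range(20):
                rows.append(
                    {
                        "participant": pid,
                        "group": "NT",
                        "correct": i < acc * 20,
                        "probe": False,
                    }
                )
            for j in range(3):
                rows.append(
                    {
                        "participant": pid,
                        "group": "NT",
                        "correct": probe_ok or j != 0,
                        "probe": True,
                    }
                )
        return pd.DataFrame(rows)

    def test_both_rules(self):
        kept, log = apply_exclusions(self._records())
        assert set(kept["participant"]) == {"p1"}
        assert dict(zip(log["participant"], log["rule"])) == {
            "p2": "below-chance",
            "p3": "probe-failure",
        }

    def test_probe_only_rule(self):
        kept, log = apply_exclusions(self._records(), rules=("probe-failure",))
        assert set(kept["participant"]) == {"p1", "p2"}
        assert list(log["participant"]) == ["p3"]

    def test_no_rules_keeps_everyone(self):
        kept, log = apply_exclusions(self._records(), rules=())
        assert kept["participant"].nunique() == 3
        assert log.empty
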