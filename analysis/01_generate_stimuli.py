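#!/usr/bin/env python
"""Generate and export the default stimulus sets for all three experiments."""

from pathlib import Path

import numpy as np

from vexpect.grammar import default_grammar
from vexpect.io import write_stimuli
from vexpect.stimuli import assemble_agl_session, gen_subtraction_set, gen_transform_set, make_rt_session

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "stimuli"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    subs = gen_subtraction_set(rng=rng)
    write_stimuli(subs, OUT / "exp1_equations.csv")
    make_rt_session(subs, 1, rng).trials.to_csv(OUT / "exp1_session.csv", index=False)

    trans = gen_transform_set(rng=rng)
    write_stimuli(trans, OUT / "exp2_problems.csv")
    make_rt_session(trans, 2, rng).trials.to_csv(OUT / "exp2_session.csv", index=False)

    sess = assemble_agl_session(default_grammar(), rng=rng)
    sess.trials.to_csv(OUT / "exp3_session.csv", index=False)

    print(f"wrote stimulus sets to {OUT}")


if __name__ == "__main__":
    main()
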