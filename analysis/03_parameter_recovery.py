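#!/usr/bin/env python
"""Monte-Carlo parameter recovery (200 replicates per experiment)."""

from pathlib import Path

from vexpect.recovery import parameter_recovery

SEED = 2026
REPS = 200
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for offset, experiment in enumerate((1, 2, 3)):
        report = parameter_recovery(
            experiment=experiment, n_replicates=REPS, seed=SEED + offset
        )
        report.to_csv(OUT / f"recovery_exp{experiment}.csv", index=False)
        print(f"experiment {experiment}:")
        print(report.to_string(index=False))
        print()


if __name__ == "__main__":
    main()
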