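#!/usr/bin/env python
"""Run the full seeded pipeline (simulate -> exclude -> score -> fit -> report)
once per experiment and collect the estimate tables."""

import shutil
from pathlib import Path

from vexpect.pipeline import RunConfig, run_pipeline

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "runs"


def main() -> None:
    for experiment in (1, 2, 3):
        run_dir = OUT / f"exp{experiment}"
        if run_dir.exists():
            shutil.rmtree(run_dir)
        run_pipeline(RunConfig(experiment=experiment, seed=SEED, out_dir=run_dir))
        print((run_dir / "report.txt").read_text())


if __name__ == "__main__":
    main()
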