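#!/usr/bin/env python
"""A-priori power: per-group sample sizes for the planning effect sizes."""

import json
from pathlib import Path

from vexpect.inference import power_n_per_group

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = [
        {"d": 1.36, "alpha": 0.05, "power": 0.95, "tails": 1},
        {"d": 1.36, "alpha": 0.05, "power": 0.95, "tails": 2},
        {"d": 1.00, "alpha": 0.05, "power": 0.80, "tails": 2},
    ]
    for row in rows:
        row["n_per_group"] = power_n_per_group(
            row["d"], alpha=row["alpha"], power=row["power"], tails=row["tails"]
        )
        print(row)
    (OUT / "power.json").write_text(json.dumps(rows, indent=2) + "\n")


if __name__ == "__main__":
    main()
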