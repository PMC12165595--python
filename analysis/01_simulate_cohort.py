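#!/usr/bin/env python
"""Simulate the study cohort: 9 sample pairs x 2 organs x 50 acquisitions.

Writes the 900-spectrum dataset (CSV dialect) and its ground-truth
trough-depth table under results/cohort/ and reports the realized
class contrast at the 543 nm trough.
"""

import dataclasses
import json
from pathlib import Path

from airwayspec.io import write_dataset
from airwayspec.simulate import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 42


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    ds, truth = simulate_cohort(cfg)
    write_dataset(ds, OUT)
    truth.to_csv(OUT / "ground_truth.csv", index=False, float_format="%.12g")
    (OUT / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2, sort_keys=True) + "\n")

    by_organ = truth.groupby("organ")[["d543", "d578"]].mean()
    print(f"wrote {len(ds)} spectra to {OUT}")
    print("mean realized trough depths per organ:")
    print(by_organ.round(4).to_string())
    ratio = by_organ.loc["trachea", "d543"] / by_organ.loc["esophagus", "d543"]
    print(f"tracheal 543 nm troughs are {ratio:.1f}x deeper than esophageal "
          "ones -- the 'pronounced vs less pronounced' contrast the "
          "classifiers exploit.")


if __name__ == "__main__":
    main()
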