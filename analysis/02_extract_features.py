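#!/usr/bin/env python
"""Preprocess the simulated cohort into the 2-D feature space.

Reference-corrects every raw spectrum, normalizes at the 561 nm peak,
extracts the (r543, r578) trough features, and writes features.csv.
Reports the per-class feature means and the gap between them.
"""

from pathlib import Path

import pandas as pd

from airwayspec.io import read_dataset
from airwayspec.preprocess import features_from_raw

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ds = read_dataset(ROOT / "cohort")
    rows = []
    for s in ds.spectra:
        f = features_from_raw(s, ds.references)
        rows.append({"pair_id": f.meta.pair_id, "organ": f.meta.organ,
                     "acq_index": f.meta.acq_index,
                     "r543": f.r543, "r578": f.r578})
    feats = pd.DataFrame(rows)
    out = ROOT / "features.csv"
    feats.to_csv(out, index=False, float_format="%.12g")

    stats = feats.groupby("organ")[["r543", "r578"]].agg(["mean", "std"])
    print(f"wrote {len(feats)} feature vectors to {out}")
    print(stats.round(4).to_string())
    gap = (feats[feats.organ == "esophagus"].r543.min()
           - feats[feats.organ == "trachea"].r543.max())
    print(f"r543 class gap (min esophagus - max trachea): {gap:+.4f} -- "
          + ("the classes are linearly separable on r543 alone."
             if gap > 0 else "the classes overlap on r543."))


if __name__ == "__main__":
    main()
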