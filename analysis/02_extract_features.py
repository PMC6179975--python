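#!/usr/bin/env python
"""Extract instrument features from the simulated curve tables.

Reads results/data/curves_*.csv, runs the rheometry / pasting / TPA landmark
extractors on every sample, checks the pasting identities (BD = PV - TV,
SB = FV - PV, LO = BD + SB) and writes the per-sample feature table to
results/curve_features.csv.
"""

from pathlib import Path

import numpy as np

import ricotype as rt
from ricotype.io import extract_features_table, read_curve_csv

DATA = Path("results/data")


def main() -> None:
    samples = {}
    for sid, curve in read_curve_csv(DATA / "curves_rheo.csv", "rheo").items():
        samples.setdefault(sid, {})["rheo"] = curve
    for sid, curve in read_curve_csv(DATA / "curves_rva.csv", "rva").items():
        samples.setdefault(sid, {})["rva"] = curve
    for sid, curve in read_curve_csv(DATA / "curves_tpa.csv", "tpa").items():
        samples.setdefault(sid, {})["tpa"] = curve

    feats = extract_features_table(samples, rt.CurveConfig(smoothing_window=1))
    bd = feats["PV"] - feats["TV"]
    sb = feats["FV"] - feats["PV"]
    assert np.allclose(feats["BD"], bd) and np.allclose(feats["SB"], sb)
    assert np.allclose(feats["LO"], bd + sb)
    print(f"extracted {feats.shape[1]} features for {feats.shape[0]} samples; "
          "pasting identities hold to machine precision")
    print(feats[["Gmax", "PV", "BD", "HRD", "COH"]].describe().round(3).loc[["mean", "std"]])
    feats.to_csv("results/curve_features.csv")


if __name__ == "__main__":
    main()
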