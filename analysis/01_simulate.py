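#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes, under results/data/:
  * per-instrument curve tables for a miniature 40-sample cooked-rice study
    (three clusters, one rheometry/RVA/TPA trace per sample) plus the true
    cluster labels;
  * a 211-sample x 25-variable quality panel at the published per-cluster
    moments (clusters of 114/70/27) with its generating labels;
  * a descriptive sensory score set (13 attributes, 150-mm scale,
    5 samples/cluster, 8 panelists).
"""

import argparse
from pathlib import Path

import pandas as pd

import ricotype as rt

OUT = Path("results/data")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    # miniature instrument study: curves with planted landmarks
    samples, truth = rt.gen_cooking_study(sizes=(20, 12, 8), seed=args.seed)
    frames = {"rheo": [], "rva": [], "tpa": []}
    for sid, d in samples.items():
        rheo, rva, tpa = d["rheo"], d["rva"], d["tpa"]
        frames["rheo"].append(pd.DataFrame({
            "sample_id": sid, "time_min": rheo.time_min, "temp_C": rheo.temp_C,
            "g_prime_kPa": rheo.g_prime_kPa,
            "g_double_prime_kPa": rheo.g_double_prime_kPa}))
        frames["rva"].append(pd.DataFrame({
            "sample_id": sid, "time_min": rva.time_min, "temp_C": rva.temp_C,
            "viscosity": rva.viscosity}))
        frames["tpa"].append(pd.DataFrame({
            "sample_id": sid, "time_s": tpa.time_s, "force_kg": tpa.force_kg}))
    for kind, parts in frames.items():
        pd.concat(parts, ignore_index=True).to_csv(OUT / f"curves_{kind}.csv", index=False)
    truth.to_csv(OUT / "curves_true_clusters.csv")
    print(f"wrote {len(samples)} samples x 3 instrument traces")

    # full-scale quality panel at the study moments
    panel, labels = rt.gen_feature_panel(
        rt.PanelSpec(include_redundant=True), seed=args.seed)
    panel.to_csv(OUT / "panel_25vars.csv")
    labels.to_csv(OUT / "panel_true_clusters.csv")
    print(f"wrote quality panel: {panel.shape[0]} samples x {panel.shape[1]} variables "
          f"(cluster sizes {labels.value_counts().sort_index().tolist()})")

    # sensory scores
    scores, cmap = rt.gen_sensory_scores(seed=args.seed)
    scores.to_csv(OUT / "sensory_scores.csv", index=False)
    cmap.rename_axis("sample_id").to_csv(OUT / "sensory_clusters.csv")
    print(f"wrote {len(scores)} sensory scores "
          f"({scores['attribute'].nunique()} attributes, "
          f"{scores['sample_id'].nunique()} samples)")


if __name__ == "__main__":
    main()
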