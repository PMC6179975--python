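#!/usr/bin/env python
"""Correlation-redundancy pruning of the 25-variable quality panel.

Reads results/data/panel_25vars.csv, computes the Pearson matrix with
significance stars, flags |r| > 0.75 pairs, drops the six redundant
variables (pinned study policy) and writes the 19-variable panel, the
correlation matrix, and a pruning report.
"""

import json

import ricotype as rt
from ricotype.io import read_panel_csv

def main() -> None:
    panel = read_panel_csv("results/data/panel_25vars.csv")
    pruned, rep = rt.prune_correlated(panel, threshold=0.75, drop_policy="paper")

    print(f"{panel.shape[1]} variables in; {len(rep.flagged)} flagged pairs "
          f"(|r| > {rep.threshold}); dropped {len(rep.dropped)}: {rep.dropped}")
    print(f"retained {pruned.shape[1]} variables")
    for a, b, r in sorted(rep.flagged, key=lambda t: -abs(t[2]))[:6]:
        print(f"  {a:>12s} ~ {b:<12s} r = {r:+.2f}")

    pruned.to_csv("results/panel_pruned.csv")
    rep.matrix.round(3).to_csv("results/correlation_matrix.csv")
    rep.stars().to_csv("results/correlation_stars.csv")
    with open("results/pruning_report.json", "w") as fh:
        json.dump({"threshold": rep.threshold, "dropped": rep.dropped,
                   "retained": rep.retained,
                   "flagged": [[a, b, round(r, 3)] for a, b, r in rep.flagged]},
                  fh, indent=2)


if __name__ == "__main__":
    main()
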