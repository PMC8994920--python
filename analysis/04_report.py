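#!/usr/bin/env python
"""Summarise the bootstrap ensemble: estimates, CrIs, contrasts, selection.

Produces the summary prevalence table (means, predictive variances, 95%
credible intervals as percentiles of the replicate distribution), the
pairwise scenario contrasts at the horizon, the predictor
selection-proportion table (>= 10%), and a projection figure.
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import mobproj as m
from mobproj.projection import ResultStore
from mobproj.reporting import summary_table


def load_store(results_dir: Path) -> ResultStore:
    prevalence = pd.read_csv(results_dir / "prevalence_replicates.csv")
    with open(results_dir / "model_specs.json") as fh:
        raw_specs = json.load(fh)
    specs = [
        {t: m.ImputationModelSpec(target=d["target"],
                                  selected=tuple(d["selected"]),
                                  forced=tuple(d["forced"]))
         for t, d in rep.items()}
        for rep in raw_specs
    ]
    with open(results_dir / "run_manifest.json") as fh:
        manifest = json.load(fh)
    return ResultStore(prevalence=prevalence, model_specs=specs, manifest=manifest)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    store = load_store(args.results_dir)
    horizon = store.manifest["horizon_year"]

    summary = summary_table(store)
    summary.to_csv(args.results_dir / "prevalence_summary.csv", index=False)

    rows = []
    for outcome in ("climb", "walk"):
        for study in sorted(store.prevalence["study"].unique()):
            for a, b in ((1, 0), (2, 0), (2, 1)):
                est = m.contrast(store, (a, horizon, study, outcome),
                                 (b, horizon, study, outcome))
                rows.append({
                    "outcome": outcome, "study": study,
                    "contrast": f"scenario {a} - scenario {b}",
                    "mean_pp": round(100 * est.mean, 1),
                    "cri_low_pp": round(100 * est.cri_low, 1),
                    "cri_high_pp": round(100 * est.cri_high, 1),
                })
    contrasts = pd.DataFrame(rows)
    contrasts.to_csv(args.results_dir / "contrasts.csv", index=False)

    sel = m.selection_table(store)
    sel.to_csv(args.results_dir / "selection_proportions.csv", index=False)

    fig, axes = plt.subplots(1, 2, figsize=(11, 4), sharey=False)
    for ax, outcome in zip(axes, ("climb", "walk")):
        for scen in sorted(store.prevalence["scenario"].unique()):
            sub = summary[(summary["scenario"] == scen)
                          & (summary["study"] == "ALL")
                          & (summary["outcome"] == outcome)].sort_values("year")
            ax.plot(sub["year"], sub["mean"], marker="o", label=f"scenario {scen}")
            ax.fill_between(sub["year"], sub["cri_low"], sub["cri_high"], alpha=0.15)
        ax.axvline(2012, color="grey", ls=":")
        ax.set_title({"climb": "Stair climbing limitations",
                      "walk": "Walking limitations"}[outcome])
        ax.set_ylabel("prevalence (%), age >= 76")
        ax.legend()
    fig.tight_layout()
    fig.savefig(args.results_dir / "projections.png", dpi=120)

    print("scenario means at the horizon (ALL, age >= min):")
    at_h = summary[(summary["year"] == horizon) & (summary["study"] == "ALL")]
    print(at_h.to_string(index=False))
    print("\npairwise contrasts at the horizon (percentage points):")
    print(contrasts[contrasts["study"] == "ALL"].to_string(index=False))
    print("\ntop selection proportions for the 2012 outcomes:")
    top = sel[sel["target"].isin(["climb_p7", "walk_p7"]) & ~sel["forced"]]
    print(top.sort_values("proportion", ascending=False).head(12).to_string(index=False))


if __name__ == "__main__":
    main()
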