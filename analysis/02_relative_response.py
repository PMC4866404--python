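#!/usr/bin/env python
"""Daily-control normalization and responder percentages.

Reads the per-trial scores from step 01, expresses every trial relative to
its day's two positive controls (induced count minus the control mean;
intensity as percent of the control mean), tallies per-species responder
percentages, and writes:

    results/relative_<organ>.tsv
    results/responders_<organ>.tsv
    results/fig_relative_response.png   (diverticulum panel)
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import dartpulse as dp

RESULTS = Path(__file__).resolve().parent.parent / "results"
ORGANS = ("diverticulum", "copulatory_canal")


def main() -> None:
    for organ in ORGANS:
        scores = pd.read_csv(RESULTS / f"scores_{organ}.tsv", sep="\t")
        rel = dp.relative_response(scores)
        rel.to_csv(RESULTS / f"relative_{organ}.tsv", sep="\t", index=False)
        pct = dp.percent_responders(scores)
        pct.to_csv(RESULTS / f"responders_{organ}.tsv", sep="\t", index=False)
        summ = (
            rel[~rel.is_control]
            .groupby("species")
            .agg(n=("induced_rel", "size"), mean_rel=("induced_rel", "mean"))
            .round(2)
        )
        print(f"-- {organ}: mean relative induced contractions by extract --")
        print(summ.to_string())

    rel = pd.read_csv(RESULTS / "relative_diverticulum.tsv", sep="\t")
    test = rel[~rel.is_control]
    stats = test.groupby("species")["induced_rel"].agg(["mean", "sem", "size"])
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(stats.index, stats["mean"], yerr=stats["sem"], color="#7a9e7e")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("relative induced contractions")
    ax.set_title("Diverticulum response relative to daily controls")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(RESULTS / "fig_relative_response.png", dpi=120)
    print("wrote figure results/fig_relative_response.png")


if __name__ == "__main__":
    main()
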