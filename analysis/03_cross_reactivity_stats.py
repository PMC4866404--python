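#!/usr/bin/env python
"""Inference on the cross-reactivity scores.

For each organ stream:
  * Steel many-one rank test of every extract's relative response (induced
    counts and intensity) against the pooled focal-species controls;
  * paired Wilcoxon between the two daily control time points;
  * Kruskal-Wallis across experimental days;
  * chi-square of each species' responder percentage against the controls;
  * Poisson / Gaussian log-link GLMs with and without the previously tested
    species, compared by AICc (the order-effect check).

Writes results/steel_<organ>.tsv and results/crossreact_tests_<organ>.tsv.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

import dartpulse as dp

RESULTS = Path(__file__).resolve().parent.parent / "results"
ORGANS = ("diverticulum", "copulatory_canal")


def steel_table(rel: pd.DataFrame, column: str) -> pd.DataFrame:
    ctrl = rel[rel.is_control][column].to_numpy()
    treats = {
        sp: g[column].to_numpy()
        for sp, g in rel[~rel.is_control].groupby("species")
        if len(g) >= 2
    }
    res = dp.steel_many_one(ctrl, treats)
    return pd.DataFrame(
        [
            {"response": column, "species": c.name, "n": c.n, "z": c.z, "p_adj": c.p_adj}
            for c in sorted(res.comparisons, key=lambda c: c.p_adj)
        ]
    )


def main() -> None:
    for organ in ORGANS:
        scores = pd.read_csv(RESULTS / f"scores_{organ}.tsv", sep="\t")
        rel = pd.read_csv(RESULTS / f"relative_{organ}.tsv", sep="\t")
        pct = pd.read_csv(RESULTS / f"responders_{organ}.tsv", sep="\t")

        steel = pd.concat(
            [steel_table(rel, "induced_rel"), steel_table(rel, "intensity_rel_pct")]
        )
        steel.to_csv(RESULTS / f"steel_{organ}.tsv", sep="\t", index=False, float_format="%.4f")
        sig = steel[steel.p_adj < 0.05]
        print(f"-- {organ}: extracts diverging from the focal control (Steel) --")
        print(sig.to_string(index=False) if len(sig) else "  none")

        tests = []
        ctrl = scores[scores.is_control]
        c1 = ctrl[ctrl["order"] == 0].sort_values("day")
        c2 = ctrl[ctrl["order"] > 0].sort_values("day")
        z, p = dp.wilcoxon_paired(c1.induced.to_numpy(float), c2.induced.to_numpy(float))
        tests.append({"test": "wilcoxon_control1_vs_control2_induced", "stat": z, "p": p})

        by_day = [g.induced.to_numpy(float) for _, g in scores.groupby("day")]
        H, p = dp.kruskal_wallis(by_day)
        tests.append({"test": "kruskal_wallis_days_induced", "stat": H, "p": p})

        ctrl_counts = (int(ctrl.responded.sum()), len(ctrl))
        for sp, g in scores[~scores.is_control].groupby("species"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                chi2, dof, p = dp.chi_square_responders(
                    (int(g.responded.sum()), len(g)), ctrl_counts
                )
            tests.append({"test": f"chi2_responders_{sp}", "stat": chi2, "p": p})

        test_trials = scores[~scores.is_control].sort_values(["day", "order"]).copy()
        prev = []
        for _, row in test_trials.iterrows():
            day = scores[(scores.day == row.day) & (scores["order"] == row["order"] - 1)]
            prev.append(day.species.iloc[0] if len(day) else "none")
        test_trials["prev_species"] = prev
        cmp_counts = dp.compare_glm_aicc(test_trials, "n_response", "species", "prev_species")
        tests.append(
            {"test": "glm_poisson_counts_aicc_without_vs_with_prev",
             "stat": cmp_counts["aicc_without"] - cmp_counts["aicc_with"],
             "p": np.nan}
        )
        cmp_int = dp.compare_glm_aicc(
            test_trials, "intensity", "species", "prev_species", family="gaussian-log"
        )
        tests.append(
            {"test": "glm_gaussian_intensity_aicc_without_vs_with_prev",
             "stat": cmp_int["aicc_without"] - cmp_int["aicc_with"],
             "p": np.nan}
        )
        print(
            f"order effect (AICc, lower wins): counts prefer "
            f"'{cmp_counts['preferred']}' previous-species term, intensity prefers "
            f"'{cmp_int['preferred']}'"
        )

        pd.DataFrame(tests).to_csv(
            RESULTS / f"crossreact_tests_{organ}.tsv", sep="\t", index=False, float_format="%.4f"
        )
        print(f"wrote results/steel_{organ}.tsv and results/crossreact_tests_{organ}.tsv\n")


if __name__ == "__main__":
    main()
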