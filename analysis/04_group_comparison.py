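"""Compare the featurized cohort across conductivity conditions.

Runs the normality-gated procedure per feature: Shapiro-Wilk per group at
0.05; ANOVA + Tukey HSD when all groups pass, flagged Kruskal-Wallis + Dunn
otherwise.  Finding: amplitude, threshold and the kinetic features separate
the conditions decisively while frequency does not — the programmed
"no frequency change" null survives the comparison.

Reads results/features.csv (run 03 first); writes results/comparison.json
and results/comparison_report.txt.
"""

import json
from pathlib import Path

import pandas as pd

from caflux.stats import compare_conditions
from caflux.workflow import _comparison_report

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = pd.read_csv(OUT / "features.csv")
    results = compare_conditions(table)
    (OUT / "comparison.json").write_text(
        json.dumps({"results": [r.to_dict() for r in results]}, indent=2, sort_keys=True) + "\n"
    )
    report = _comparison_report(results)
    (OUT / "comparison_report.txt").write_text(report)
    for res in results:
        pw = res.pairwise
        hit = pw[(pw.group_a.isin(["low", "high"])) & (pw.group_b.isin(["low", "high"]))]
        print(
            f"{res.feature:20s} {res.omnibus['test']:8s} omnibus p={res.omnibus['p']:.3g}  "
            f"high-vs-low p_adj={hit.p_adj.iloc[0]:.3g} reject={bool(hit.reject.iloc[0])}"
        )


if __name__ == "__main__":
    main()
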