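"""Survival contrast between the two signature-defined clusters.

Patients inherit the applied cluster of their tumour group; Kaplan-Meier
medians and the Mantel-Cox log-rank test compare the clusters. Writes
results/survival_comparison.json.
"""

import json
from pathlib import Path

import pandas as pd

from protstrat import io
from protstrat.stats import km_estimate, logrank_test

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    survival = io.read_survival(ROOT / "panel" / "survival.csv")
    applied = pd.read_csv(ROOT / "applied_clusters.csv",
                          index_col=0).iloc[:, 0]
    truth = json.loads((ROOT / "panel" / "truth.json").read_text())
    group_of_line = {s.rsplit("_R", 1)[0]: g
                     for s, g in truth["group_of_sample"].items()}

    cluster_of_group = {}
    for group in set(group_of_line.values()):
        members = [l for l in applied.index if group_of_line[l] == group]
        cluster_of_group[group] = int(applied[members].mode().iloc[0])
    mapped = survival.assign(cluster=survival["cluster"].map(cluster_of_group))

    chi2, p = logrank_test(mapped)
    medians = {int(c): km_estimate(mapped, cluster=c).median
               for c in sorted(mapped["cluster"].unique())}
    result = {"chi_square": chi2, "p": p,
              "median_survival_by_cluster": medians,
              "cluster_of_group": cluster_of_group}
    (ROOT / "survival_comparison.json").write_text(
        json.dumps(result, indent=2, sort_keys=True) + "\n")

    for c, m in medians.items():
        arm = [g for g, cc in cluster_of_group.items() if cc == c]
        print(f"cluster {c} (groups {'+'.join(sorted(arm))}): "
              f"median survival {m:.1f} time units")
    print(f"Mantel-Cox log-rank: chi-square = {chi2:.3f}, p = {p:.4f}")


if __name__ == "__main__":
    main()
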