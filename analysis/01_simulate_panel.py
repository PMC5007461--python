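"""Generate the synthetic cell-line panel used by the downstream analyses.

Writes a MaxQuant-style protein-groups TSV, sample metadata, a GMT annotation
file, a patient survival table and the planted ground truth to
results/panel/.
"""

import json
from pathlib import Path

from protstrat import io
from protstrat.simulate import PanelConfig, generate_panel

OUT = Path(__file__).resolve().parents[1] / "results" / "panel"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = PanelConfig(seed=SEED)
    matrix, meta, annotations, survival, truth = generate_panel(config)

    io.write_protein_groups(matrix, OUT / "proteinGroups.tsv")
    io.write_sample_meta(meta, OUT / "samples.csv")
    io.write_gmt(annotations, OUT / "annotations.gmt")
    io.write_survival(survival, OUT / "survival.csv")
    (OUT / "truth.json").write_text(json.dumps({
        "group_of_sample": truth.group_of_sample,
        "markers_of_group": {g: sorted(v)
                             for g, v in truth.markers_of_group.items()},
        "shared_markers": sorted(truth.shared_markers),
        "planted_effect": truth.planted_effect,
        "planted_survival_medians": truth.planted_survival_medians,
    }, indent=2, sort_keys=True) + "\n")

    missing = float(matrix.values.isna().to_numpy().mean())
    print(f"panel: {matrix.n_proteins} proteins x {matrix.n_samples} samples "
          f"({config.n_groups} groups x {config.lines_per_group} lines x "
          f"{config.replicates_per_line} replicates)")
    print(f"planted: {config.markers_per_group} markers/group at "
          f"{config.effect_size} log2 units, {config.shared_markers} shared "
          f"axis proteins; missing fraction {missing:.3f}")
    print(f"wrote panel to {OUT}")


if __name__ == "__main__":
    main()
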