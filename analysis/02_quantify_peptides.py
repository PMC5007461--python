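"""Check the label-free quantification core on synthetic peptide tables.

Reconstructs protein profiles from median pairwise peptide ratios and
reports the log2 recovery error against the generator's truth, noiseless
and noisy. Writes results/quantification_check.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from protstrat.quantify import quantify_peptides
from protstrat.simulate import generate_peptide_table

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def recovery_error(noise_sd: float, missing_rate: float) -> float:
    profile = [0.0, 1.5, -1.0, 0.5, 2.0, -0.5]
    peptides, truth = generate_peptide_table(
        20, 6, 6, profile=profile, noise_sd=noise_sd,
        missing_rate=missing_rate, seed=SEED)
    reconstructed = quantify_peptides(peptides)
    err = np.log2(reconstructed.to_numpy() / truth.to_numpy())
    err -= np.nanmean(err, axis=1, keepdims=True)  # per-protein offset free
    return float(np.nanmax(np.abs(err)))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for noise_sd, missing_rate in [(0.0, 0.0), (0.1, 0.0), (0.3, 0.1),
                                   (0.5, 0.2)]:
        err = recovery_error(noise_sd, missing_rate)
        rows.append({"noise_sd": noise_sd, "missing_rate": missing_rate,
                     "max_abs_log2_error": err})
        print(f"noise_sd={noise_sd:.1f} missing={missing_rate:.1f}: "
              f"max |log2 error| = {err:.4f}")
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "quantification_check.csv", index=False)
    noiseless = table["max_abs_log2_error"].iloc[0]
    print(f"noiseless reconstruction is exact to {noiseless:.2e} log2 units; "
          f"errors grow with peptide-level noise as expected")


if __name__ == "__main__":
    main()
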