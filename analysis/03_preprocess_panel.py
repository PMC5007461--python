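"""Filter, average and impute the simulated panel.

Applies the standard chain (flag removal, 2-of-3 replicate filter, replicate
averaging, minimum-valid filter, down-shifted imputation, row z-scoring) and
writes the processed line-level matrix to results/.
"""

from pathlib import Path

from protstrat import io, preprocess

ROOT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    matrix = io.read_protein_groups(ROOT / "panel" / "proteinGroups.tsv")
    meta = io.read_sample_meta(ROOT / "panel" / "samples.csv")
    print(f"input: {matrix.n_proteins} proteins x {matrix.n_samples} samples")

    matrix = preprocess.remove_flagged(matrix)
    matrix = preprocess.filter_replicates(matrix, meta, min_quantified=2)
    print(f"after replicate filter (2 of 3): {matrix.n_proteins} proteins")

    matrix, line_meta = preprocess.average_replicates(matrix, meta)
    matrix = preprocess.filter_min_valid(matrix, min(10, matrix.n_samples))
    print(f"line-averaged, >= {min(10, matrix.n_samples)} valid values: "
          f"{matrix.n_proteins} proteins x {matrix.n_samples} lines")

    imputed = preprocess.impute_downshifted(
        matrix, preprocess.ImputationParams(width=0.15, down_shift=1.8,
                                            seed=SEED))
    io.write_protein_groups(imputed, ROOT / "matrix_imputed.tsv")
    line_meta.to_csv(ROOT / "lines.csv", index_label="sample")

    zscored = preprocess.zscore(imputed, by="rows")
    io.write_protein_groups(zscored, ROOT / "matrix_zscored.tsv")
    print(f"imputed matrix -> {ROOT / 'matrix_imputed.tsv'}; z-scored matrix "
          f"-> {ROOT / 'matrix_zscored.tsv'}")


if __name__ == "__main__":
    main()
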