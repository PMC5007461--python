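"""Filtering, transformation, normalization and imputation of protein matrices.

The canonical order used by the pipeline driver is: flag removal ->
replicate filter -> replicate averaging -> (variability) -> minimum-valid
filter -> imputation; plasma-protein removal precedes PCA when tumour-derived
samples are mixed in. Every operation is also correct standalone and
idempotent where that makes sense (filters).

Conventions: matrices are log2 with NaN missingness; standard deviations use
the n-1 (sample) denominator throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .containers import ProteinMatrix, validate_sample_meta
from .errors import ConfigError, FormatError
from .io import read_protein_groups, write_protein_groups  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Row-filtering thresholds.

    min_replicates_quantified: replicates (out of the line's replicates) in
    which a protein must be observed for the line's values to be kept.
    min_valid_values: observed values a row needs to survive the matrix-wide
    filter (10 for clustering, 30 of 41 for the mixed PCA in the reference
    analysis).
    """

    min_replicates_quantified: int = 2
    min_valid_values: int = 10
    remove_contaminants: bool = True


@dataclass(frozen=True)
class ImputationParams:
    """Down-shifted normal imputation for left-censored missing values.

    Each missing entry in sample column j is drawn from
    Normal(mean_j - down_shift * sd_j, (width * sd_j)^2) with mean_j / sd_j
    computed over the column's observed values. Defaults are width 0.15 and
    down-shift 1.8 (in units of the sample SD).
    """

    width: float = 0.15
    down_shift: float = 1.8
    seed: int = 0
    per_sample: bool = True  # False: one mean/SD for the whole matrix

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("width must be > 0")
        if self.down_shift < 0:
            raise ConfigError("down_shift must be >= 0")


def default_plasma_proteins() -> set[str]:
    """Packaged list of ~200 abundant plasma-protein gene symbols.

    A curated stand-in list of classical high-abundance plasma proteins
    (albumin, immunoglobulin chains, complement, coagulation factors,
    apolipoproteins, protease inhibitors and other acute-phase reactants).
    """
    text = resources.files("protstrat.data").joinpath(
        "plasma_proteins.txt").read_text()
    return {line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")}


def remove_flagged(matrix: ProteinMatrix, remove_contaminants: bool = True
                   ) -> ProteinMatrix:
    """Drop reverse-decoy and only-identified-by-site rows (and contaminants).

    Contaminant removal is on by default but separable.
    """
    flags = matrix.flags
    drop = flags["reverse"] | flags["only_by_site"]
    if remove_contaminants:
        drop = drop | flags["contaminant"]
    keep = matrix.proteins[~drop.to_numpy()]
    logger.info("remove_flagged: %d -> %d rows", matrix.n_proteins, len(keep))
    return matrix.subset_rows(keep)


def filter_replicates(matrix: ProteinMatrix, meta: pd.DataFrame,
                      min_quantified: int = 2) -> ProteinMatrix:
    """Require quantification in >= ``min_quantified`` replicates per line.

    Within each cell line, a protein's replicate values are kept only when at
    least ``min_quantified`` of them are observed; otherwise the line's
    values for that protein are set missing. Rows left with no observed value
    anywhere are dropped. Lines with fewer replicates than expected are
    handled with the same threshold applied to the available replicates.
    """
    validate_sample_meta(meta)
    if min_quantified < 1:
        raise ConfigError("min_quantified must be >= 1")
    values = matrix.values.copy()
    for line, sub in meta.groupby("line", sort=False):
        cols = [s for s in sub.index if s in values.columns]
        if not cols:
            continue
        if len(cols) < min_quantified:
            logger.warning("line %s has only %d replicates (threshold %d)",
                           line, len(cols), min_quantified)
        observed = values[cols].notna().sum(axis=1)
        fail = observed < min(min_quantified, len(cols))
        values.loc[fail, cols] = np.nan
    keep = values.notna().any(axis=1)
    logger.info("filter_replicates: %d -> %d rows", len(values), int(keep.sum()))
    out = matrix.copy()
    out.values = values
    return out.subset_rows(values.index[keep])


def average_replicates(matrix: ProteinMatrix, meta: pd.DataFrame
                       ) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Average replicate log2 intensities into one column per cell line.

    The mean runs over observed replicates only; a line value is missing when
    all its replicates are. Returns the line-level matrix and line-level
    metadata (one row per line). iBAQ values, when present, are averaged on
    linear scale the same way.
    """
    validate_sample_meta(meta)
    line_values: dict[str, pd.Series] = {}
    line_ibaq: dict[str, pd.Series] = {}
    line_rows = []
    for line, sub in meta.groupby("line", sort=False):
        cols = [s for s in sub.index if s in matrix.values.columns]
        if not cols:
            continue
        line_values[line] = matrix.values[cols].mean(axis=1)
        if matrix.ibaq is not None:
            present = [c for c in cols if c in matrix.ibaq.columns]
            line_ibaq[line] = matrix.ibaq[present].mean(axis=1)
        row = sub.iloc[0].to_dict()
        row.pop("replicate", None)
        row["line"] = line
        line_rows.append(row)
    values = pd.DataFrame(line_values)
    ibaq = pd.DataFrame(line_ibaq) if line_ibaq else None
    line_meta = pd.DataFrame(line_rows, index=pd.Index(values.columns,
                                                       name="sample"))
    line_meta["replicate"] = 1
    out = ProteinMatrix(values=values, flags=matrix.flags.copy(), ibaq=ibaq)
    return out, line_meta


def filter_min_valid(matrix: ProteinMatrix, n: int) -> ProteinMatrix:
    """Keep rows with at least ``n`` observed values."""
    if n < 0:
        raise ConfigError("n must be >= 0")
    if n > matrix.n_samples:
        raise ConfigError(
            f"min valid {n} exceeds number of samples {matrix.n_samples}")
    keep = matrix.mask.sum(axis=1) >= n
    logger.info("filter_min_valid(%d): %d -> %d rows", n, matrix.n_proteins,
                int(keep.sum()))
    return matrix.subset_rows(matrix.proteins[keep.to_numpy()])


def remove_plasma_proteins(matrix: ProteinMatrix,
                           plasma_ids: set[str] | None = None
                           ) -> ProteinMatrix:
    """Drop rows whose id (or any ';'-separated member) is a plasma protein."""
    if plasma_ids is None:
        plasma_ids = default_plasma_proteins()
    plasma_ids = set(plasma_ids)

    def hits(protein_id: str) -> bool:
        return any(part in plasma_ids for part in str(protein_id).split(";"))

    keep = [p for p in matrix.proteins if not hits(p)]
    logger.info("remove_plasma_proteins: %d -> %d rows", matrix.n_proteins,
                len(keep))
    return matrix.subset_rows(keep)


def zscore(matrix: ProteinMatrix, by: str = "rows",
           groups: pd.Series | None = None) -> ProteinMatrix:
    """Standardize to mean 0, SD 1 (n-1 denominator) over observed entries.

    by='rows' standardizes each protein across samples (the default for
    clustering); by='columns' standardizes each sample. With ``groups`` (a
    sample -> cohort mapping, e.g. LFQ vs ITRAQ), standardization is applied
    within each cohort's columns separately, so mixed-technology matrices are
    comparable. Zero-variance units are set to all zeros with a warning.
    """
    if by not in ("rows", "columns"):
        raise ConfigError("by must be 'rows' or 'columns'")
    out = matrix.copy()
    if groups is not None:
        groups = pd.Series(groups)
        for cohort in pd.unique(groups):
            cols = [s for s in matrix.samples if groups.get(s) == cohort]
            block = ProteinMatrix(values=matrix.values[cols])
            out.values[cols] = zscore(block, by=by).values
        return out

    values = out.values
    axis = 1 if by == "rows" else 0
    mean = values.mean(axis=axis)
    sd = values.std(axis=axis, ddof=1)
    zero = sd.fillna(0.0) == 0.0
    if zero.any():
        logger.warning("zscore: %d zero-variance %s set to zeros",
                       int(zero.sum()), by)
    sd = sd.where(~zero, 1.0)
    if by == "rows":
        out.values = values.sub(mean, axis=0).div(sd, axis=0)
        rows = zero[zero].index
        out.values.loc[rows] = out.values.loc[rows].where(
            values.loc[rows].isna(), 0.0)
    else:
        out.values = values.sub(mean, axis=1).div(sd, axis=1)
        for col in values.columns[zero.to_numpy()]:
            out.values[col] = out.values[col].where(values[col].isna(), 0.0)
    return out


def normalize_itraq(reporter_matrix: pd.DataFrame, control_channel_id: str
                    ) -> ProteinMatrix:
    """Normalize isobaric reporter intensities against a control channel.

    ``reporter_matrix`` holds raw (linear) reporter intensities; columns may
    be a (run, channel) MultiIndex for multi-run designs or plain channel ids
    for a single run. Per run, log2 reporter intensities are reduced by the
    same-run control channel, the control column is dropped, and finally each
    output column is shifted to median 0.
    """
    if isinstance(reporter_matrix.columns, pd.MultiIndex):
        runs = reporter_matrix.columns.get_level_values(0).unique()
        pieces = []
        for run in runs:
            block = reporter_matrix[run]
            if control_channel_id not in block.columns:
                raise FormatError(
                    f"control channel {control_channel_id!r} absent in run {run!r}")
            norm = _normalize_single_run(block, control_channel_id)
            norm.columns = [f"{run}:{c}" for c in norm.columns]
            pieces.append(norm)
        values = pd.concat(pieces, axis=1)
    else:
        if control_channel_id not in reporter_matrix.columns:
            raise FormatError(
                f"control channel {control_channel_id!r} absent")
        values = _normalize_single_run(reporter_matrix, control_channel_id)
    values = values.sub(values.median(axis=0), axis=1)
    return ProteinMatrix(values=values)


def _normalize_single_run(block: pd.DataFrame, control: str) -> pd.DataFrame:
    arr = block.to_numpy(dtype=float)
    arr = np.where(arr <= 0, np.nan, arr)
    log2 = pd.DataFrame(np.log2(arr), index=block.index, columns=block.columns)
    normed = log2.sub(log2[control], axis=0)
    return normed.drop(columns=[control])


def impute_downshifted(matrix: ProteinMatrix,
                       params: ImputationParams | None = None
                       ) -> ProteinMatrix:
    """Impute missing values from a down-shifted narrowed normal distribution.

    Observed entries are never altered; the observed mask remains available
    via the input matrix. Columns with fewer than two observed values are
    skipped with a warning. Deterministic for a fixed seed.
    """
    params = params or ImputationParams()
    rng = np.random.default_rng(params.seed)
    out = matrix.copy()
    values = out.values

    if not params.per_sample:
        flat = values.to_numpy().ravel()
        observed = flat[np.isfinite(flat)]
        if observed.size < 2:
            logger.warning("impute_downshifted: fewer than 2 observed values")
            return out
        mu, sd = observed.mean(), observed.std(ddof=1)
        miss = values.isna()
        draws = rng.normal(mu - params.down_shift * sd, params.width * sd,
                           size=int(miss.to_numpy().sum()))
        arr = values.to_numpy()
        arr[miss.to_numpy()] = draws
        out.values = pd.DataFrame(arr, index=values.index,
                                  columns=values.columns)
        return out

    for col in values.columns:
        observed = values[col].dropna()
        if observed.size < 2:
            logger.warning("impute_downshifted: column %s has <2 observed "
                           "values, skipped", col)
            continue
        mu, sd = observed.mean(), observed.std(ddof=1)
        miss = values[col].isna()
        n_miss = int(miss.sum())
        if n_miss == 0:
            continue
        values.loc[miss, col] = rng.normal(
            mu - params.down_shift * sd, params.width * sd, size=n_miss)
    return out
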