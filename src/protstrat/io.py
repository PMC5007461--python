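"""Readers and writers for the plain-text formats used throughout.

Supported dialects:

* MaxQuant-style ``proteinGroups`` TSV — columns ``Protein IDs``,
  ``LFQ intensity <sample>``, ``iBAQ <sample>``, ``Reverse``,
  ``Only identified by site``, ``Potential contaminant``. Intensities are
  raw (linear); ``0`` is the missing sentinel; flags use ``+``.
* MaxQuant-style peptide TSV — ``Sequence``, ``Protein IDs``,
  ``Intensity <sample>`` columns.
* GMT annotation files (category <TAB> description <TAB> protein ids...).
* Plain CSV for sample metadata and survival tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FLAG_COLUMNS, ProteinMatrix, validate_sample_meta
from .errors import FormatError

logger = logging.getLogger(__name__)

_FLAG_HEADER = {
    "reverse": "Reverse",
    "only_by_site": "Only identified by site",
    "contaminant": "Potential contaminant",
}
_LFQ_PREFIX = "LFQ intensity "
_IBAQ_PREFIX = "iBAQ "
_INTENSITY_PREFIX = "Intensity "
_FLOAT_FORMAT = "%.17g"  # round-trips IEEE doubles through text


def read_protein_groups(path) -> ProteinMatrix:
    """Read a proteinGroups-style TSV into a log2 :class:`ProteinMatrix`.

    Zero intensities become missing (NaN); LFQ intensities are
    log2-transformed; iBAQ columns, when present, stay on linear scale with
    zeros as NaN.
    """
    table = pd.read_csv(path, sep="\t", dtype={"Protein IDs": str})
    if "Protein IDs" not in table.columns:
        raise FormatError("required column 'Protein IDs' not found")
    lfq_cols = [c for c in table.columns if c.startswith(_LFQ_PREFIX)]
    if not lfq_cols:
        raise FormatError(f"no '{_LFQ_PREFIX}<sample>' columns found")
    samples = [c[len(_LFQ_PREFIX):] for c in lfq_cols]

    raw = table[lfq_cols].to_numpy(dtype=float)
    raw[raw == 0.0] = np.nan
    values = pd.DataFrame(
        np.log2(raw), index=pd.Index(table["Protein IDs"], name="protein"),
        columns=samples,
    )

    flags = pd.DataFrame(index=values.index)
    for key, header in _FLAG_HEADER.items():
        if header in table.columns:
            col = table[header].fillna("").astype(str).str.strip()
            flags[key] = (col == "+").to_numpy()
        else:
            flags[key] = False

    ibaq = None
    ibaq_cols = [c for c in table.columns if c.startswith(_IBAQ_PREFIX)]
    if ibaq_cols:
        ibaq_samples = [c[len(_IBAQ_PREFIX):] for c in ibaq_cols]
        arr = table[ibaq_cols].to_numpy(dtype=float)
        arr[arr == 0.0] = np.nan
        ibaq = pd.DataFrame(arr, index=values.index, columns=ibaq_samples)

    matrix = ProteinMatrix(values=values, flags=flags, ibaq=ibaq)
    logger.info("read %d proteins x %d samples from %s",
                matrix.n_proteins, matrix.n_samples, path)
    return matrix


def write_protein_groups(matrix: ProteinMatrix, path) -> None:
    """Write a :class:`ProteinMatrix` back to the proteinGroups TSV dialect."""
    columns: dict = {"Protein IDs": matrix.proteins}
    linear = np.exp2(matrix.values.to_numpy())
    linear = np.nan_to_num(linear, nan=0.0)
    for j, sample in enumerate(matrix.samples):
        columns[_LFQ_PREFIX + sample] = linear[:, j]
    if matrix.ibaq is not None:
        for sample in matrix.ibaq.columns:
            columns[_IBAQ_PREFIX + sample] = \
                matrix.ibaq[sample].fillna(0.0).to_numpy()
    for key, header in _FLAG_HEADER.items():
        columns[header] = np.where(matrix.flags[key].to_numpy(), "+", "")
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False,
                                 float_format=_FLOAT_FORMAT)


def read_peptide_table(path) -> pd.DataFrame:
    """Read a peptide TSV into a DataFrame (peptide, protein, sample cols).

    Intensity columns are renamed to bare sample ids; zeros become NaN.
    """
    table = pd.read_csv(path, sep="\t")
    for col in ("Sequence", "Protein IDs"):
        if col not in table.columns:
            raise FormatError(f"required column {col!r} not found")
    intensity_cols = [c for c in table.columns if c.startswith(_INTENSITY_PREFIX)]
    if not intensity_cols:
        raise FormatError(f"no '{_INTENSITY_PREFIX}<sample>' columns found")
    out = pd.DataFrame({
        "peptide": table["Sequence"].astype(str),
        "protein": table["Protein IDs"].astype(str),
    })
    for col in intensity_cols:
        vals = table[col].to_numpy(dtype=float)
        vals[vals == 0.0] = np.nan
        out[col[len(_INTENSITY_PREFIX):]] = vals
    return out


def write_peptide_table(peptides: pd.DataFrame, path) -> None:
    sample_cols = [c for c in peptides.columns if c not in ("peptide", "protein")]
    out = pd.DataFrame({
        "Sequence": peptides["peptide"],
        "Protein IDs": peptides["protein"],
    })
    for col in sample_cols:
        out[_INTENSITY_PREFIX + col] = peptides[col].fillna(0.0)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT annotation file into {category: set of protein ids}."""
    annotations: dict[str, set[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line {line_no}: expected >= 3 tab-separated fields")
        annotations[parts[0]] = {p for p in parts[2:] if p}
    return annotations


def write_gmt(annotations: dict[str, set[str]], path, description: str = "na") -> None:
    lines = []
    for category in sorted(annotations):
        members = sorted(annotations[category])
        lines.append("\t".join([category, description, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, index_col="sample")
    return validate_sample_meta(meta)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index_label="sample")


def read_survival(path) -> pd.DataFrame:
    """Read a survival CSV with columns time, event, cluster."""
    table = pd.read_csv(path)
    for col in ("time", "event", "cluster"):
        if col not in table.columns:
            raise FormatError(f"survival table lacks column {col!r}")
    if (table["time"] <= 0).any():
        raise FormatError("survival times must be positive")
    return table


def write_survival(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
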