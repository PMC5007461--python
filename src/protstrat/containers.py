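"""Central in-memory containers.

The pipeline's central object is :class:`ProteinMatrix`: a proteins x samples
matrix of log2 intensities with NaN marking missing values, MaxQuant-style
per-row flags (reverse-decoy hit, identified only by a modification site,
potential contaminant) and an optional parallel iBAQ matrix on linear scale.

Sample metadata travels separately as a plain :class:`pandas.DataFrame`
indexed by sample id with columns ``line`` (cell-line name), ``replicate``
(1-based index), and optionally ``group``, ``entity`` and ``cohort``
(quantification technology tag such as ``LFQ`` or ``ITRAQ``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

FLAG_COLUMNS = ("reverse", "only_by_site", "contaminant")

#: Required metadata columns for replicate-aware operations.
META_COLUMNS = ("line", "replicate")


@dataclass
class ProteinMatrix:
    """Proteins x samples log2-intensity matrix with explicit missingness.

    Parameters
    ----------
    values
        Log2 intensities; index = protein ids (unique), columns = sample ids,
        NaN = missing.
    flags
        Boolean DataFrame aligned to ``values.index`` with columns
        ``reverse``, ``only_by_site`` and ``contaminant``. Created all-False
        when omitted.
    ibaq
        Optional linear-scale iBAQ values aligned to ``values``.
    is_log2
        Scale marker; all package operations expect log2 data.
    """

    values: pd.DataFrame
    flags: pd.DataFrame | None = None
    ibaq: pd.DataFrame | None = None
    is_log2: bool = True

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate protein ids: {list(dupes)[:5]}")
        if self.flags is None:
            self.flags = pd.DataFrame(
                False, index=self.values.index, columns=list(FLAG_COLUMNS)
            )
        else:
            missing = set(FLAG_COLUMNS) - set(self.flags.columns)
            if missing:
                raise FormatError(f"flag columns missing: {sorted(missing)}")
            if not self.flags.index.equals(self.values.index):
                self.flags = self.flags.reindex(self.values.index, fill_value=False)
        if self.ibaq is not None and not self.ibaq.index.equals(self.values.index):
            self.ibaq = self.ibaq.reindex(self.values.index)

    # -- convenience -------------------------------------------------------

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-value mask (True = observed)."""
        return self.values.notna()

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(
            values=self.values.copy(),
            flags=self.flags.copy() if self.flags is not None else None,
            ibaq=self.ibaq.copy() if self.ibaq is not None else None,
            is_log2=self.is_log2,
        )

    def subset_rows(self, ids) -> "ProteinMatrix":
        """Row-subset keeping flags/iBAQ aligned."""
        ids = pd.Index(ids)
        return ProteinMatrix(
            values=self.values.loc[ids],
            flags=self.flags.loc[ids] if self.flags is not None else None,
            ibaq=self.ibaq.loc[ids] if self.ibaq is not None else None,
            is_log2=self.is_log2,
        )


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata contract and return the frame unchanged.

    (line, replicate) pairs must be unique and replicate indices >= 1.
    """
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise FormatError(f"sample metadata lacks required column {col!r}")
    if (meta["replicate"] < 1).any():
        raise FormatError("replicate indices must be >= 1")
    if meta.duplicated(subset=["line", "replicate"]).any():
        raise FormatError("(line, replicate) pairs must be unique")
    return meta


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the panel generator.

    ``shared_markers`` holds the optional program elevated in every group
    except the first (disjoint from the per-group marker sets).
    """

    group_of_sample: dict[str, str]
    markers_of_group: dict[str, set[str]]
    planted_effect: float
    planted_survival_medians: dict[str, float]
    shared_markers: set[str] = field(default_factory=set)

    def group_of_line(self) -> dict[str, str]:
        """Map line name -> group, derived from sample names 'LINE_Rk'."""
        out: dict[str, str] = {}
        for sample, grp in self.group_of_sample.items():
            line = sample.rsplit("_R", 1)[0]
            out[line] = grp
        return out

    def all_markers(self) -> set[str]:
        everything = set(self.shared_markers)
        for ids in self.markers_of_group.values():
            everything |= ids
        return everything
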