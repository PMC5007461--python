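"""Per-protein expression variability across cell lines.

Variability is the standard deviation of logarithmized LFQ intensity across
the (line-averaged) panel; abundance is log10 of the summed iBAQ intensity.
Proteins with SD above a cutoff (default 0.5 on log10 scale) form the
high-variability subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ProteinMatrix
from .errors import ConfigError

_LOG10_2 = np.log10(2.0)


def protein_variability(matrix: ProteinMatrix,
                        ibaq: pd.DataFrame | None = None,
                        min_valid: int = 10,
                        log_base: int = 10) -> pd.DataFrame:
    """Variability records for proteins quantified in >= ``min_valid`` lines.

    Parameters
    ----------
    matrix
        Line-averaged log2 matrix (use the raw matrix only deliberately).
    ibaq
        Linear-scale iBAQ matrix; defaults to ``matrix.ibaq``.
    log_base
        10 (default, matching the usual variability plots) or 2; the SD is
        computed on intensities in this base.

    Returns
    -------
    DataFrame indexed by protein with columns ``sd`` (SD over observed line
    values, n-1 denominator), ``abundance`` (log10 summed iBAQ; NaN when no
    iBAQ is available) and ``n_valid``.
    """
    if log_base not in (2, 10):
        raise ConfigError("log_base must be 2 or 10")
    if min_valid < 1:
        raise ConfigError("min_valid must be >= 1")
    if ibaq is None:
        ibaq = matrix.ibaq

    values = matrix.values
    if log_base == 10:
        values = values * _LOG10_2
    n_valid = values.notna().sum(axis=1)
    sd = values.std(axis=1, ddof=1)

    if ibaq is not None:
        total = ibaq.sum(axis=1, min_count=1)
        abundance = np.log10(total.where(total > 0))
    else:
        abundance = pd.Series(np.nan, index=values.index)

    records = pd.DataFrame({
        "sd": sd, "abundance": abundance, "n_valid": n_valid,
    })
    return records[records["n_valid"] >= min_valid]


def high_variability_set(records: pd.DataFrame, cutoff: float = 0.5
                         ) -> set[str]:
    """Proteins with SD strictly above the cutoff (sd > cutoff)."""
    return set(records.index[records["sd"] > cutoff])
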