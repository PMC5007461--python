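"""Test statistics, multiple testing, enrichment and survival comparison.

The workhorse is an s0-moderated two-sample statistic in the SAM tradition:
``t = (mean_a - mean_b) / (se + s0)`` with a pooled standard error. The
constant s0 damps the significance of low-variance, small-effect features;
s0 = 0 recovers the ordinary two-sample t statistic. P-values evaluate the
moderated statistic against the Student reference distribution of the
unmoderated statistic; where calibration matters, a label-permutation FDR is
available instead.

Enrichment comes in two flavours: Fisher's exact test on a
foreground/background split (categorical), and a rank-based one-dimensional
enrichment whose position score in [-1, 1] locates a category's proteins
within the overall value distribution (+1 = top ranks, -1 = bottom ranks).

Survival comparison uses the Kaplan-Meier product-limit estimator and the
Mantel-Cox log-rank test (via lifelines).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModeratedTestParams:
    s0: float = 2.0
    n_permutations: int = 250
    fdr_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ConfigError("s0 must be >= 0")
        if not 0 < self.fdr_threshold < 1:
            raise ConfigError("fdr_threshold must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")


@dataclass(frozen=True)
class EnrichmentParams:
    min_category_size: int = 4
    fdr_threshold: float = 0.02

    def __post_init__(self) -> None:
        if self.min_category_size < 1:
            raise ConfigError("min_category_size must be >= 1")
        if not 0 < self.fdr_threshold < 1:
            raise ConfigError("fdr_threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# moderated two-sample statistic


def _pooled_se(values_a: np.ndarray, values_b: np.ndarray
               ) -> tuple[float, float, int]:
    na, nb = len(values_a), len(values_b)
    va = values_a.var(ddof=1)
    vb = values_b.var(ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * va + (nb - 1) * vb) / df
    se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    return se, pooled, df


def moderated_t(values_a, values_b, s0: float = 0.0,
                welch: bool = False) -> dict:
    """s0-moderated two-sample statistic for one protein.

    Returns a dict with ``difference`` (mean_a - mean_b), ``statistic``
    (difference / (se + s0)), ``p`` (two-sided, Student reference with the
    unmoderated degrees of freedom evaluated at the moderated statistic) and
    ``df``. The default pools the two group variances; ``welch=True``
    switches to the unpooled standard error with Welch-Satterthwaite df.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("moderated_t needs >= 2 valid values per side")
    if s0 < 0:
        raise ConfigError("s0 must be >= 0")
    diff = a.mean() - b.mean()
    if welch:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1)) \
            if va + vb > 0 else len(a) + len(b) - 2
    else:
        se, _, df = _pooled_se(a, b)
    denom = se + s0
    statistic = diff / denom if denom > 0 else 0.0
    p = 2.0 * sps.t.sf(abs(statistic), df) if denom > 0 else 1.0
    return {"difference": float(diff), "statistic": float(statistic),
            "p": float(p), "df": float(df)}


def moderated_t_matrix(values: pd.DataFrame, labels, group_a, s0: float = 0.0
                       ) -> pd.DataFrame:
    """Vectorized moderated t over all rows: group_a vs the rest.

    NaN-aware; rows with fewer than 2 valid values on either side get NaN
    statistics (and are skipped downstream).
    """
    labels = pd.Series(labels).reindex(values.columns)
    in_a = (labels == group_a).to_numpy()
    return _moderated_t_arrays(values.to_numpy(dtype=float), in_a, s0,
                               index=values.index)


def _moderated_t_arrays(arr: np.ndarray, in_a: np.ndarray, s0: float,
                        index=None) -> pd.DataFrame:
    xa, xb = arr[:, in_a], arr[:, ~in_a]
    na = np.isfinite(xa).sum(axis=1)
    nb = np.isfinite(xb).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma = np.nanmean(np.where(np.isfinite(xa), xa, np.nan), axis=1)
        mb = np.nanmean(np.where(np.isfinite(xb), xb, np.nan), axis=1)
        va = np.nanvar(xa, axis=1, ddof=1)
        vb = np.nanvar(xb, axis=1, ddof=1)
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        diff = ma - mb
        stat = diff / (se + s0)
        p = 2.0 * sps.t.sf(np.abs(stat), df)
    bad = (na < 2) | (nb < 2)
    stat[bad] = np.nan
    p[bad] = np.nan
    diff[bad] = np.nan
    return pd.DataFrame({"difference": diff, "statistic": stat, "p": p,
                         "df": df.astype(float)}, index=index)


# ---------------------------------------------------------------------------
# permutation FDR


def _two_group_indicator(labels) -> tuple[np.ndarray, list]:
    labels = pd.Series(labels)
    uniq = sorted(pd.unique(labels.dropna()))
    if len(uniq) != 2:
        raise ConfigError(f"permutation FDR needs exactly 2 groups, got {uniq}")
    return (labels == uniq[0]).to_numpy(), uniq


def permutation_fdr(values: pd.DataFrame, labels,
                    params: ModeratedTestParams | None = None) -> pd.DataFrame:
    """SAM-style significance: observed |t| against label-permutation nulls.

    For each candidate cutoff c (the observed |statistic| values), the
    estimated FDR is (mean permuted count >= c) / (observed count >= c);
    each protein's q is the smallest estimated FDR over cutoffs at or below
    its own |statistic|, making the significant set the largest one whose
    estimated FDR stays within the threshold.

    When the number of distinct label arrangements is at most
    ``n_permutations`` the permutation distribution is enumerated exactly;
    otherwise seeded random permutations are drawn.
    """
    params = params or ModeratedTestParams()
    if params.n_permutations < 100:
        logger.warning("permutation FDR with %d permutations is noisy",
                       params.n_permutations)
    in_a, _ = _two_group_indicator(labels)
    arr = values.to_numpy(dtype=float)
    n = arr.shape[1]
    na = int(in_a.sum())

    observed = _moderated_t_arrays(arr, in_a, params.s0)
    obs_abs = np.abs(observed["statistic"].to_numpy())
    valid = np.isfinite(obs_abs)

    n_arrangements = math.comb(n, na)
    perm_stats = []
    if n_arrangements <= params.n_permutations:
        for combo in itertools.combinations(range(n), na):
            perm = np.zeros(n, dtype=bool)
            perm[list(combo)] = True
            perm_stats.append(np.abs(
                _moderated_t_arrays(arr, perm, params.s0)["statistic"]
                .to_numpy()))
    else:
        rng = np.random.default_rng(params.seed)
        for _ in range(params.n_permutations):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=na, replace=False)] = True
            perm_stats.append(np.abs(
                _moderated_t_arrays(arr, perm, params.s0)["statistic"]
                .to_numpy()))
    perm_matrix = np.vstack(perm_stats)
    perm_flat = np.sort(perm_matrix[np.isfinite(perm_matrix)])
    n_perm = perm_matrix.shape[0]

    order = np.argsort(-np.where(valid, obs_abs, -np.inf))
    sorted_abs = obs_abs[order]
    q_sorted = np.full(len(order), np.nan)
    running_min = np.inf
    fdr_at = np.full(len(order), np.nan)
    for rank, idx in enumerate(order):
        c = sorted_abs[rank]
        if not np.isfinite(c):
            break
        n_obs = rank + 1
        n_perm_above = len(perm_flat) - np.searchsorted(perm_flat, c,
                                                        side="left")
        fdr = (n_perm_above / n_perm) / n_obs
        fdr_at[rank] = min(fdr, 1.0)
    # q = suffix-min over thresholds at or below each protein's statistic,
    # taken in increasing-threshold direction
    for rank in range(len(order) - 1, -1, -1):
        if np.isfinite(fdr_at[rank]):
            running_min = min(running_min, fdr_at[rank])
            q_sorted[rank] = running_min

    q = np.full(arr.shape[0], np.nan)
    q[order] = q_sorted
    out = observed.copy()
    out.index = values.index
    out["q"] = q
    out["significant"] = np.where(np.isfinite(q),
                                  q <= params.fdr_threshold, False)
    return out


# ---------------------------------------------------------------------------
# multiple testing and enrichment


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(foreground: set[str], background: set[str],
                      annotations: dict[str, set[str]],
                      params: EnrichmentParams | None = None) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment of categories in a foreground set.

    Categories with fewer than ``min_category_size`` background members are
    not tested. Returns a DataFrame sorted by p with columns category,
    n_members (in background), n_foreground (members in foreground),
    odds_ratio, p, q, significant.
    """
    params = params or EnrichmentParams()
    foreground, background = set(foreground), set(background)
    if not foreground:
        raise ConfigError("foreground set is empty")
    if not foreground <= background:
        raise ConfigError("foreground must be a subset of background")
    rows = []
    n_bg = len(background)
    n_fg = len(foreground)
    for category, members in annotations.items():
        in_bg = members & background
        if len(in_bg) < params.min_category_size:
            continue
        a = len(in_bg & foreground)            # fg, in category
        b = n_fg - a                           # fg, out of category
        c = len(in_bg) - a                     # bg-only, in category
        d = (n_bg - n_fg) - c                  # bg-only, out of category
        odds, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"category": category, "n_members": len(in_bg),
                     "n_foreground": a, "odds_ratio": odds, "p": p})
    if not rows:
        return pd.DataFrame(columns=["category", "n_members", "n_foreground",
                                     "odds_ratio", "p", "q", "significant"])
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] <= params.fdr_threshold
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def enrichment_1d(values: pd.Series, annotations: dict[str, set[str]],
                  params: EnrichmentParams | None = None) -> pd.DataFrame:
    """Rank-based 1D annotation enrichment over a numeric per-protein score.

    All n proteins are ranked by value (average ranks for ties; rank 1 =
    smallest). Per category the position score is
    ``2 * (mean rank of members - mean rank of non-members) / n``: +1 when
    members occupy the top ranks, -1 at the bottom, 0 when they spread like
    the rest. P-values come from the two-sided Mann-Whitney U test;
    categories below the minimum size, covering all proteins, or without
    non-member complement are skipped.
    """
    params = params or EnrichmentParams()
    values = values.dropna()
    n = len(values)
    if n == 0:
        raise ConfigError("no values to rank")
    ranks = pd.Series(sps.rankdata(values.to_numpy()), index=values.index)
    universe = set(values.index)
    rows = []
    for category, members in annotations.items():
        inside = members & universe
        m = len(inside)
        if m < params.min_category_size or m == n:
            continue
        member_idx = list(inside)
        outside_idx = list(universe - inside)
        mean_in = ranks[member_idx].mean()
        mean_out = ranks[outside_idx].mean()
        score = 2.0 * (mean_in - mean_out) / n
        p = sps.mannwhitneyu(values[member_idx], values[outside_idx],
                             alternative="two-sided").pvalue
        rows.append({"category": category, "n_members": m,
                     "score": float(score), "p": float(p)})
    if not rows:
        return pd.DataFrame(columns=["category", "n_members", "score", "p",
                                     "q", "significant"])
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] <= params.fdr_threshold
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# survival


@dataclass
class KmResult:
    """Product-limit survival curve and its median."""

    times: np.ndarray           # event/censoring times (sorted)
    survival: np.ndarray        # S(t) just after each time
    median: float               # earliest t with S(t) <= 0.5; inf if never

    def at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_survival(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in table.columns:
            raise ConfigError(f"survival table lacks column {col!r}")
    if (table["time"] <= 0).any():
        raise ConfigError("survival times must be positive")
    return table


def km_estimate(table: pd.DataFrame, cluster=None) -> KmResult:
    """Kaplan-Meier estimate, optionally restricted to one cluster label.

    The median is the earliest time at which the survival function drops to
    0.5 or below; it is infinite when that never happens (e.g. all subjects
    censored).
    """
    table = _check_survival(table)
    if cluster is not None:
        table = table[table["cluster"] == cluster]
        if table.empty:
            raise ConfigError(f"no rows with cluster {cluster!r}")
    fitter = KaplanMeierFitter()
    fitter.fit(table["time"], event_observed=table["event"])
    sf = fitter.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    median = float(fitter.median_survival_time_)
    return KmResult(times=times, survival=surv, median=median)


def logrank_test(table: pd.DataFrame) -> tuple[float, float]:
    """Mantel-Cox log-rank test between the two clusters in the table.

    Returns (chi-square statistic on 1 df, two-sided p). Requires exactly two
    cluster labels; arms without any event are tolerated with a warning.
    """
    table = _check_survival(table)
    if "cluster" not in table.columns:
        raise ConfigError("survival table lacks column 'cluster'")
    clusters = sorted(table["cluster"].unique())
    if len(clusters) != 2:
        raise ConfigError(f"log-rank test needs exactly 2 clusters, got "
                          f"{clusters}")
    arm_a = table[table["cluster"] == clusters[0]]
    arm_b = table[table["cluster"] == clusters[1]]
    for name, arm in zip(clusters, (arm_a, arm_b)):
        if arm["event"].sum() == 0:
            logger.warning("cluster %r has no events", name)
    result = _lifelines_logrank(arm_a["time"], arm_b["time"],
                                event_observed_A=arm_a["event"],
                                event_observed_B=arm_b["event"])
    return float(result.test_statistic), float(result.p_value)
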