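"""Discriminating protein signature via SVM feature selection.

For each group, proteins are ranked one-versus-all by the p-value of the
s0-moderated statistic (default s0 = 4). Feature selection is embedded in a
cross-validation resampling scheme: on each of ``n_repeats`` repeats a
stratified random split reserves 15% of the samples for testing, proteins
are ranked on the training split only, and for each candidate list size k a
linear one-vs-all SVM trained on the top-k training features is scored on
the held-out split. The per-group error curve over k guides the choice of
list size (smallest k within one standard error of the minimum mean error,
overridable), and the final signature is the union of the per-group top-k
lists. The signature is applied to any z-scored matrix by restricting to the
signature rows and cutting a Spearman-distance dendrogram of the samples
into (by default two) clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ConfigError, CoverageError
from .multivariate import cut_clusters, hierarchical_cluster, spearman_distance
from .stats import moderated_t_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureParams:
    n_repeats: int = 250
    train_fraction: float = 0.85
    s0: float = 4.0
    candidate_ks: tuple[int, ...] = (5, 10, 25, 50, 75)
    svm_kernel: str = "linear"
    svm_cost: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if self.s0 < 0:
            raise ConfigError("s0 must be >= 0")
        if not self.candidate_ks or list(self.candidate_ks) != sorted(
                set(self.candidate_ks)):
            raise ConfigError("candidate_ks must be nonempty strictly ascending")
        if self.svm_cost <= 0:
            raise ConfigError("svm_cost must be > 0")


@dataclass
class CvResult:
    """Cross-validation output of :func:`cv_feature_selection`."""

    error_curves: pd.DataFrame      # index k, columns group -> mean error
    error_se: pd.DataFrame          # standard error of the mean error
    aggregate_ranks: dict[str, pd.Series]  # group -> protein -> median rank
    error_trace: pd.DataFrame       # repeat x (group, k) held-out error
    splits: list[dict]              # per repeat: {"train": [...], "test": [...]}

    def ranked_list(self, group: str) -> list[str]:
        """Aggregate ranked protein list (best first) for one group."""
        ranks = self.aggregate_ranks[group]
        return list(ranks.sort_values(kind="mergesort").index)


@dataclass
class SignatureResult:
    per_group_lists: dict[str, list[str]]   # chosen top-k per group, in order
    chosen_ks: dict[str, int]
    signature: set[str]
    overlap_count: int
    error_curves: pd.DataFrame | None = None
    error_trace: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        """Two-column view: protein id, comma-joined source group(s)."""
        sources: dict[str, list[str]] = {}
        for group, ids in self.per_group_lists.items():
            for p in ids:
                sources.setdefault(p, []).append(group)
        rows = [{"protein": p, "groups": ",".join(str(x) for x in g)}
                for p, g in sorted(sources.items())]
        return pd.DataFrame(rows)


def rank_proteins_ova(values: pd.DataFrame, group_labels, target_group,
                      s0: float = 4.0) -> pd.DataFrame:
    """One-vs-all ranking of proteins for one group.

    Proteins are ordered by ascending moderated-t p-value (target group vs
    all other samples), with deterministic tie-breaking by descending
    |statistic| and then by protein id. Rows without a computable statistic
    are placed last.
    """
    labels = pd.Series(group_labels).reindex(values.columns)
    n_target = int((labels == target_group).sum())
    n_rest = int((labels != target_group).sum())
    if n_target < 2 or n_rest < 2:
        raise ConfigError(
            f"group {target_group!r} needs >= 2 samples on both sides "
            f"(got {n_target} vs {n_rest})")
    result = moderated_t_matrix(values, labels, target_group, s0=s0)
    result = result.assign(abs_stat=result["statistic"].abs())
    result["_id"] = result.index.astype(str)
    result = result.sort_values(["p", "abs_stat", "_id"],
                                ascending=[True, False, True],
                                kind="mergesort", na_position="last")
    result["rank"] = np.arange(1, len(result) + 1)
    return result.drop(columns=["abs_stat", "_id"])


def _stratified_split(labels: pd.Series, train_fraction: float,
                      rng: np.random.Generator) -> tuple[list, list]:
    """Per-group random split keeping at least one test and two train samples."""
    train: list = []
    test: list = []
    for group in sorted(labels.unique()):
        members = list(labels.index[labels == group])
        if len(members) < 2:
            raise ConfigError(f"group {group!r} has fewer than 2 samples")
        rng.shuffle(members)
        n_test = max(1, round((1.0 - train_fraction) * len(members)))
        n_test = min(n_test, len(members) - 2) if len(members) > 2 else 1
        test.extend(members[:n_test])
        train.extend(members[n_test:])
    return sorted(train), sorted(test)


def cv_feature_selection(values: pd.DataFrame, group_labels,
                         params: SignatureParams | None = None) -> CvResult:
    """Held-out error curves and aggregate rankings over CV repeats.

    Rankings are computed on the training split only — held-out samples never
    influence feature selection. The per-(group, k) error is the one-vs-all
    SVM's held-out misclassification rate, averaged over repeats; the
    aggregate rank of a protein in a group is its median training rank.
    """
    params = params or SignatureParams()
    labels = pd.Series(group_labels).reindex(values.columns)
    if labels.isna().any():
        raise ConfigError("every sample column needs a group label")
    groups = sorted(labels.unique())
    max_k = max(params.candidate_ks)
    if max_k > values.shape[0]:
        raise ConfigError(f"candidate k {max_k} exceeds number of proteins "
                          f"{values.shape[0]}")
    rng = np.random.default_rng(params.seed)

    rank_store: dict[str, list[pd.Series]] = {g: [] for g in groups}
    error_rows = []
    splits = []
    for repeat in range(params.n_repeats):
        train_ids, test_ids = _stratified_split(labels, params.train_fraction,
                                                rng)
        splits.append({"train": train_ids, "test": test_ids})
        x_train = values[train_ids]
        x_test = values[test_ids]
        y_train = labels[train_ids]
        y_test = labels[test_ids]
        row: dict = {"repeat": repeat}
        for group in groups:
            ranking = rank_proteins_ova(x_train, y_train, group, s0=params.s0)
            rank_store[group].append(
                pd.Series(ranking["rank"].to_numpy(), index=ranking.index))
            ordered = list(ranking.index)
            for k in params.candidate_ks:
                features = ordered[:k]
                clf = SVC(kernel=params.svm_kernel, C=params.svm_cost)
                clf.fit(x_train.loc[features].T.to_numpy(),
                        (y_train == group).to_numpy())
                pred = clf.predict(x_test.loc[features].T.to_numpy())
                row[(group, k)] = float(
                    np.mean(pred != (y_test == group).to_numpy()))
        error_rows.append(row)

    error_trace = pd.DataFrame(error_rows).set_index("repeat")
    error_trace.columns = pd.MultiIndex.from_tuples(error_trace.columns,
                                                    names=["group", "k"])
    mean_err = error_trace.mean(axis=0)
    se_err = error_trace.std(axis=0, ddof=1) / np.sqrt(params.n_repeats) \
        if params.n_repeats > 1 else mean_err * 0.0
    error_curves = mean_err.unstack("group").reindex(list(params.candidate_ks))
    error_se = se_err.unstack("group").reindex(list(params.candidate_ks))

    aggregate = {
        g: pd.concat(rank_store[g], axis=1).median(axis=1).sort_values(
            kind="mergesort")
        for g in groups
    }
    return CvResult(error_curves=error_curves, error_se=error_se,
                    aggregate_ranks=aggregate, error_trace=error_trace,
                    splits=splits)


def choose_k(error_curves: pd.DataFrame, error_se: pd.DataFrame
             ) -> dict[str, int]:
    """Smallest k within one standard error of each group's minimum error."""
    chosen = {}
    for group in error_curves.columns:
        curve = error_curves[group]
        k_best = curve.idxmin()
        ceiling = curve.loc[k_best] + error_se[group].loc[k_best]
        eligible = curve.index[curve <= ceiling]
        chosen[group] = int(eligible.min())
    return chosen


def assemble_signature(ranked_lists: dict[str, list[str]],
                       chosen_ks: dict[str, int],
                       error_curves: pd.DataFrame | None = None,
                       error_trace: pd.DataFrame | None = None
                       ) -> SignatureResult:
    """Union of the per-group top-k ranked proteins.

    ``overlap_count`` is the number of membership duplications absorbed by
    the union (sum of list sizes minus union size); e.g. lists of sizes
    53/10/10 with six overlapping members combine to 67 proteins.
    """
    per_group = {}
    for group, ids in ranked_lists.items():
        k = chosen_ks[group]
        if k > len(ids):
            raise ConfigError(f"chosen k {k} exceeds list length {len(ids)} "
                              f"for group {group!r}")
        per_group[group] = list(ids[:k])
    union: set[str] = set().union(*per_group.values()) if per_group else set()
    overlap = sum(len(v) for v in per_group.values()) - len(union)
    return SignatureResult(per_group_lists=per_group,
                           chosen_ks=dict(chosen_ks), signature=union,
                           overlap_count=overlap, error_curves=error_curves,
                           error_trace=error_trace)


def derive_signature(values: pd.DataFrame, group_labels,
                     params: SignatureParams | None = None,
                     chosen_ks: dict[str, int] | None = None
                     ) -> SignatureResult:
    """End-to-end: CV feature selection + k choice + signature assembly."""
    params = params or SignatureParams()
    cv = cv_feature_selection(values, group_labels, params)
    ks = chosen_ks or choose_k(cv.error_curves, cv.error_se)
    lists = {g: cv.ranked_list(g) for g in cv.aggregate_ranks}
    return assemble_signature(lists, ks, error_curves=cv.error_curves,
                              error_trace=cv.error_trace)


def apply_signature(values: pd.DataFrame, signature: set[str],
                    k_clusters: int = 2, linkage: str = "average"
                    ) -> pd.Series:
    """Cluster samples on the signature rows and cut into ``k_clusters``.

    ``values`` should already be z-scored (group-wise across cohorts when
    quantification technologies are mixed). At least half the signature
    proteins must be present in the matrix. Cluster identities are arbitrary
    labels 1..k; naming conventions (e.g. epithelial-like vs
    mesenchymal-like) are downstream decisions by marker direction.
    """
    signature = set(signature)
    if not signature:
        raise ConfigError("signature is empty")
    present = [p for p in values.index if p in signature]
    if len(present) < len(signature) / 2:
        raise CoverageError(
            f"only {len(present)} of {len(signature)} signature proteins "
            f"present in the matrix")
    restricted = values.loc[present]
    dist = spearman_distance(restricted, axis="columns")
    dend = hierarchical_cluster(dist, linkage=linkage)
    return cut_clusters(dend, k_clusters)
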