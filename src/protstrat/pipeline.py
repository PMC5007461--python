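"""Configuration-driven pipeline chaining all analysis stages.

Stage order: flag removal -> replicate filter -> replicate averaging ->
variability profiling -> minimum-valid filter -> imputation -> z-scoring ->
Spearman hierarchical clustering + PCA -> signature derivation (CV-embedded
SVM feature selection on the cluster labels) -> signature application
(2-cluster cut) -> enrichment (Fisher on the high-variability set, 1D on the
pairwise cluster difference) -> pairwise volcano (s0 = 2, permutation FDR
5%) -> survival comparison of the applied clusters. A machine-readable
manifest records inputs, parameters, seeds and the matrix shape after every
stage; outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, multivariate, preprocess, signature as sig, stats, variability
from .containers import ProteinMatrix
from .errors import ConfigError
from .simulate import PanelConfig, generate_panel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    When ``protein_groups`` is unset, a synthetic panel is generated from
    ``panel`` (seeded by ``seed``); otherwise input files are read from the
    given paths.
    """

    seed: int = 0
    # inputs (all-or-nothing file mode)
    protein_groups: str | None = None
    sample_meta: str | None = None
    annotations: str | None = None
    survival: str | None = None
    panel: PanelConfig = field(default_factory=PanelConfig)
    # preprocessing
    min_replicates_quantified: int = 2
    min_valid_values: int = 10
    remove_contaminants: bool = True
    remove_plasma: bool = False
    imputation: preprocess.ImputationParams | None = None
    # clustering / signature
    n_groups: int = 3
    k_apply: int = 2
    linkage: str = "average"
    signature: sig.SignatureParams | None = None
    # pairwise statistics
    volcano: stats.ModeratedTestParams | None = None
    enrichment: stats.EnrichmentParams | None = None
    variability_cutoff: float = 0.5
    marker_ratio: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.imputation is None:
            self.imputation = preprocess.ImputationParams(seed=self.seed)
        if self.signature is None:
            self.signature = sig.SignatureParams(seed=self.seed)
        if self.volcano is None:
            self.volcano = stats.ModeratedTestParams(s0=2.0, fdr_threshold=0.05,
                                                     seed=self.seed)
        if self.enrichment is None:
            self.enrichment = stats.EnrichmentParams()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        seed = int(raw.get("seed", 0))
        if "panel" in raw:
            panel_kwargs = dict(raw.pop("panel"))
            if "survival_median_by_group" in panel_kwargs:
                panel_kwargs["survival_median_by_group"] = tuple(
                    panel_kwargs["survival_median_by_group"])
            panel_kwargs.setdefault("seed", seed)
            raw["panel"] = PanelConfig(**panel_kwargs)
        if "imputation" in raw:
            kwargs = dict(raw.pop("imputation"))
            kwargs.setdefault("seed", seed)
            raw["imputation"] = preprocess.ImputationParams(**kwargs)
        if "signature" in raw:
            kwargs = dict(raw.pop("signature"))
            if "candidate_ks" in kwargs:
                kwargs["candidate_ks"] = tuple(kwargs["candidate_ks"])
            kwargs.setdefault("seed", seed)
            raw["signature"] = sig.SignatureParams(**kwargs)
        if "volcano" in raw:
            kwargs = dict(raw.pop("volcano"))
            kwargs.setdefault("seed", seed)
            raw["volcano"] = stats.ModeratedTestParams(**kwargs)
        if "enrichment" in raw:
            raw["enrichment"] = stats.EnrichmentParams(**raw.pop("enrichment"))
        if "marker_ratio" in raw and raw["marker_ratio"] is not None:
            raw["marker_ratio"] = tuple(raw["marker_ratio"])
        return cls(**raw)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj)] if isinstance(obj, set) \
            else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


class PipelineRun:
    """Mutable run context accumulating the manifest."""

    def __init__(self, config: PipelineConfig, outdir: Path):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {"config": _jsonable(config), "stages": []}

    def record(self, stage: str, matrix: ProteinMatrix | None = None,
               **extra) -> None:
        entry: dict = {"stage": stage}
        if matrix is not None:
            entry["n_proteins"] = matrix.n_proteins
            entry["n_samples"] = matrix.n_samples
        entry.update(_jsonable(extra))
        self.manifest["stages"].append(entry)
        logger.info("stage %s: %s", stage, entry)

    def write_manifest(self) -> None:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True)
                        + "\n")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full analysis and return the manifest dict.

    Every output file under ``outdir`` is re-derivable from the manifest
    (config + seeds + input paths).
    """
    run = PipelineRun(config, Path(outdir))
    out = run.outdir

    # ---- inputs ----------------------------------------------------------
    truth = None
    if config.protein_groups is not None:
        matrix = io.read_protein_groups(config.protein_groups)
        meta = io.read_sample_meta(config.sample_meta)
        annotations = io.read_gmt(config.annotations) if config.annotations \
            else {}
        survival = io.read_survival(config.survival) if config.survival \
            else None
        run.record("load", matrix, inputs={
            "protein_groups": config.protein_groups,
            "sample_meta": config.sample_meta})
    else:
        panel = config.panel
        if panel.seed != config.seed:
            panel = dataclasses.replace(panel, seed=config.seed)
        matrix, meta, annotations, survival, truth = generate_panel(panel)
        run.record("simulate", matrix, panel=panel)

    # ---- preprocessing ---------------------------------------------------
    matrix = preprocess.remove_flagged(
        matrix, remove_contaminants=config.remove_contaminants)
    run.record("remove_flagged", matrix)

    matrix = preprocess.filter_replicates(
        matrix, meta, min_quantified=config.min_replicates_quantified)
    run.record("filter_replicates", matrix,
               min_quantified=config.min_replicates_quantified)

    matrix, line_meta = preprocess.average_replicates(matrix, meta)
    run.record("average_replicates", matrix)

    records = variability.protein_variability(
        matrix, min_valid=min(10, matrix.n_samples))
    high_var = variability.high_variability_set(
        records, cutoff=config.variability_cutoff)
    records.assign(high_variability=records.index.isin(high_var)).to_csv(
        out / "variability.csv")
    run.record("variability", n_records=len(records),
               n_high_variability=len(high_var),
               cutoff=config.variability_cutoff)

    min_valid = min(config.min_valid_values, matrix.n_samples)
    matrix = preprocess.filter_min_valid(matrix, min_valid)
    run.record("filter_min_valid", matrix, min_valid=min_valid)

    if config.remove_plasma:
        matrix = preprocess.remove_plasma_proteins(matrix)
        run.record("remove_plasma_proteins", matrix)

    matrix = preprocess.impute_downshifted(matrix, config.imputation)
    run.record("impute", matrix, params=config.imputation)

    zmatrix = preprocess.zscore(matrix, by="rows")
    io.write_protein_groups(matrix, out / "protein_matrix_processed.tsv")
    run.record("zscore", zmatrix)

    # ---- clustering & PCA ------------------------------------------------
    dist = multivariate.spearman_distance(zmatrix)
    dend = multivariate.hierarchical_cluster(dist, linkage=config.linkage)
    group_labels = multivariate.cut_clusters(dend, config.n_groups)
    (out / "dendrogram.newick").write_text(dend.to_newick() + "\n")
    group_labels.to_csv(out / "clusters.csv")
    pca_result = multivariate.pca(zmatrix)
    pca_result.scores.to_csv(out / "pca_scores.csv",
                             float_format="%.10g")
    run.record("cluster_pca", zmatrix, n_groups=config.n_groups,
               cluster_sizes=group_labels.value_counts().sort_index()
               .to_dict(),
               explained_variance_top2=float(
                   pca_result.explained_variance_ratio[:2].sum()))

    # ---- signature -------------------------------------------------------
    signature_result = sig.derive_signature(zmatrix.values, group_labels,
                                            config.signature)
    signature_result.to_frame().to_csv(out / "signature.tsv", sep="\t",
                                       index=False)
    signature_result.error_curves.to_csv(out / "error_curves.csv",
                                         float_format="%.10g")
    run.record("signature", chosen_ks=signature_result.chosen_ks,
               signature_size=len(signature_result.signature),
               overlap_count=signature_result.overlap_count)

    applied = sig.apply_signature(zmatrix.values, signature_result.signature,
                                  k_clusters=config.k_apply,
                                  linkage=config.linkage)
    applied.to_csv(out / "applied_clusters.csv")
    run.record("apply_signature",
               cluster_sizes=applied.value_counts().sort_index().to_dict())

    # ---- enrichment & volcano -------------------------------------------
    if annotations:
        fisher = stats.fisher_enrichment(
            foreground=high_var & set(matrix.proteins),
            background=set(matrix.proteins),
            annotations=annotations, params=config.enrichment) \
            if high_var & set(matrix.proteins) else pd.DataFrame()
        fisher.to_csv(out / "enrichment_fisher.csv", index=False)
        run.record("fisher_enrichment", n_tested=len(fisher))

    cluster_ids = sorted(applied.unique())
    volcano = None
    if len(cluster_ids) == 2:
        volcano = stats.permutation_fdr(matrix.values, applied,
                                        config.volcano)
        volcano = volcano.assign(neg_log10_p=-np.log10(volcano["p"]))
        volcano.to_csv(out / "volcano.csv", float_format="%.10g")
        run.record("volcano", s0=config.volcano.s0,
                   fdr_threshold=config.volcano.fdr_threshold,
                   n_significant=int(volcano["significant"].sum()))
        if annotations:
            one_d = stats.enrichment_1d(volcano["difference"].dropna(),
                                        annotations, config.enrichment)
            one_d.to_csv(out / "enrichment_1d.csv", index=False)
            run.record("enrichment_1d", n_tested=len(one_d))

    if config.marker_ratio is not None:
        report = marker_ratio_report(matrix, group_labels,
                                     *config.marker_ratio)
        report.to_csv(out / "marker_ratio.csv", float_format="%.10g")
        run.record("marker_ratio", proteins=list(config.marker_ratio))

    # ---- survival --------------------------------------------------------
    if survival is not None and len(cluster_ids) == 2:
        mapped = _map_survival_clusters(survival, applied, line_meta, truth)
        if mapped is not None and mapped["cluster"].nunique() == 2:
            chi2, p = stats.logrank_test(mapped)
            medians = {
                str(c): stats.km_estimate(mapped, cluster=c).median
                for c in sorted(mapped["cluster"].unique())}
            result = {"chi_square": chi2, "p": p, "median_survival": medians}
            (out / "survival.json").write_text(
                json.dumps(_jsonable(result), indent=2, sort_keys=True) + "\n")
            run.record("survival", **result)

    run.write_manifest()
    return run.manifest


def _map_survival_clusters(survival: pd.DataFrame, applied: pd.Series,
                           line_meta: pd.DataFrame, truth) -> pd.DataFrame | None:
    """Relabel survival rows with the applied 2-cluster partition.

    If the survival table already carries a binary partition it is used as
    is; otherwise its labels are interpreted as biological groups and each
    group is assigned the majority applied-cluster of its cell lines (via
    the ``group`` column of the line metadata).
    """
    if survival["cluster"].nunique() == 2:
        return survival
    if "group" not in line_meta.columns:
        logger.warning("cannot map %d survival groups without line metadata",
                       survival["cluster"].nunique())
        return None
    group_to_cluster = {}
    for group, sub in line_meta.groupby("group"):
        members = [s for s in sub.index if s in applied.index]
        if not members:
            continue
        group_to_cluster[group] = int(applied[members].mode().iloc[0])
    mapped = survival.copy()
    mapped["cluster"] = mapped["cluster"].map(group_to_cluster)
    mapped = mapped.dropna(subset=["cluster"])
    mapped["cluster"] = mapped["cluster"].astype(int)
    return mapped


def marker_ratio_report(matrix: ProteinMatrix, group_labels: pd.Series,
                        protein_a: str, protein_b: str) -> pd.DataFrame:
    """Per-group two-protein log2 ratio (mean of log2 a - log2 b per group).

    Generic form of a marker-ratio readout (e.g. CRABP2/FABP5 between
    epithelial- and mesenchymal-like clusters).
    """
    for p in (protein_a, protein_b):
        if p not in matrix.proteins:
            raise ConfigError(f"protein {p!r} not in matrix")
    diff = matrix.values.loc[protein_a] - matrix.values.loc[protein_b]
    rows = []
    for group in sorted(group_labels.unique()):
        cols = group_labels.index[group_labels == group]
        cols = [c for c in cols if c in diff.index]
        rows.append({"group": group,
                     "log2_ratio_mean": float(diff[cols].mean()),
                     "n_samples": len(cols)})
    return pd.DataFrame(rows)
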