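"""Synthetic proteomic panels with planted structure.

The generator emulates the statistical shape of a label-free cell-line panel
study: a small number of biological groups of cell lines, each measured in
replicate, log2-scale protein intensities with group-specific marker proteins
shifted by a configurable log2 effect, intensity-dependent (left-censored)
missingness, annotation categories concentrated in the marker sets, and
group-dependent survival times for a matched patient cohort.

Ground truth (group membership, marker sets, planted effect and survival
medians) is returned alongside the data so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import ProteinMatrix, SyntheticTruth
from .errors import ConfigError

_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")


def _group_names(n: int) -> list[str]:
    if n <= len(_ROMAN):
        return list(_ROMAN[:n])
    return [f"G{i + 1}" for i in range(n)]


@dataclass(frozen=True)
class PanelConfig:
    """Study conditions for :func:`generate_panel`.

    Defaults mirror a 30-cell-line panel in three groups measured in
    triplicate, scaled to 1,000 proteins: 50 markers per group shifted by
    4 log2 units, plus a 50-protein program shared by the non-first groups
    (the mesenchymal-like axis that makes groups II and III co-cluster
    against group I). The axis programs (group-I markers and the shared
    program) have partial per-line penetrance, emulating the heterogeneity
    of real epithelial/mesenchymal panels; the remaining groups' identity
    markers are fully penetrant. Survival medians default to 58 months for
    the epithelial-like group versus 43.5 months for the rest.
    """

    n_groups: int = 3
    lines_per_group: int = 10
    replicates_per_line: int = 3
    n_proteins: int = 1000
    markers_per_group: int = 50
    shared_markers: int = 50
    effect_size: float = 4.0
    shared_effect_multiplier: float = 1.5
    group1_marker_penetrance: float = 0.75
    base_mean: float = 25.0
    base_sd: float = 2.0
    noise_sd: float = 0.5
    missing_censor_quantile: float = 0.1
    n_categories: int = 20
    marker_category_fraction: float = 0.8
    survival_median_by_group: tuple[float, ...] = (58.0, 43.5, 43.5)
    patients_per_group: int = 28
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_groups": self.n_groups,
            "lines_per_group": self.lines_per_group,
            "replicates_per_line": self.replicates_per_line,
            "n_proteins": self.n_proteins,
            "markers_per_group": self.markers_per_group,
            "n_categories": self.n_categories,
            "patients_per_group": self.patients_per_group,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if self.shared_markers < 0:
            raise ConfigError("shared_markers must be >= 0")
        if self.shared_effect_multiplier < 0:
            raise ConfigError("shared_effect_multiplier must be >= 0")
        if not 0 < self.group1_marker_penetrance <= 1:
            raise ConfigError("group1_marker_penetrance must lie in (0, 1]")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd < 0 or self.base_sd < 0:
            raise ConfigError("noise_sd and base_sd must be >= 0")
        for name in ("missing_censor_quantile", "marker_category_fraction",
                     "censor_rate"):
            value = getattr(self, name)
            if not 0 <= value < 1:
                raise ConfigError(f"{name} must lie in [0, 1), got {value}")
        n_planted = self.n_groups * self.markers_per_group + self.shared_markers
        if n_planted > self.n_proteins:
            raise ConfigError(
                f"{n_planted} planted proteins exceed n_proteins={self.n_proteins}"
            )
        if len(self.survival_median_by_group) < self.n_groups:
            raise ConfigError(
                "survival_median_by_group must provide one median per group"
            )
        if any(m <= 0 for m in self.survival_median_by_group[: self.n_groups]):
            raise ConfigError("survival medians must be positive")


def _censor_left(values: np.ndarray, quantile: float, rng: np.random.Generator
                 ) -> np.ndarray:
    """Boolean missing mask, per column, probit-shaped in log intensity.

    For each column the probability of missingness is Phi((t - x)/s) with s
    set to half the column spread; the threshold t is calibrated numerically
    so the column's expected missing fraction equals ``quantile``.
    """
    miss = np.zeros(values.shape, dtype=bool)
    if quantile <= 0:
        return miss
    for j in range(values.shape[1]):
        col = values[:, j]
        s = 0.5 * col.std()
        if s == 0:
            s = 1.0

        def expected_fraction(t: float) -> float:
            return float(stats.norm.cdf((t - col) / s).mean()) - quantile

        lo, hi = col.min() - 10 * s, col.max() + 10 * s
        t = optimize.brentq(expected_fraction, lo, hi)
        miss[:, j] = rng.random(col.shape) < stats.norm.cdf((t - col) / s)
    return miss


def generate_panel(config: PanelConfig) -> tuple[
        ProteinMatrix, pd.DataFrame, dict[str, set[str]], pd.DataFrame,
        SyntheticTruth]:
    """Generate (matrix, sample metadata, annotations, survival, truth).

    The matrix holds log2 intensities with NaN missingness and a parallel
    iBAQ matrix (linear intensity divided by a per-protein theoretical
    peptide count). Deterministic for a fixed config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    groups = _group_names(config.n_groups)

    lines = [f"{g}-L{i + 1:02d}" for g in groups
             for i in range(config.lines_per_group)]
    line_group = {line: line.split("-L")[0] for line in lines}
    samples = [f"{line}_R{r + 1}" for line in lines
               for r in range(config.replicates_per_line)]
    sample_group = {s: line_group[s.rsplit("_R", 1)[0]] for s in samples}

    proteins = [f"P{i + 1:05d}" for i in range(config.n_proteins)]
    markers_of_group: dict[str, set[str]] = {}
    cursor = 0
    for g in groups:
        markers_of_group[g] = set(proteins[cursor:cursor + config.markers_per_group])
        cursor += config.markers_per_group
    shared = set(proteins[cursor:cursor + config.shared_markers])
    cursor += config.shared_markers

    # log2 intensity model: protein baseline + planted shift + replicate noise
    base = rng.normal(config.base_mean, config.base_sd, size=config.n_proteins)
    shift = np.zeros((config.n_proteins, len(samples)))
    protein_pos = {p: i for i, p in enumerate(proteins)}
    group_cols = {g: [j for j, s in enumerate(samples) if sample_group[s] == g]
                  for g in groups}
    line_of_col = [samples[j].rsplit("_R", 1)[0] for j in range(len(samples))]

    def _planted_shift(rows: list[int], cols: list[int], effect: float,
                       penetrance: float) -> None:
        """Shift marker rows in the given sample columns.

        With penetrance < 1 each (marker, line) pair expresses the shift
        independently with that probability — line-level heterogeneity, so
        replicates of a line agree.
        """
        if penetrance >= 1:
            shift[np.ix_(rows, cols)] += effect
            return
        affected_lines = sorted({line_of_col[j] for j in cols})
        expressed = rng.random((len(rows), len(affected_lines))) < penetrance
        on_of_line = {ln: expressed[:, k]
                      for k, ln in enumerate(affected_lines)}
        rows_arr = np.asarray(rows)
        for j in cols:
            shift[rows_arr[on_of_line[line_of_col[j]]], j] += effect

    # Axis programs (the first group's epithelial-like markers and the shared
    # mesenchymal-like program of all other groups) are heterogeneous: each
    # axis protein is expressed in only a fraction of the relevant lines, so
    # no small protein set classifies group I — its discriminating list must
    # be long, as for real epithelial tumour panels. The per-group identity
    # markers of the remaining groups are fully penetrant.
    for gi, g in enumerate(groups):
        rows = [protein_pos[p] for p in markers_of_group[g]]
        penetrance = config.group1_marker_penetrance if gi == 0 else 1.0
        _planted_shift(rows, group_cols[g], config.effect_size, penetrance)
    if shared:
        # the shared program separates group I from the rest more strongly
        # than individual markers separate the groups, so a 2-cluster cut
        # isolates group I rather than an arbitrary group
        rows = [protein_pos[p] for p in shared]
        shared_effect = config.effect_size * config.shared_effect_multiplier
        rest_cols = sorted(j for g in groups[1:] for j in group_cols[g])
        _planted_shift(rows, rest_cols, shared_effect,
                       config.group1_marker_penetrance)

    noise = rng.normal(0.0, config.noise_sd, size=shift.shape)
    log2_true = base[:, None] + shift + noise

    miss = _censor_left(log2_true, config.missing_censor_quantile, rng)
    values = pd.DataFrame(np.where(miss, np.nan, log2_true),
                          index=pd.Index(proteins, name="protein"),
                          columns=samples)

    n_theoretical = rng.integers(5, 51, size=config.n_proteins)
    ibaq = pd.DataFrame(np.exp2(values.to_numpy()) / n_theoretical[:, None],
                        index=values.index, columns=samples)

    matrix = ProteinMatrix(values=values, ibaq=ibaq)

    meta = pd.DataFrame({
        "line": [s.rsplit("_R", 1)[0] for s in samples],
        "replicate": [int(s.rsplit("_R", 1)[1]) for s in samples],
        "group": [sample_group[s] for s in samples],
        "entity": "cell line",
        "cohort": "LFQ",
    }, index=pd.Index(samples, name="sample"))

    annotations = _make_annotations(config, rng, proteins, markers_of_group)
    survival = _make_survival(config, rng, groups)

    truth = SyntheticTruth(
        group_of_sample=sample_group,
        markers_of_group=markers_of_group,
        planted_effect=config.effect_size,
        planted_survival_medians={
            g: float(config.survival_median_by_group[i])
            for i, g in enumerate(groups)},
        shared_markers=shared,
    )
    return matrix, meta, annotations, survival, truth


def _make_annotations(config: PanelConfig, rng: np.random.Generator,
                      proteins: list[str],
                      markers_of_group: dict[str, set[str]]
                      ) -> dict[str, set[str]]:
    """Marker-concentrated categories first, random filler categories after."""
    annotations: dict[str, set[str]] = {}
    groups = list(markers_of_group)
    n_marker_cats = min(config.n_categories, len(groups))
    for g in groups[:n_marker_cats]:
        members = sorted(markers_of_group[g])
        n_in = max(1, round(config.marker_category_fraction * len(members)))
        chosen = set(rng.choice(members, size=n_in, replace=False))
        # pad with random non-members so the category is not the marker set
        n_pad = max(4 - n_in, rng.integers(2, 6))
        pool = [p for p in proteins if p not in markers_of_group[g]]
        chosen |= set(rng.choice(pool, size=n_pad, replace=False))
        annotations[f"MARKER_SET_{g}"] = chosen
    for k in range(config.n_categories - n_marker_cats):
        size = int(rng.integers(10, 40))
        size = min(size, len(proteins))
        annotations[f"CAT{k + 1:03d}"] = set(
            rng.choice(proteins, size=size, replace=False))
    return annotations


def _make_survival(config: PanelConfig, rng: np.random.Generator,
                   groups: list[str]) -> pd.DataFrame:
    """Exponential survival per group around the planted medians.

    Censoring is an independent exponential time whose rate is calibrated so
    the expected censored fraction equals ``censor_rate`` (keeping the
    Kaplan-Meier estimator unbiased).
    """
    rows = []
    for i, g in enumerate(groups):
        median = config.survival_median_by_group[i]
        scale = median / np.log(2)
        times = rng.exponential(scale=scale, size=config.patients_per_group)
        if config.censor_rate > 0:
            # P(C < T) = mu/(lambda+mu) = censor_rate for independent
            # exponentials with rates lambda (event) and mu (censoring)
            censor_scale = scale * (1 - config.censor_rate) / config.censor_rate
            censor = rng.exponential(scale=censor_scale,
                                     size=config.patients_per_group)
        else:
            censor = np.full(config.patients_per_group, np.inf)
        observed = np.minimum(times, censor)
        event = times <= censor
        for t, e in zip(observed, event):
            rows.append({"time": float(max(t, 1e-9)), "event": int(e),
                         "cluster": g})
    return pd.DataFrame(rows)


def generate_peptide_table(n_proteins: int, peptides_per_protein: int,
                           n_samples: int, profile=None,
                           noise_sd: float = 0.1, missing_rate: float = 0.0,
                           seed: int = 0
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide-level intensity table plus true protein profiles.

    Each peptide's linear intensity is (peptide base) x (protein's sample
    profile) x (multiplicative noise): on log2 scale
    ``base_pep + profile[s] + N(0, noise_sd)``. The returned truth holds, per
    protein and sample, the noiseless summed peptide intensity (linear scale),
    i.e. the profile the quantification module should reconstruct.

    Parameters
    ----------
    profile
        Per-sample log2 offsets (length ``n_samples``); zeros when omitted.
    missing_rate
        Probability for each peptide intensity to be missing at random.
    """
    if peptides_per_protein < 1:
        raise ConfigError("peptides_per_protein must be >= 1")
    if n_proteins < 1 or n_samples < 1:
        raise ConfigError("n_proteins and n_samples must be >= 1")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if not 0 <= missing_rate < 1:
        raise ConfigError("missing_rate must lie in [0, 1)")
    if profile is None:
        profile = np.zeros(n_samples)
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (n_samples,):
        raise ConfigError("profile must have one log2 offset per sample")

    rng = np.random.default_rng(seed)
    samples = [f"S{j + 1}" for j in range(n_samples)]
    rows = []
    truth = np.zeros((n_proteins, n_samples))
    for i in range(n_proteins):
        protein = f"P{i + 1:05d}"
        bases = rng.normal(20.0, 2.0, size=peptides_per_protein)
        truth[i] = np.exp2(bases).sum() * np.exp2(profile)
        for k, b in enumerate(bases):
            log2_int = b + profile + rng.normal(0.0, noise_sd, size=n_samples)
            intensity = np.exp2(log2_int)
            if missing_rate > 0:
                intensity = np.where(rng.random(n_samples) < missing_rate,
                                     np.nan, intensity)
            rows.append({"peptide": f"{protein}_pep{k + 1}", "protein": protein,
                         **dict(zip(samples, intensity))})
    peptides = pd.DataFrame(rows)
    truth_df = pd.DataFrame(truth, index=pd.Index(
        [f"P{i + 1:05d}" for i in range(n_proteins)], name="protein"),
        columns=samples)
    return peptides, truth_df
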