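"""Label-free protein quantification from peptide intensities.

The algorithm follows the MaxLFQ idea: for every protein and every pair of
samples, the protein's pairwise ratio is the median of the ratios of the
peptides observed in *both* samples; a least-squares fit over the resulting
ratio graph reconstructs each protein's relative abundance profile, and the
profile is rescaled so that the total summed intensity of the protein over
all samples is preserved. Samples disconnected from the ratio graph stay
missing; single-sample components keep their observed intensity.

Peptide intensities of zero are treated as missing (the usual raw-table
sentinel). Shared peptides mapping to several protein groups are out of
scope: every peptide belongs to exactly one protein id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError


class RatioEdge(NamedTuple):
    """Median pairwise log2 ratio between two samples for one protein."""

    sample_a: str
    sample_b: str
    log2_ratio: float  # median over shared peptides of log2(I_a / I_b)
    n_peptides: int


@dataclass
class RatioGraph:
    """Per-protein pairwise-ratio graphs over a common sample set.

    Edges are stored once per unordered pair with ``sample_a < sample_b`` in
    column order; the reverse ratio is the negation.
    """

    samples: list[str]
    edges: dict[str, list[RatioEdge]]
    observed_totals: pd.DataFrame  # proteins x samples summed peptide intensity


def _sample_columns(peptides: pd.DataFrame) -> list[str]:
    cols = [c for c in peptides.columns if c not in ("peptide", "protein")]
    if not cols:
        raise FormatError("peptide table has no sample intensity columns")
    return cols


def build_ratio_graph(peptides: pd.DataFrame, min_ratio_count: int = 1
                      ) -> RatioGraph:
    """Median-of-pairwise-peptide-ratio graph per protein.

    For each protein and ordered sample pair (A, B), the edge weight is the
    median over peptides observed in both samples of log2(I_A / I_B); pairs
    with fewer than ``min_ratio_count`` shared peptides get no edge. Only
    peptides observed in both samples of a pair contribute.
    """
    if peptides.empty:
        raise FormatError("peptide table is empty")
    if min_ratio_count < 1:
        raise ConfigError("min_ratio_count must be >= 1")
    samples = _sample_columns(peptides)

    edges: dict[str, list[RatioEdge]] = {}
    totals: dict[str, np.ndarray] = {}
    for protein, block in peptides.groupby("protein", sort=True):
        intensities = block[samples].to_numpy(dtype=float)
        intensities[intensities == 0.0] = np.nan  # zero is the missing sentinel
        log2_int = np.log2(intensities)
        totals[protein] = np.nansum(intensities, axis=0)
        protein_edges: list[RatioEdge] = []
        for a in range(len(samples)):
            for b in range(a + 1, len(samples)):
                both = np.isfinite(log2_int[:, a]) & np.isfinite(log2_int[:, b])
                n_shared = int(both.sum())
                if n_shared < min_ratio_count:
                    continue
                ratio = float(np.median(log2_int[both, a] - log2_int[both, b]))
                protein_edges.append(
                    RatioEdge(samples[a], samples[b], ratio, n_shared))
        edges[protein] = protein_edges

    observed_totals = pd.DataFrame(
        {p: totals[p] for p in edges}, index=samples).T
    observed_totals.index.name = "protein"
    return RatioGraph(samples=samples, edges=edges,
                      observed_totals=observed_totals)


def _connected_components(n: int, pairs: list[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def _solve_component(nodes: list[int], edges: list[tuple[int, int, float]]
                     ) -> np.ndarray:
    """Least-squares log2 profile for one connected component.

    Minimises sum over edges of (x_a - x_b - r_ab)^2; the solution is defined
    up to an additive constant, fixed later by total-intensity preservation.
    """
    index = {node: k for k, node in enumerate(nodes)}
    m, n = len(edges), len(nodes)
    design = np.zeros((m + 1, n))
    rhs = np.zeros(m + 1)
    for row, (a, b, ratio) in enumerate(edges):
        design[row, index[a]] = 1.0
        design[row, index[b]] = -1.0
        rhs[row] = ratio
    # gauge row: pin the mean, removing the additive degeneracy
    design[m, :] = 1.0 / n
    solution, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return solution


def reconstruct_profiles(graph: RatioGraph,
                         observed_totals: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Reconstruct linear-scale abundance profiles from a ratio graph.

    Per protein and per connected component of its sample graph, the log2
    profile minimises the squared deviations from the edge ratios and is then
    shifted so the summed linear abundance over the component equals the
    component's summed observed intensity. Samples with no observation stay
    missing (NaN).
    """
    if observed_totals is None:
        observed_totals = graph.observed_totals
    samples = graph.samples
    out = np.full((len(graph.edges), len(samples)), np.nan)
    proteins = list(graph.edges)
    for i, protein in enumerate(proteins):
        totals = observed_totals.loc[protein, samples].to_numpy(dtype=float)
        observed = np.isfinite(totals) & (totals > 0)
        pairs = [(samples.index(e.sample_a), samples.index(e.sample_b))
                 for e in graph.edges[protein]]
        ratios = [e.log2_ratio for e in graph.edges[protein]]
        comps = _connected_components(len(samples), pairs)
        for comp in comps:
            comp_observed = [j for j in comp if observed[j]]
            if not comp_observed:
                continue  # nothing measured in this component
            if len(comp_observed) == 1 and len(comp) == 1:
                j = comp[0]
                out[i, j] = totals[j]  # forced by total preservation
                continue
            comp_set = set(comp)
            comp_edges = [(a, b, r) for (a, b), r in zip(pairs, ratios)
                          if a in comp_set]
            if not comp_edges:
                # isolated observed node inside a degenerate component
                for j in comp_observed:
                    out[i, j] = totals[j]
                continue
            log_profile = _solve_component(comp, comp_edges)
            linear = np.exp2(log_profile)
            total = totals[comp_observed].sum()
            linear *= total / linear.sum()
            for k, j in enumerate(comp):
                out[i, j] = linear[k]
    return pd.DataFrame(out, index=pd.Index(proteins, name="protein"),
                        columns=samples)


def quantify_peptides(peptides: pd.DataFrame, min_ratio_count: int = 1
                      ) -> pd.DataFrame:
    """Convenience wrapper: ratio graph + reconstruction in one call."""
    graph = build_ratio_graph(peptides, min_ratio_count=min_ratio_count)
    return reconstruct_profiles(graph)


def compute_ibaq(protein_total_intensity: float,
                 n_theoretical_peptides: int) -> float:
    """iBAQ: total intensity divided by theoretically observable peptides."""
    if n_theoretical_peptides < 1:
        raise ConfigError("n_theoretical_peptides must be >= 1")
    if protein_total_intensity < 0:
        raise ConfigError("protein intensity must be >= 0")
    return protein_total_intensity / n_theoretical_peptides
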