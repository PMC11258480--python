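"""Consensus perturbation-similarity network from log2 fold-change profiles.

Pairwise similarities between perturbation effect profiles are scored by
several methods (absolute Pearson, absolute Spearman, normalized mutual
information on equal-frequency bins); each method's off-diagonal scores are
converted to fractional ranks in [0, 1] and averaged, then rescaled so the
strongest link has intensity 1 — a rank-aggregation consensus.  Links at or
above an intensity threshold (0.8 by default) form the reported network.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_METHODS = ("pearson", "spearman", "mutual_information")


@dataclass
class ConsensusNetwork:
    """Perturbation nodes with consensus link intensities in [0, 1]."""

    nodes: list[str]
    intensity: pd.DataFrame
    threshold: float = 0.8
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, w in self.edges:
            g.add_edge(u, v, intensity=w)
        return g


def _binned_mi(a: np.ndarray, b: np.ndarray, n_bins: int = 8) -> float:
    """Mutual information on equal-frequency bins, normalized to [0, 1]
    by the smaller marginal entropy."""
    def discretize(v: np.ndarray) -> np.ndarray:
        edges = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(edges, v, side="right")

    xa, xb = discretize(a), discretize(b)
    joint = pd.crosstab(xa, xb).to_numpy(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    outer = np.outer(pa, pb)
    nz = joint > 0
    mi = float((joint[nz] * np.log(joint[nz] / outer[nz])).sum())
    ha = -float((pa[pa > 0] * np.log(pa[pa > 0])).sum())
    hb = -float((pb[pb > 0] * np.log(pb[pb > 0])).sum())
    denom = min(ha, hb)
    if denom <= 0:
        return 0.0
    return min(1.0, mi / denom)


def edge_scores(
    profiles: pd.DataFrame, methods=DEFAULT_METHODS, n_bins: int = 8
) -> dict[str, pd.DataFrame]:
    """Symmetric per-method similarity matrices with unit diagonal.

    ``profiles`` is features x perturbations.  Pearson and Spearman use the
    absolute correlation; mutual information uses equal-frequency binning
    normalized by the smaller marginal entropy.  A constant profile scores 0
    against everything, with a warning.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 perturbations")
    if profiles.shape[0] < 10:
        raise ValueError("need at least 10 shared features")
    unknown = set(methods) - set(DEFAULT_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    labels = list(profiles.columns)
    constant = [c for c in labels if profiles[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"constant profile(s) {constant}: similarity set to 0", stacklevel=2
        )

    out = {}
    for method in methods:
        k = len(labels)
        mat = np.eye(k)
        for i, j in itertools.combinations(range(k), 2):
            a = profiles.iloc[:, i].to_numpy(float)
            b = profiles.iloc[:, j].to_numpy(float)
            if labels[i] in constant or labels[j] in constant:
                score = 0.0
            elif method == "pearson":
                score = abs(np.corrcoef(a, b)[0, 1])
            elif method == "spearman":
                score = abs(stats.spearmanr(a, b).statistic)
            else:
                score = _binned_mi(a, b, n_bins)
            mat[i, j] = mat[j, i] = score
        out[method] = pd.DataFrame(mat, index=labels, columns=labels)
    return out


def consensus(score_matrices: dict[str, pd.DataFrame]) -> ConsensusNetwork:
    """Aggregate per-method scores into consensus link intensities.

    Off-diagonal scores of each method are replaced by fractional ranks in
    [0, 1]; intensities are the mean rank across methods, rescaled so the
    maximal off-diagonal intensity is 1.
    """
    if not score_matrices:
        raise ValueError("need at least one score matrix")
    mats = list(score_matrices.values())
    labels = list(mats[0].index)
    for m in mats[1:]:
        if list(m.index) != labels or m.shape != mats[0].shape:
            raise ValueError("score matrices have mismatched shapes or labels")

    k = len(labels)
    iu = np.triu_indices(k, 1)
    ranks = []
    for m in mats:
        vals = m.to_numpy()[iu]
        ranks.append(stats.rankdata(vals) / len(vals))
    mean_rank = np.mean(ranks, axis=0)
    if mean_rank.size and mean_rank.max() > 0:
        mean_rank = mean_rank / mean_rank.max()

    intensity = np.ones((k, k))
    intensity[iu] = mean_rank
    intensity[(iu[1], iu[0])] = mean_rank
    return ConsensusNetwork(
        nodes=labels,
        intensity=pd.DataFrame(intensity, index=labels, columns=labels),
    )


def threshold_edges(
    network: ConsensusNetwork, threshold: float = 0.8, out_dir: str | Path | None = None
) -> list[tuple[str, str, float]]:
    """Edges with intensity >= threshold, sorted descending; optional export.

    When ``out_dir`` is given, writes ``network.sif`` (tab-separated
    node/interaction/node triples) and ``network.graphml``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    labels = network.nodes
    mat = network.intensity
    edges = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        w = float(mat.iloc[i, j])
        if w >= threshold:
            edges.append((labels[i], labels[j], w))
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    network.edges = edges
    network.threshold = threshold

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "network.sif", "w") as fh:
            for u, v, _ in edges:
                fh.write(f"{u}\tlink\t{v}\n")
        nx.write_graphml(network.to_graph(), out_dir / "network.graphml")
    return edges
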