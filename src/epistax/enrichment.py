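"""Preranked gene-set enrichment: running-sum score, permutation NES and FDR.

Features are ranked by their log2 fold change; each gene set gets the classic
weighted Kolmogorov–Smirnov enrichment score (hit increments proportional to
|metric|^p, miss increments uniform), a gene-permutation null of random
same-size sets, a sign-matched normalized enrichment score and a GSEA-style
FDR q-value.  Term-reporting filters reproduce the recurrence rules used for
cross-condition summaries (minimum q gate plus |NES| recurrence thresholds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import ContrastResult

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class GeneSetCollection:
    """Named gene sets, optionally tagged with a category level."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    category_level: str | None = None

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    """Enrichment summary for one gene set against one ranked list."""

    set_name: str
    es: float
    nes: float
    p: float
    q: float
    size: int


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name, description, members...; tab-separated).

    Duplicate members within a line are stored once with a logged warning; a
    line with fewer than 3 fields is a parse error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "expected name, description and at least one member"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "set %r (line %d): %d duplicate member(s) removed",
                    name, lineno, len(members) - len(unique),
                )
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def enrichment_score(
    ranked: list[tuple[str, float]], gene_set, weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of a set along a descending ranked list.

    The running sum increments by |metric|^weight_p (normalized over set
    members) at member positions and decrements by 1/(N - set size)
    elsewhere; the score is the running-sum value of maximal absolute
    deviation from zero, signed.
    """
    if not ranked:
        raise ValueError("ranked list is empty")
    genes = [g for g, _ in ranked]
    metrics = np.array([m for _, m in ranked], float)
    members = set(gene_set)
    in_set = np.fromiter((g in members for g in genes), bool, len(genes))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set is disjoint from the ranked universe")
    if n_hit == len(genes):
        raise ValueError("gene set covers the whole ranked universe")
    weights = np.abs(metrics) ** weight_p
    running = _running_sum(weights, in_set)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _running_sum(weights: np.ndarray, in_set: np.ndarray) -> np.ndarray:
    n = weights.size
    n_hit = int(in_set.sum())
    hit_mass = weights * in_set
    denom = hit_mass.sum()
    if denom < _EPS:
        hit_mass = in_set.astype(float)
        denom = float(n_hit)
    steps = np.where(in_set, hit_mass / denom, -1.0 / (n - n_hit))
    return np.cumsum(steps)


def _es_only(weights: np.ndarray, in_set: np.ndarray) -> float:
    running = _running_sum(weights, in_set)
    return float(running[np.argmax(np.abs(running))])


def _ranked_from_contrast(contrast: ContrastResult, metric: str = "beta") -> list[tuple[str, float]]:
    df = contrast.to_frame()
    if metric == "beta":
        score = df["beta"]
    elif metric == "signed_logp":
        score = np.sign(df["beta"]) * -np.log10(np.maximum(df["p"], _EPS))
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    order = score.sort_values(ascending=False)
    return list(order.items())


def gsea_prerank(
    contrast: ContrastResult | list[tuple[str, float]],
    collection: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
    weight_p: float = 1.0,
    metric: str = "beta",
) -> list[EnrichmentResult]:
    """Preranked GSEA over a collection with a gene-permutation null.

    Per set, the null is the enrichment score of ``n_perm`` random same-size
    feature sets; NES = es / mean(|null es| of matching sign); FDR q is the
    GSEA convention — fraction of pooled null NES at least as extreme (same
    sign) divided by the fraction of observed NES at least as extreme,
    capped at 1.  Deterministic under a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = (
        _ranked_from_contrast(contrast, metric)
        if isinstance(contrast, ContrastResult)
        else sorted(contrast, key=lambda kv: kv[1], reverse=True)
    )
    universe = [g for g, _ in ranked]
    n = len(universe)
    rng = np.random.default_rng(seed)

    kept: list[tuple[str, list[str]]] = []
    for name, members in collection.sets.items():
        inside = [g for g in members if g in set(universe)]
        if not min_size <= len(inside) <= max_size:
            logger.info(
                "set %r skipped: size %d outside [%d, %d] after intersection",
                name, len(inside), min_size, max_size,
            )
            continue
        kept.append((name, inside))
    if not kept:
        return []

    weights = np.abs(np.array([m for _, m in ranked], float)) ** weight_p
    results = []
    null_nes_pool: list[np.ndarray] = []
    obs_nes = []
    for name, inside in kept:
        es, _ = enrichment_score(ranked, inside, weight_p)
        size = len(inside)
        null_es = np.empty(n_perm)
        mask = np.zeros(n, bool)
        for i in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            mask[:] = False
            mask[idx] = True
            null_es[i] = _es_only(weights, mask)
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        norm = np.abs(same_sign).mean() if same_sign.size else _EPS
        nes = es / max(norm, _EPS)
        null_nes = np.where(
            null_es >= 0,
            null_es / max(np.abs(null_es[null_es >= 0]).mean(), _EPS) if (null_es >= 0).any() else 0.0,
            null_es / max(np.abs(null_es[null_es < 0]).mean(), _EPS) if (null_es < 0).any() else 0.0,
        )
        p = float(np.mean(np.abs(same_sign) >= abs(es))) if same_sign.size else 1.0
        results.append((name, es, nes, p, size))
        null_nes_pool.append(null_nes)
        obs_nes.append(nes)

    pooled = np.concatenate(null_nes_pool)
    obs_arr = np.array(obs_nes)
    final = []
    for (name, es, nes, p, size) in results:
        if nes >= 0:
            frac_null = np.mean(pooled >= nes) if (pooled >= 0).any() else 0.0
            frac_obs = np.mean(obs_arr >= nes)
        else:
            frac_null = np.mean(pooled <= nes)
            frac_obs = np.mean(obs_arr <= nes)
        q = float(min(1.0, frac_null / max(frac_obs, _EPS)))
        final.append(EnrichmentResult(set_name=name, es=es, nes=float(nes), p=p, q=q, size=size))
    return final


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"set": r.set_name, "size": r.size, "es": r.es, "nes": r.nes, "p": r.p, "q": r.q}
         for r in results]
    ).set_index("set") if results else pd.DataFrame(columns=["size", "es", "nes", "p", "q"])


def filter_terms(
    results_by_condition: dict[str, list[EnrichmentResult]],
    nes_threshold: float = 1.5,
    min_conditions: int = 4,
    q_threshold: float = 0.05,
    dual_rule: bool = False,
) -> list[str]:
    """Cross-condition term-reporting filter.

    A term is kept when its minimum q across conditions is <= q_threshold and
    |NES| > nes_threshold in at least ``min_conditions`` conditions.  With
    ``dual_rule=True`` the recurrence clause becomes: at least 5 conditions
    with |NES| > 1.5 OR at least 6 conditions with |NES| > 1.25.
    """
    if not results_by_condition:
        raise ValueError("need at least one condition")
    per_term: dict[str, list[EnrichmentResult]] = {}
    for cond_results in results_by_condition.values():
        for r in cond_results:
            per_term.setdefault(r.set_name, []).append(r)

    kept = []
    for term, rs in per_term.items():
        if min(r.q for r in rs) > q_threshold:
            continue
        if dual_rule:
            n15 = sum(1 for r in rs if abs(r.nes) > 1.5)
            n125 = sum(1 for r in rs if abs(r.nes) > 1.25)
            if n15 >= 5 or n125 >= 6:
                kept.append(term)
        else:
            n_hit = sum(1 for r in rs if abs(r.nes) > nes_threshold)
            if n_hit >= min_conditions:
                kept.append(term)
    return sorted(kept)
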