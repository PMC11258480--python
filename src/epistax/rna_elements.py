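"""Category-level statistics for structural/functional RNA classes and splicing.

Features are aggregated per annotation category (exonic, intron-derived,
intergenic, lincRNA) as per-sample sums; group differences use a two-tailed
Welch's t test.  Splicing-event up/down counts (skipped exon, proximal 5'SS,
distal 3'SS, mutually exclusive exon, retained intron; events significant at
nominal p < 0.05 by direction) are compared with a two-tailed Fisher's exact
test against an explicit background, or a binomial 50:50 sign-test
alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = ("exonic", "intron_derived", "intergenic", "lincRNA")
EVENT_TYPES = (
    "skipped_exon",
    "proximal_5ss",
    "distal_3ss",
    "mutually_exclusive",
    "retained_intron",
)


@dataclass
class SplicingEventCounts:
    """Counts of significant splicing events by direction for one event type."""

    event_type: str
    n_up: int
    n_down: int

    def __post_init__(self) -> None:
        if self.n_up < 0 or self.n_down < 0:
            raise ValueError("event counts must be non-negative")


def aggregate_categories(expr: pd.DataFrame, annotation: dict) -> pd.DataFrame:
    """Per-sample sums of expression within each annotation category.

    ``annotation`` maps feature -> category; features without an annotation
    are ignored with a logged count, empty categories aggregate to 0 with a
    warning.  Returns categories x samples.
    """
    known = [f for f in expr.index if f in annotation]
    n_unannotated = expr.shape[0] - len(known)
    if n_unannotated:
        logger.info("%d features without annotation ignored", n_unannotated)

    out = {}
    for cat in sorted(set(annotation.values())):
        feats = [f for f in known if annotation[f] == cat]
        if not feats:
            logger.warning("category %r has no annotated features; aggregate is 0", cat)
            out[cat] = pd.Series(0.0, index=expr.columns)
        else:
            out[cat] = expr.loc[feats].sum(axis=0)
    if not out:
        return pd.DataFrame(0.0, index=[], columns=expr.columns)
    return pd.DataFrame(out).T


def welch_t(group1, group2) -> tuple[float, float, float]:
    """Two-tailed Welch's t test with Satterthwaite degrees of freedom.

    Degenerate inputs follow a documented convention: zero variance in both
    groups gives p = 1 for equal means and p = 0 otherwise.
    """
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(g1)) and np.all(np.isfinite(g2))):
        raise ValueError("groups must be finite")

    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if g1.mean() == g2.mean():
            return 0.0, float(g1.size + g2.size - 2), 1.0
        return np.inf if g1.mean() > g2.mean() else -np.inf, float(g1.size + g2.size - 2), 0.0

    res = stats.ttest_ind(g1, g2, equal_var=False)
    se2_1, se2_2 = v1 / g1.size, v2 / g2.size
    df = (se2_1 + se2_2) ** 2 / (
        se2_1**2 / (g1.size - 1) + se2_2**2 / (g2.size - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def splicing_direction_test(
    counts: SplicingEventCounts,
    background: SplicingEventCounts | None = None,
    mode: str = "fisher",
) -> float:
    """Two-sided test on up/down splicing-event counts.

    ``fisher``: Fisher's exact test on [[n_up, n_down], [bg_up, bg_down]]
    (hypergeometric enumeration, two-sided by summing table probabilities no
    larger than the observed).  ``binomial``: sign test of n_up against a
    50:50 split of n_up + n_down, needing no background.
    """
    if mode == "binomial":
        n = counts.n_up + counts.n_down
        if n == 0:
            raise ValueError("all-zero event counts")
        return float(stats.binomtest(counts.n_up, n, 0.5).pvalue)
    if mode != "fisher":
        raise ValueError(f"unknown mode {mode!r}")
    if background is None:
        raise ValueError("fisher mode requires a background")
    table = np.array(
        [[counts.n_up, counts.n_down], [background.n_up, background.n_down]], int
    )
    if table.sum() == 0:
        raise ValueError("all-zero 2x2 table")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def read_event_counts(path) -> dict[str, SplicingEventCounts]:
    """Read an event-count TSV with columns event_type, n_up, n_down."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        out[row["event_type"]] = SplicingEventCounts(
            event_type=row["event_type"], n_up=int(row["n_up"]), n_down=int(row["n_down"])
        )
    return out
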