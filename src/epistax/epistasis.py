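"""Transcriptome-wide epistasis coefficient between two perturbations.

For genotypes A, B and the double mutant AB, each feature contributes a point
(x, delta) where x = beta_a + beta_b is the expected additive log2 effect and
delta = beta_ab - x the deviation from additivity.  The epistasis coefficient
s is the slope of the through-origin orthogonal-distance regression of delta
on x.  Its regimes classify the genetic interaction: s = 0 additive,
-1/2 < s < 0 branched, s = -1/2 unbranched (single linear pathway), s = -1
repressive (double mutant reverts to wild type); masking architectures
(A > B or B > A) make the double mutant resemble one single mutant.

The observed coefficient is bootstrapped over features, and candidate
architectures are scored by how closely their simulated coefficient
distributions (built from the observed single-mutant effects) match the
observed bootstrap distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .diffexpr import ContrastResult

CANDIDATE_MODELS = ("additive", "branched", "unbranched", "repressive", "a_masks_b", "b_masks_a")


@dataclass
class EpistasisInput:
    """Selected features with their per-genotype effects and derived (x, delta)."""

    feature_ids: list[str]
    beta_a: np.ndarray
    beta_b: np.ndarray
    beta_ab: np.ndarray
    warnings: list[str] = field(default_factory=list)

    @property
    def x(self) -> np.ndarray:
        return self.beta_a + self.beta_b

    @property
    def delta(self) -> np.ndarray:
        return self.beta_ab - self.x

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class EpistasisResult:
    """Observed epistasis coefficient with bootstrap and model comparison."""

    s_hat: float
    boot: np.ndarray
    ci: tuple[float, float]
    n_features: int
    seed: int
    model_dists: dict[str, np.ndarray] = field(default_factory=dict)
    model_ranking: list[tuple[str, float]] = field(default_factory=list)
    model_overlap: dict[str, float] = field(default_factory=dict)

    @property
    def boot_mean(self) -> float:
        return float(np.mean(self.boot))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for model, score in self.model_ranking:
            rows.append(
                {
                    "model": model,
                    "score": score,
                    "mean_s": float(np.mean(self.model_dists[model])),
                    "overlap_ci": self.model_overlap.get(model, np.nan),
                }
            )
        return pd.DataFrame(rows)


def select_features(
    res_a: ContrastResult,
    res_b: ContrastResult,
    res_ab: ContrastResult,
    q_threshold: float = 0.1,
    require: str = "all",
) -> EpistasisInput:
    """Keep features with adjusted p < q_threshold in the required contrasts.

    ``require="all"`` demands significance in all three contrasts (the
    default intersection rule); ``require="singles"`` demands it only in the
    two single-mutant contrasts — needed for repressive interactions, where
    the double mutant reverts to wild type and the AB contrast is null by
    construction.  Features with non-finite betas are dropped.
    """
    if require not in ("all", "singles"):
        raise ValueError(f"unknown require mode {require!r}")
    frames = [r.to_frame() for r in (res_a, res_b, res_ab)]
    universe = frames[0].index
    for f in frames[1:]:
        if not universe.equals(f.index):
            common = universe.intersection(f.index)
            if len(common) == 0:
                raise ValueError("contrasts share no features")
            universe = common
    a, b, ab = (f.loc[universe] for f in frames)

    finite = (
        np.isfinite(a["beta"]) & np.isfinite(b["beta"]) & np.isfinite(ab["beta"])
    ).to_numpy()
    notes = []
    n_dropped = int((~finite).sum())
    if n_dropped:
        notes.append(f"dropped {n_dropped} features with non-finite betas")

    sig = (a["q"] < q_threshold) & (b["q"] < q_threshold)
    if require == "all":
        sig &= ab["q"] < q_threshold
    keep = finite & sig.to_numpy()
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError(
            f"no features pass q < {q_threshold} in the required contrasts ({require})"
        )
    if n_kept < 10:
        msg = f"only {n_kept} features selected; epistasis estimate will be unstable"
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)

    ids = [str(i) for i in universe[keep]]
    return EpistasisInput(
        feature_ids=ids,
        beta_a=a.loc[keep, "beta"].to_numpy(float),
        beta_b=b.loc[keep, "beta"].to_numpy(float),
        beta_ab=ab.loc[keep, "beta"].to_numpy(float),
        warnings=notes,
    )


def _odr_objective(m, sxx: float, syy: float, sxy: float):
    # sum (delta - m x)^2 / (1 + m^2) expanded in the sufficient statistics
    m = np.asarray(m, float)
    return (syy - 2.0 * m * sxy + m**2 * sxx) / (1.0 + m**2)


def fit_epistasis_slope(x: np.ndarray, delta: np.ndarray | None = None) -> float:
    """Slope of the through-origin orthogonal-distance regression of delta on x.

    Minimizes sum_i (delta_i - m x_i)^2 / (1 + m^2).  Stationary slopes solve
    the quadratic m^2 Sxy + m (Sxx - Syy) - Sxy = 0 with Sxx = sum x^2,
    Syy = sum delta^2, Sxy = sum x delta; of the two roots the one with the
    smaller objective is returned (ties toward smaller |m|).  When Sxy = 0
    the quadratic degenerates and a dense grid search is used instead.

    Accepts either (x, delta) vectors or a single ``EpistasisInput``.
    """
    if delta is None:
        inp = x
        x, delta = inp.x, inp.delta
    x = np.asarray(x, float)
    delta = np.asarray(delta, float)
    if x.size < 2:
        raise ValueError("need at least 2 features")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all x are zero; epistasis slope undefined")
    syy = float(np.dot(delta, delta))
    sxy = float(np.dot(x, delta))

    if syy == 0.0:
        return 0.0  # all points on the x-axis: perfectly additive
    if sxy == 0.0:
        grid = np.arange(-5.0, 5.0 + 1e-9, 1e-4)
        return float(grid[np.argmin(_odr_objective(grid, sxx, syy, sxy))])

    disc = np.sqrt((sxx - syy) ** 2 + 4.0 * sxy**2)
    roots = np.array([(syy - sxx + disc) / (2.0 * sxy), (syy - sxx - disc) / (2.0 * sxy)])
    obj = _odr_objective(roots, sxx, syy, sxy)
    best = np.flatnonzero(np.isclose(obj, obj.min(), rtol=1e-12, atol=1e-12))
    if len(best) > 1:
        return float(roots[best[np.argmin(np.abs(roots[best]))]])
    return float(roots[np.argmin(obj)])


def _resampled_slopes(
    n_boot: int,
    rng: np.random.Generator,
    x: np.ndarray,
    delta_of: callable,
    max_redraw: int = 10,
) -> np.ndarray:
    """Bootstrap feature indices and refit the slope; redraw degenerate resamples."""
    n = x.size
    out = []
    for _ in range(n_boot):
        for _attempt in range(max_redraw):
            idx = rng.integers(0, n, size=n)
            xb = x[idx]
            if np.dot(xb, xb) > 0:
                out.append(fit_epistasis_slope(xb, delta_of(idx)))
                break
    return np.asarray(out)


def bootstrap_epistasis(
    inp: EpistasisInput, n_boot: int = 5000, seed: int = 0
) -> EpistasisResult:
    """Empirical bootstrap of the epistasis slope over features.

    Features are resampled with replacement ``n_boot`` times and the slope is
    refit on each resample; the reported central value is the bootstrap mean
    and the CI the (2.5, 97.5) percentile interval.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    x, delta = inp.x, inp.delta
    s_hat = fit_epistasis_slope(x, delta)
    boot = _resampled_slopes(n_boot, rng, x, lambda idx: delta[idx])
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return EpistasisResult(
        s_hat=s_hat, boot=boot, ci=ci, n_features=inp.n_features, seed=seed
    )


def simulate_model_distributions(
    inp: EpistasisInput, n_boot: int = 5000, seed: int = 0
) -> dict[str, np.ndarray]:
    """Predicted slope distributions under each candidate architecture.

    Pseudo-data keep the observed single-mutant betas (pairing preserved,
    features resampled with replacement) and replace beta_ab by the model's
    composition: additive a+b, a_masks_b a, b_masks_a b, unbranched the
    per-feature mean of a and b, repressive 0, branched a + c*b with the
    attenuation c fit to the observed double-mutant effects by least squares
    and clipped to [0.1, 0.9] (the interior of the branched regime, so the
    composite family never collapses onto additive or masking).  Each
    resample is refit, giving ``n_boot`` slopes per model.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    a, b = inp.beta_a, inp.beta_b
    x = a + b
    sbb = float(np.dot(b, b))
    c_hat = float(np.dot(inp.beta_ab - a, b) / sbb) if sbb > 0 else 0.5
    c_hat = float(np.clip(c_hat, 0.1, 0.9))
    compositions = {
        "additive": lambda idx: np.zeros(idx.size),          # delta = (a+b) - x = 0
        "a_masks_b": lambda idx: -b[idx],                    # delta = a - x = -b
        "b_masks_a": lambda idx: -a[idx],                    # delta = b - x = -a
        "unbranched": lambda idx: (a[idx] + b[idx]) / 2.0 - x[idx],
        "repressive": lambda idx: -x[idx],
        "branched": lambda idx: (c_hat - 1.0) * b[idx],      # ab = a + c*b
    }
    # Common random numbers: every model reuses the same resampling stream as
    # bootstrap_epistasis, so model-vs-observed score differences reflect the
    # compositions, not Monte Carlo noise.
    dists: dict[str, np.ndarray] = {}
    for model in CANDIDATE_MODELS:
        rng = np.random.default_rng(seed)
        dists[model] = _resampled_slopes(n_boot, rng, x, compositions[model])
    return dists


def classify_interaction(
    observed: EpistasisResult, model_dists: dict[str, np.ndarray]
) -> EpistasisResult:
    """Rank candidate architectures against the observed bootstrap distribution.

    Each model is scored by the absolute difference between its mean simulated
    slope and the mean observed bootstrap slope (ascending); the fraction of
    model draws inside the observed 95% CI is reported alongside.
    """
    if not model_dists:
        raise ValueError("model_dists must be nonempty")
    obs_mean = observed.boot_mean
    lo, hi = observed.ci
    scores = {m: float(abs(np.mean(d) - obs_mean)) for m, d in model_dists.items()}
    overlap = {
        m: float(np.mean((d >= lo) & (d <= hi))) for m, d in model_dists.items()
    }
    ranking = sorted(scores.items(), key=lambda kv: kv[1])
    observed.model_dists = model_dists
    observed.model_ranking = ranking
    observed.model_overlap = overlap
    return observed


class EpistasisAnalysis(BaseEstimator):
    """Estimator computing the epistasis coefficient and model classification.

    Parameters
    ----------
    q_threshold : float, default 0.1
        Adjusted-p selection threshold applied to all three contrasts when
        fitting from ``ContrastResult`` objects.
    n_boot : int, default 5000
        Bootstrap replicates for the observed slope and each model.
    seed : int, default 0
        Seed for all resampling.

    Attributes
    ----------
    s_hat_ : float
        Observed through-origin orthogonal slope of delta on x.
    boot_mean_ : float
        Mean of the bootstrap slope distribution (the reported coefficient).
    ci_ : tuple of float
        Percentile (2.5, 97.5) bootstrap interval.
    result_ : EpistasisResult
        Full result including model distributions and ranking.
    best_model_ : str
        Top-ranked candidate architecture.
    """

    def __init__(self, q_threshold: float = 0.1, n_boot: int = 5000, seed: int = 0):
        self.q_threshold = q_threshold
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y=None):
        """Fit from an (n_features, 3) array of [beta_a, beta_b, beta_ab],
        an ``EpistasisInput``, or a 3-tuple of ``ContrastResult`` objects."""
        if isinstance(X, EpistasisInput):
            inp = X
        elif isinstance(X, (tuple, list)) and len(X) == 3 and isinstance(X[0], ContrastResult):
            try:
                inp = select_features(*X, q_threshold=self.q_threshold)
            except ValueError:
                # repressive interactions null the AB contrast by construction;
                # fall back to requiring only the single-mutant contrasts
                inp = select_features(*X, q_threshold=self.q_threshold, require="singles")
                inp.warnings.append(
                    "triple-contrast selection was empty; kept features "
                    "significant in both single-mutant contrasts only"
                )
        else:
            arr = np.asarray(X, float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError("X must be (n_features, 3): beta_a, beta_b, beta_ab")
            inp = EpistasisInput(
                feature_ids=[f"f{i}" for i in range(arr.shape[0])],
                beta_a=arr[:, 0], beta_b=arr[:, 1], beta_ab=arr[:, 2],
            )
        res = bootstrap_epistasis(inp, n_boot=self.n_boot, seed=self.seed)
        dists = simulate_model_distributions(inp, n_boot=self.n_boot, seed=self.seed)
        res = classify_interaction(res, dists)
        self.input_ = inp
        self.result_ = res
        self.s_hat_ = res.s_hat
        self.boot_mean_ = res.boot_mean
        self.ci_ = res.ci
        self.best_model_ = res.model_ranking[0][0]
        return self
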