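"""Synthetic genotype-design RNA-seq data under specified interaction architectures.

Generates per-genotype log2 effect vectors (wild type, single mutants A and B,
double mutant AB) composed according to a genetic-interaction architecture, and
negative-binomial count matrices with configurable biological coefficient of
variation, library-size variation and optional multiplicative batch factors.
Every downstream stage of the pipeline is testable against these without any
external sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MODEL_NAMES = (
    "additive",
    "branched",
    "unbranched",
    "repressive",
    "a_masks_b",
    "b_masks_a",
)

GENOTYPES = ("WT", "A", "B", "AB")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class InteractionModel:
    """A genetic-interaction architecture for composing double-mutant effects.

    Parameters
    ----------
    name:
        One of ``additive``, ``branched``, ``unbranched``, ``repressive``,
        ``a_masks_b``, ``b_masks_a``.  The name fixes how the double-mutant
        log2 effect ``beta_ab`` is composed from the single-mutant effects.
    correlation:
        Correlation between the two single-mutant effect vectors, in [-1, 1].
        ``unbranched`` ignores it (the vectors are forced identical); the
        ``branched`` preset uses 1.0 so that the attenuated composition stays
        inside the branched slope regime (-1/2, 0).
    noise_sd:
        Standard deviation (log2 units) of Gaussian noise added independently
        to each of the three effect vectors.
    """

    name: str
    correlation: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ConfigurationError(
                f"unknown interaction model {self.name!r}; expected one of {MODEL_NAMES}"
            )
        if not -1.0 <= self.correlation <= 1.0:
            raise ConfigurationError("correlation must be in [-1, 1]")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be finite and >= 0")

    @classmethod
    def preset(cls, name: str, noise_sd: float = 0.0) -> "InteractionModel":
        """Architecture with its conventional single-mutant correlation.

        ``branched`` uses fully correlated single-mutant vectors (a shared
        linear pathway with a partially attenuated second step), which keeps
        the analytic epistasis slope strictly inside (-1/2, 0); all other
        architectures default to independent single-mutant effects.
        """
        corr = 1.0 if name == "branched" else 0.0
        return cls(name=name, correlation=corr, noise_sd=noise_sd)


@dataclass
class TrueEffects:
    """Ground-truth per-genotype log2 effect vectors for a feature panel."""

    feature_ids: list[str]
    beta_a: np.ndarray
    beta_b: np.ndarray
    beta_ab: np.ndarray
    model: InteractionModel
    seed: int

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        for name in ("beta_a", "beta_b", "beta_ab"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, vec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta_a": self.beta_a, "beta_b": self.beta_b, "beta_ab": self.beta_ab},
            index=pd.Index(self.feature_ids, name="feature"),
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class CountMatrix:
    """Integer count matrix (features x samples) with genotype design metadata.

    ``sample_meta`` carries one row per sample with columns ``genotype``
    (WT/A/B/AB), ``replicate`` and ``batch``.  ``bcv`` squared equals the
    negative-binomial dispersion used at generation.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    baseline_mean: np.ndarray | None = None
    bcv: float | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.sample_meta.index) ^ set(self.counts.columns)
        if missing:
            raise ValueError(f"sample_meta and counts disagree on samples: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    def samples_for(self, genotype: str) -> list[str]:
        mask = self.sample_meta["genotype"] == genotype
        return list(self.sample_meta.index[mask])

    def write_tsv(self, counts_path: str | Path, meta_path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "feature"
        out.to_csv(counts_path, sep="\t")
        meta = self.sample_meta.copy()
        meta.index.name = "sample"
        meta.to_csv(meta_path, sep="\t")

    @classmethod
    def read_tsv(cls, counts_path: str | Path, meta_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts=counts, sample_meta=meta)


def simulate_effects(
    model: InteractionModel,
    n_features: int,
    effect_sd: float,
    frac_nonnull: float = 1.0,
    seed: int = 0,
) -> TrueEffects:
    """Draw per-genotype log2 effect vectors under an interaction architecture.

    Non-null features draw ``beta_a ~ Normal(0, effect_sd^2)``; ``beta_b`` is
    correlated with ``beta_a`` according to ``model.correlation``; ``beta_ab``
    is composed per architecture:

    - additive:   beta_a + beta_b
    - unbranched: beta_ab = beta_b = beta_a (single linear pathway)
    - repressive: 0 (double mutant reverts to wild type)
    - a_masks_b:  beta_a
    - b_masks_a:  beta_b
    - branched:   beta_a + c * beta_b with attenuation c drawn once from
      Uniform(0.1, 0.9)

    Gaussian noise of sd ``model.noise_sd`` is then added independently to all
    three vectors.  Null features have all three betas equal to noise only.
    """
    if n_features < 2:
        raise ValueError("n_features must be >= 2")
    if effect_sd <= 0:
        raise ValueError("effect_sd must be > 0")
    if not 0 < frac_nonnull <= 1:
        raise ConfigurationError("frac_nonnull must be in (0, 1]")

    rng = np.random.default_rng(seed)
    n_nonnull = max(1, int(round(frac_nonnull * n_features)))

    beta_a = np.zeros(n_features)
    beta_b = np.zeros(n_features)
    beta_ab = np.zeros(n_features)

    a = rng.normal(0.0, effect_sd, size=n_nonnull)
    rho = model.correlation
    b = rho * a + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(0.0, effect_sd, size=n_nonnull)

    if model.name == "unbranched":
        b = a.copy()
        ab = a.copy()
    elif model.name == "additive":
        ab = a + b
    elif model.name == "repressive":
        ab = np.zeros(n_nonnull)
    elif model.name == "a_masks_b":
        ab = a.copy()
    elif model.name == "b_masks_a":
        ab = b.copy()
    else:  # branched
        attenuation = rng.uniform(0.1, 0.9)
        ab = a + attenuation * b

    beta_a[:n_nonnull] = a
    beta_b[:n_nonnull] = b
    beta_ab[:n_nonnull] = ab

    if model.noise_sd > 0:
        beta_a += rng.normal(0.0, model.noise_sd, size=n_features)
        beta_b += rng.normal(0.0, model.noise_sd, size=n_features)
        beta_ab += rng.normal(0.0, model.noise_sd, size=n_features)

    ids = [f"g{i:05d}" for i in range(n_features)]
    return TrueEffects(
        feature_ids=ids, beta_a=beta_a, beta_b=beta_b, beta_ab=beta_ab, model=model, seed=seed
    )


def simulate_counts(
    effects: TrueEffects,
    n_reps: int = 3,
    depth_mean: float = 200.0,
    bcv: float = 0.1,
    batch_sd: float = 0.0,
    seed: int = 0,
    library_sd: float = 0.2,
    baseline_log_sd: float = 1.0,
) -> CountMatrix:
    """Generate negative-binomial counts for the WT/A/B/AB genotype design.

    The wild-type mean of each feature is drawn from a log-normal with median
    ``depth_mean`` and log-sd ``baseline_log_sd``; genotype g scales it by
    ``2**beta_g``, a per-sample log-normal library factor (sd ``library_sd``)
    and, for the second half of the replicates of every genotype, a shared
    log-normal batch factor (sd ``batch_sd``).  Counts are NB with variance
    ``mu + bcv^2 * mu^2`` (Poisson when ``bcv=0``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    if bcv < 0:
        raise ValueError("bcv must be >= 0")

    rng = np.random.default_rng(seed)
    n = len(effects.feature_ids)
    baseline = depth_mean * np.exp(rng.normal(0.0, baseline_log_sd, size=n) - baseline_log_sd**2 / 2)

    betas = {
        "WT": np.zeros(n),
        "A": effects.beta_a,
        "B": effects.beta_b,
        "AB": effects.beta_ab,
    }

    # batch 1 = second half of replicates of every genotype, when batch_sd > 0.
    # The loading is per feature (drawn once), so the batch effect is a rank-1
    # structure in log space rather than a pure library-size shift that
    # normalization would already absorb.
    if batch_sd > 0:
        batch_factor = np.exp(rng.normal(0.0, batch_sd, size=n))
    else:
        batch_factor = np.ones(n)

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for genotype in GENOTYPES:
        for rep in range(1, n_reps + 1):
            in_batch = batch_sd > 0 and rep > n_reps // 2 and n_reps > 1
            lib = np.exp(rng.normal(0.0, library_sd)) if library_sd > 0 else 1.0
            mu = baseline * 2.0 ** betas[genotype] * lib * (batch_factor if in_batch else 1.0)
            if bcv == 0:
                counts = rng.poisson(mu)
            else:
                # NB as Poisson-gamma mixture: shape 1/bcv^2 gives var mu + bcv^2 mu^2
                shape = 1.0 / bcv**2
                lam = rng.gamma(shape, mu / shape)
                counts = rng.poisson(lam)
            sample = f"{genotype}_r{rep}"
            columns[sample] = counts
            meta_rows.append(
                {"sample": sample, "genotype": genotype, "replicate": rep,
                 "batch": "b1" if in_batch else "b0"}
            )

    counts_df = pd.DataFrame(columns, index=pd.Index(effects.feature_ids, name="feature"))
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CountMatrix(counts=counts_df, sample_meta=meta, baseline_mean=baseline, bcv=bcv)
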