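"""Synthetic connectome features and phenotypes with planted effects.

Stands in for access-restricted consortium data: generates subjects-by-edges
feature tables shaped like structural connectomes and continuous phenotypes
whose predictable variance is controlled exactly, so the resampling engine
and the theory module can be validated against a known ground truth.

The phenotype is built as

    y = rho * z(X w) + confound_weight * z(c) + sqrt(1 - rho^2) * eps,

with ``rho = sqrt(true_r2 * reliability)``: ``true_r2`` is the fraction of
phenotype variance explained by the optimal linear readout ``X w`` of the
features, and ``reliability`` attenuates it the way imperfect test-retest
reliability caps the achievable effect size (trait-like targets high,
state-like low).  ``c`` is a positive, TIV-like per-subject scalar that can
be injected into both the features and the phenotype to emulate a
confounder.  With ``confound_weight = 0`` the population correlation of the
oracle predictor ``X w`` with ``y`` is exactly ``rho``; with a nonzero
confound weight it is inflated slightly because the confounder enters both
sides — which is precisely the bias the knob exists to exercise.

Connectome edges are strongly inter-correlated in real data (shared
anatomical factors: head size, global connectivity, community structure),
which is what lets a ridge model at a few hundred training subjects recover
a sizable fraction of the oracle correlation.  The generator therefore
builds edges from ``n_latent`` shared factors plus idiosyncratic noise
(``latent_share`` of each edge's variance is factor-driven).  All
distributional choices (lognormal edge weights, per-edge presence
probabilities, factor counts) are plausibility stand-ins, not a fit to any
real dataset's marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable, edge_labels_for_nodes

__all__ = ["SyntheticConfig", "PlantedPhenotype", "generate_features", "generate_phenotype"]

FEATURE_MODELS = ("sparse-lognormal", "dense-gaussian")

# child-stream indices off the config seed, so features and phenotype can be
# generated independently yet consistently
_STREAM_FEATURES = 0
_STREAM_CONFOUND = 1
_STREAM_SIGNAL = 2
_STREAM_NOISE = 3


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of one synthetic dataset.

    Parameters
    ----------
    n_subjects
        Number of subjects (rows).
    n_nodes
        Atlas size; features are the n_nodes*(n_nodes-1)/2 unique edges
        (default 84, a Desikan-Killiany-sized parcellation -> 3486 edges).
    true_r2
        Population fraction of phenotype variance explained by the optimal
        linear readout of the features, in [0, 1).
    reliability
        Test-retest attenuation multiplying the signal variance, in (0, 1];
        1 for a perfectly stable trait, lower for state-like targets.
    confound_weight
        Strength of the TIV-like scalar entering both features and target.
    feature_model
        ``"sparse-lognormal"`` (nonnegative, right-skewed, streamline-count
        like; default) or ``"dense-gaussian"`` (standardized, FA-like).
    n_informative
        Number of edges carrying signal; default 10% of the edge count
        (at least 1).
    n_latent
        Number of shared latent factors generating inter-edge correlation.
    latent_share
        Fraction of each edge's variance driven by the latent factors,
        in [0, 1); 0 gives independent edges.
    """

    n_subjects: int
    n_nodes: int = 84
    true_r2: float = 0.0
    reliability: float = 1.0
    confound_weight: float = 0.0
    feature_model: str = "sparse-lognormal"
    n_informative: int | None = None
    n_latent: int = 6
    latent_share: float = 0.92
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_nodes < 2:
            raise InvalidConfigError("need n_subjects >= 2 and n_nodes >= 2")
        if not 0.0 <= self.true_r2 < 1.0:
            raise InvalidConfigError("true_r2 must lie in [0, 1)")
        if not 0.0 < self.reliability <= 1.0:
            raise InvalidConfigError("reliability must lie in (0, 1]")
        if self.true_r2 * self.reliability >= 1.0:
            raise InvalidConfigError("true_r2 * reliability must be < 1")
        if self.confound_weight < 0.0:
            raise InvalidConfigError("confound_weight must be nonnegative")
        if self.feature_model not in FEATURE_MODELS:
            raise InvalidConfigError(f"feature_model must be one of {FEATURE_MODELS}")
        if self.n_informative is not None and not (
            1 <= self.n_informative <= self.n_edges
        ):
            raise InvalidConfigError(
                f"n_informative must lie in [1, {self.n_edges}]"
            )
        if self.n_latent < 1:
            raise InvalidConfigError("n_latent must be >= 1")
        if not 0.0 <= self.latent_share < 1.0:
            raise InvalidConfigError("latent_share must lie in [0, 1)")

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def effective_n_informative(self) -> int:
        if self.n_informative is not None:
            return self.n_informative
        return max(1, self.n_edges // 10)

    @property
    def oracle_r(self) -> float:
        """Population correlation of the oracle predictor with the target."""
        return float(np.sqrt(self.true_r2 * self.reliability))


@dataclass
class PlantedPhenotype:
    """A generated target with its planted ground truth."""

    y: np.ndarray
    weights: np.ndarray = field(repr=False)
    confounder: np.ndarray = field(repr=False)
    informative_edges: np.ndarray = field(repr=False)
    oracle_r: float = 0.0


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stream,))
    )


def _confounder(config: SyntheticConfig) -> np.ndarray:
    rng = _rng(config, _STREAM_CONFOUND)
    return rng.lognormal(mean=0.0, sigma=0.2, size=config.n_subjects)


def generate_features(config: SyntheticConfig) -> FeatureTable:
    """Connectome-like feature table for the given configuration.

    Deterministic under the config seed.  The sparse-lognormal model keeps
    ~70% of edges (anatomically present across the cohort) and gives them
    lognormal weights, yielding nonnegative right-skewed columns with
    structural zeros; dense-gaussian gives standardized columns.  Both
    share the latent-factor correlation structure.
    """
    rng = _rng(config, _STREAM_FEATURES)
    n, E = config.n_subjects, config.n_edges
    # correlated edge scores: latent factors + idiosyncratic noise, unit variance
    loadings = rng.standard_normal((config.n_latent, E))
    loadings /= np.linalg.norm(loadings, axis=0, keepdims=True)
    factors = rng.standard_normal((n, config.n_latent))
    scores = np.sqrt(config.latent_share) * (factors @ loadings) + np.sqrt(
        1.0 - config.latent_share
    ) * rng.standard_normal((n, E))
    if config.feature_model == "dense-gaussian":
        values = scores
    else:
        # structural sparsity: an edge is anatomically present or absent for
        # the whole cohort; present edges carry lognormal weights
        edge_mu = rng.normal(0.0, 1.0, size=E)
        present = rng.random(E) < 0.7
        values = present[None, :] * np.exp(edge_mu + 0.5 * scores)
    if config.confound_weight > 0.0:
        c = _confounder(config)
        sel = _rng(config, _STREAM_SIGNAL)  # same stream as signal placement
        confounded = sel.permutation(E)[: max(1, E // 2)]
        values[:, confounded] += config.confound_weight * c[:, None]
    labels = edge_labels_for_nodes([f"n{k + 1:03d}" for k in range(config.n_nodes)])
    ids = np.array([f"sub-{k + 1:04d}" for k in range(n)], dtype=object)
    return FeatureTable(ids, labels, values)


def generate_phenotype(
    features: FeatureTable, config: SyntheticConfig
) -> PlantedPhenotype:
    """Phenotype with planted signal, confound and noise for ``features``.

    The returned weights form the oracle predictor: as n grows,
    ``corr(X @ weights, y)`` converges to ``sqrt(true_r2 * reliability)``
    (exactly, when ``confound_weight`` is 0).
    """
    if features.n_subjects != config.n_subjects or features.n_edges != config.n_edges:
        raise ValueError("features were not generated from this configuration")
    n, E = config.n_subjects, config.n_edges
    rho = config.oracle_r

    sel = _rng(config, _STREAM_SIGNAL)
    informative = np.sort(sel.permutation(E)[: config.effective_n_informative])
    w = np.zeros(E)
    w[informative] = sel.standard_normal(len(informative))

    noise_rng = _rng(config, _STREAM_NOISE)
    eps = noise_rng.standard_normal(n)
    c = _confounder(config)

    signal = features.values @ w
    sd = signal.std()
    z_signal = (signal - signal.mean()) / sd if sd > 0 else np.zeros(n)
    z_conf = (c - c.mean()) / c.std()
    y = (
        rho * z_signal
        + config.confound_weight * z_conf
        + np.sqrt(1.0 - rho**2) * eps
    )
    return PlantedPhenotype(y, w, c, informative, oracle_r=rho)


def write_sidecar(config: SyntheticConfig, planted: PlantedPhenotype, path) -> None:
    """Key-value text file recording the config and planted truth."""
    lines = [f"{k} = {v}" for k, v in vars(config).items()]
    lines.append(f"oracle_r = {planted.oracle_r}")
    lines.append(f"n_informative_effective = {len(planted.informative_edges)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
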