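"""Effect-size-driven theoretical replication probability.

The probability that an independent, equally sized replication sample yields
a significant prediction-outcome correlation is computed in the Killeen
p_rep tradition: the replication t statistic, given the observed discovery
t, follows a K-prime distribution

    t_rep / sqrt(2)  ~  K'_{v,v}(t_obs / sqrt(2)),

where ``v = n - 2`` and the sqrt(2) scaling reflects that discovery and
replication each contribute one sample's worth of estimation noise.  The
K-prime distribution K'_{v1,v2}(ncp) is a noncentral-t variate with v2
degrees of freedom whose noncentrality parameter is itself scaled by an
independent chi_{v1}/sqrt(v1) factor; it is the predictive distribution of
a future t statistic when the underlying effect is unknown.

P_srep(alpha) = Pr(t_rep > T_alpha | t_obs) then gives the probability of
significant replication at level alpha, and inverting it over n yields the
sample size required to reach a target replication probability for a given
Pearson correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "EffectSize",
    "TheoreticalEstimate",
    "t_from_r",
    "kprime_survival",
    "p_srep",
    "theoretical_n",
    "compare_empirical_theoretical",
]

#: sentinel meaning "target probability not reached within n_max"
NOT_REACHED = None


@dataclass(frozen=True)
class EffectSize:
    """A Pearson correlation with its sample size and derived t statistic."""

    r: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 < self.r < 1.0:
            raise ValueError(f"correlation must lie in (-1, 1), got {self.r}")
        if self.n < 3:
            raise ValueError(f"sample size must be >= 3, got {self.n}")

    @property
    def df(self) -> int:
        return self.n - 2

    @property
    def t_obs(self) -> float:
        return t_from_r(self.r, self.n)


@dataclass(frozen=True)
class TheoreticalEstimate:
    """Required sample size for a target significant-replication probability.

    ``n_required`` is None when the target probability is not reached by
    ``n_max``.
    """

    r: float
    alpha: float
    target_prob: float
    n_required: int | None
    p_srep_at_n: float | None
    n_max: int
    sided: str


def t_from_r(r: float, n: int) -> float:
    """t statistic of a Pearson correlation r observed on n pairs.

    t = r * sqrt((n - 2) / (1 - r^2)), with n - 2 degrees of freedom.
    """
    if not -1.0 < r < 1.0:
        raise ValueError(f"correlation must lie in (-1, 1), got {r}")
    if n < 3:
        raise ValueError(f"sample size must be >= 3, got {n}")
    return r * math.sqrt((n - 2) / (1.0 - r * r))


def _chi_mixing(v1: float):
    # distribution of chi_{v1}/sqrt(v1), the factor scaling the noncentrality
    return stats.chi(v1, scale=1.0 / math.sqrt(v1))


def kprime_survival(
    q: float,
    v1: float,
    v2: float,
    ncp: float,
    method: str = "quadrature",
    n_draws: int = 200_000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Survival function Pr(K'_{v1,v2}(ncp) > q) of the K-prime distribution.

    K'_{v1,v2}(ncp) is distributed as a noncentral-t variate with ``v2``
    degrees of freedom whose noncentrality is ``ncp * Q`` with
    ``Q = chi_{v1} / sqrt(v1)`` drawn independently.

    Parameters
    ----------
    q
        Threshold; ``-inf`` returns 1, ``+inf`` returns 0.
    v1, v2
        Degrees of freedom of the chi mixing factor and of the noncentral t.
    ncp
        Noncentrality before chi scaling.
    method
        ``"quadrature"`` (default, deterministic) integrates the
        noncentral-t survival over the chi density; ``"montecarlo"``
        averages over ``n_draws`` seeded draws and serves as an
        independent cross-check.
    """
    if v1 < 1 or v2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if not (np.isfinite(ncp)):
        raise ValueError("noncentrality must be finite")
    if np.isneginf(q):
        return 1.0
    if np.isposinf(q):
        return 0.0
    if not np.isfinite(q):
        raise ValueError("threshold q must be finite or infinite, not NaN")

    mixing = _chi_mixing(v1)
    if method == "quadrature":
        lo, hi = mixing.ppf(1e-12), mixing.ppf(1.0 - 1e-12)
        val, _ = integrate.quad(
            lambda x: mixing.pdf(x) * stats.nct.sf(q, v2, ncp * x),
            lo,
            hi,
            limit=200,
        )
        return min(1.0, max(0.0, val))
    if method == "montecarlo":
        gen = np.random.default_rng(rng)
        scale = mixing.rvs(size=n_draws, random_state=gen)
        z = gen.standard_normal(n_draws)
        denom = np.sqrt(gen.chisquare(v2, size=n_draws) / v2)
        draws = (z + ncp * scale) / denom
        return float(np.mean(draws > q))
    raise ValueError(f"unknown method {method!r}")


def _critical_t(alpha: float, df: float, sided: str) -> float:
    if sided == "one":
        return float(stats.t.ppf(1.0 - alpha, df))
    if sided == "two":
        return float(stats.t.ppf(1.0 - alpha / 2.0, df))
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def p_srep(
    r: float,
    n: int,
    alpha: float = 0.05,
    sided: str = "two",
    critical_df: int | None = None,
    method: str = "quadrature",
    rng: np.random.Generator | int | None = None,
) -> float:
    """Probability of significant replication of correlation r at size n.

    Evaluates Pr(K'_{v,v}(t_obs/sqrt(2)) > T_alpha/sqrt(2)) with v = n - 2,
    t_obs = t_from_r(r, n) and T_alpha the critical t at level ``alpha``.

    ``critical_df`` overrides the degrees of freedom used for T_alpha (by
    default the replication test's own df, n - 2); fixing it at a large
    reference size reproduces published worked examples computed with a
    single reference critical value.
    """
    if n < 4:
        raise ValueError("p_srep needs n >= 4 (df >= 2)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    v = n - 2
    t_obs = t_from_r(r, n)
    t_crit = _critical_t(alpha, critical_df if critical_df is not None else v, sided)
    return kprime_survival(
        t_crit / math.sqrt(2.0),
        v,
        v,
        t_obs / math.sqrt(2.0),
        method=method,
        rng=rng,
    )


def theoretical_n(
    r: float,
    alpha: float = 0.05,
    target_prob: float = 0.8,
    n_max: int = 1000,
    sided: str = "two",
    critical_df: int | None = None,
) -> TheoreticalEstimate:
    """Smallest n at which p_srep(r, n, alpha) reaches ``target_prob``.

    Scans n in [4, n_max] exploiting the monotonicity of p_srep in n for
    fixed r > 0 (bisection); returns a sentinel estimate with
    ``n_required=None`` if the target is not reached by ``n_max`` (always
    the case for r <= 0).
    """
    if not 0.0 < target_prob < 1.0:
        raise ValueError("target_prob must lie in (0, 1)")

    def reached(n: int) -> bool:
        return p_srep(r, n, alpha, sided=sided, critical_df=critical_df) >= target_prob

    if r <= 0.0 or not reached(n_max):
        return TheoreticalEstimate(r, alpha, target_prob, None, None, n_max, sided)
    lo, hi = 4, n_max
    while lo < hi:
        mid = (lo + hi) // 2
        if reached(mid):
            hi = mid
        else:
            lo = mid + 1
    return TheoreticalEstimate(
        r,
        alpha,
        target_prob,
        lo,
        p_srep(r, lo, alpha, sided=sided, critical_df=critical_df),
        n_max,
        sided,
    )


def compare_empirical_theoretical(pairs) -> tuple[float, "pd.DataFrame"]:
    """Correlate empirical minimum replicable sizes with theoretical ones.

    Parameters
    ----------
    pairs
        Iterable of ``(n_empirical, n_theoretical)``; entries with a None
        or non-finite member are dropped.

    Returns
    -------
    (r, table)
        Pearson correlation across the finite pairs and a DataFrame with
        columns ``n_empirical``/``n_theoretical``.
    """
    import pandas as pd

    clean = [
        (float(a), float(b))
        for a, b in pairs
        if a is not None and b is not None and np.isfinite(a) and np.isfinite(b)
    ]
    if len(clean) < 3:
        raise ValueError(
            f"need >= 3 finite (n_empirical, n_theoretical) pairs, got {len(clean)}"
        )
    table = pd.DataFrame(clean, columns=["n_empirical", "n_theoretical"])
    r = float(stats.pearsonr(table["n_empirical"], table["n_theoretical"])[0])
    return r, table
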