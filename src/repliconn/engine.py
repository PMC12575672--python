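"""Split-resample estimation of replication probability.

For each sample size n on a grid, the dataset is repeatedly split into
disjoint, equally sized discovery and replication samples (uniformly at
random, no matching or stratification).  Each draw trains a nested-CV ridge
on the discovery half, evaluates the refit model on the replication half,
and records both effect sizes and p-values.  The replication probability
at n is the fraction of draws significant in the replication half among
those significant in discovery:

    P_replicability = #{p_rep < alpha and p_dis < alpha} / #{p_dis < alpha}

and the minimum replicable sample size n_E is the smallest grid n at which
this probability strictly exceeds the threshold (0.8 by default).
"""

from __future__ import annotations

import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DEFAULT_ALPHA_GRID, fit_nested_cv, refit_and_evaluate

__all__ = [
    "DEFAULT_GRID",
    "ShuffleRecord",
    "PReplicability",
    "ReplicationCurve",
    "UnionReplicability",
    "draw_split",
    "estimate_p_replicability",
    "run_curve",
    "min_replicable_n",
    "union_replicability",
    "summarize_effects",
]

logger = logging.getLogger(__name__)

#: per-half sample sizes 25..425 in steps of 25
DEFAULT_GRID: tuple[int, ...] = tuple(range(25, 426, 25))

RECORD_COLUMNS = [
    "phenotype",
    "metric",
    "n",
    "shuffle",
    "r_dis",
    "p_dis",
    "r_rep",
    "p_rep",
    "selected_alpha",
]


@dataclass
class ShuffleRecord:
    """One discovery/replication draw at per-half size n."""

    shuffle_index: int
    n: int
    discovery_ids: np.ndarray = field(repr=False)
    replication_ids: np.ndarray = field(repr=False)
    r_dis: float = float("nan")
    p_dis: float = 1.0
    r_rep: float = float("nan")
    p_rep: float = 1.0
    selected_alpha: float = float("nan")


@dataclass
class PReplicability:
    """P_replicability estimate with its denominator diagnostics.

    ``value`` is None (undefined) when no draw was discovery-significant —
    deliberately distinct from 0, which would mean "discovered but never
    replicated".
    """

    value: float | None
    n_discovery_significant: int
    n_records: int
    low_confidence: bool


@dataclass
class ReplicationCurve:
    """Replicability as a function of per-half sample size, one phenotype."""

    phenotype: str
    metric: str
    grid: tuple[int, ...]
    alpha: float
    records: list[ShuffleRecord] = field(repr=False)
    p_replicability: dict[int, PReplicability] = field(repr=False, default_factory=dict)

    def records_at(self, n: int) -> list[ShuffleRecord]:
        return [rec for rec in self.records if rec.n == n]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "phenotype": self.phenotype,
                "metric": self.metric,
                "n": rec.n,
                "shuffle": rec.shuffle_index,
                "r_dis": rec.r_dis,
                "p_dis": rec.p_dis,
                "r_rep": rec.r_rep,
                "p_rep": rec.p_rep,
                "selected_alpha": rec.selected_alpha,
            }
            for rec in self.records
        ]
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@dataclass
class UnionReplicability:
    """Whether any metric's curve replicates within the grid."""

    replicable: bool
    contributing: dict[str, int]
    min_n: int | None


def draw_split(
    N: int, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two disjoint uniform-random index sets of size n each.

    No stratification or demographic matching: replicability is assessed
    against arbitrary same-population samples.
    """
    if 2 * n > N:
        raise ValueError(f"cannot draw two disjoint samples of {n} from {N} subjects")
    perm = rng.permutation(N)
    return np.sort(perm[:n]), np.sort(perm[n : 2 * n])


def estimate_p_replicability(
    records: list[ShuffleRecord],
    alpha: float = 0.05,
    min_denominator: int = 10,
) -> PReplicability:
    """Fraction of discovery-significant draws that also replicated."""
    if not records:
        raise ValueError("need at least one record")
    sizes = {rec.n for rec in records}
    if len(sizes) != 1:
        raise ValueError(f"records mix sample sizes {sorted(sizes)}")
    dis = [rec for rec in records if rec.p_dis < alpha]
    if not dis:
        return PReplicability(None, 0, len(records), True)
    both = sum(1 for rec in dis if rec.p_rep < alpha)
    return PReplicability(
        both / len(dis), len(dis), len(records), len(dis) < min_denominator
    )


def _child_seed(master_seed: int, phenotype: str, metric: str, n: int, shuffle: int):
    key = zlib.crc32(f"{phenotype}|{metric}".encode())
    return np.random.SeedSequence(master_seed, spawn_key=(key, n, shuffle))


def _load_done(records_path, phenotype: str, metric: str) -> set[tuple[int, int]]:
    if records_path is None or not os.path.exists(records_path):
        return set()
    df = pd.read_csv(records_path, sep="\t")
    df = df[(df["phenotype"] == phenotype) & (df["metric"] == metric)]
    return set(zip(df["n"].astype(int), df["shuffle"].astype(int)))


def run_curve(
    X: np.ndarray,
    y: np.ndarray,
    phenotype: str = "phenotype",
    metric: str = "sc",
    grid=DEFAULT_GRID,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_outer: int = 5,
    n_inner: int = 5,
    alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
    sided: str = "one",
    refit_strategy: str = "refit",
    min_denominator: int = 10,
    records_path=None,
) -> ReplicationCurve:
    """Run the split-resample experiment over a sample-size grid.

    Per-(n, shuffle) seeds are derived deterministically from the master
    seed and the phenotype/metric tag, so any cell of the experiment can be
    reproduced in isolation and runs are order-free.  When
    ``records_path`` is given, records are appended to a long-format TSV as
    they complete and previously finished (n, shuffle) cells are skipped on
    resume.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    N = len(y)
    usable = [int(n) for n in grid if 2 * n <= N]
    if len(usable) < len(list(grid)):
        logger.warning(
            "truncating grid to %s (dataset has %d subjects)", usable, N
        )
    if not usable:
        raise ValueError("no grid entry fits the dataset size")

    done = _load_done(records_path, phenotype, metric)
    if records_path is not None and not os.path.exists(records_path):
        pd.DataFrame(columns=RECORD_COLUMNS).to_csv(records_path, sep="\t", index=False)
    prior = _load_records(records_path, phenotype, metric) if done else []

    records: list[ShuffleRecord] = list(prior)
    for n in usable:
        for s in range(n_shuffles):
            if (n, s) in done:
                continue
            split_ss, cv_ss = _child_seed(seed, phenotype, metric, n, s).spawn(2)
            rng = np.random.default_rng(split_ss)
            cv_seed = int(cv_ss.generate_state(1)[0] >> 1)
            dis_idx, rep_idx = draw_split(N, n, rng)
            nested = fit_nested_cv(
                X[dis_idx],
                y[dis_idx],
                n_outer=n_outer,
                n_inner=n_inner,
                alpha_grid=alpha_grid,
                seed=cv_seed,
                sided=sided,
            )
            r_rep, p_rep, _ = refit_and_evaluate(
                X[dis_idx],
                y[dis_idx],
                nested.selected_alpha,
                X[rep_idx],
                y[rep_idx],
                sided=sided,
                strategy=refit_strategy,
                fold_models=nested.fold_models,
            )
            rec = ShuffleRecord(
                s,
                n,
                dis_idx,
                rep_idx,
                nested.r_dis,
                nested.p_dis,
                r_rep,
                p_rep,
                nested.selected_alpha,
            )
            records.append(rec)
            if records_path is not None:
                pd.DataFrame(
                    [[phenotype, metric, n, s, rec.r_dis, rec.p_dis, rec.r_rep,
                      rec.p_rep, rec.selected_alpha]],
                    columns=RECORD_COLUMNS,
                ).to_csv(records_path, sep="\t", index=False, mode="a", header=False)

    curve = ReplicationCurve(phenotype, metric, tuple(usable), alpha, records)
    for n in usable:
        curve.p_replicability[n] = estimate_p_replicability(
            curve.records_at(n), alpha=alpha, min_denominator=min_denominator
        )
    return curve


def _load_records(records_path, phenotype: str, metric: str) -> list[ShuffleRecord]:
    df = pd.read_csv(records_path, sep="\t")
    df = df[(df["phenotype"] == phenotype) & (df["metric"] == metric)]
    empty = np.array([], dtype=int)
    return [
        ShuffleRecord(
            int(row["shuffle"]), int(row["n"]), empty, empty,
            float(row["r_dis"]), float(row["p_dis"]),
            float(row["r_rep"]), float(row["p_rep"]),
            float(row["selected_alpha"]),
        )
        for _, row in df.iterrows()
    ]


def min_replicable_n(
    curve: ReplicationCurve, threshold: float = 0.8, require_confident: bool = False
) -> int | None:
    """Smallest grid n with P_replicability strictly above ``threshold``.

    Undefined entries count as failing; returns None ("not replicable at
    the maximum grid size") when no entry qualifies.  With
    ``require_confident``, low-confidence estimates (denominator below the
    curve's minimum) also count as failing — at modest shuffle counts a
    crossing supported by a handful of significant discoveries is noise.
    """
    for n in curve.grid:
        est = curve.p_replicability.get(n)
        if est is None or est.value is None:
            continue
        if require_confident and est.low_confidence:
            continue
        if est.value > threshold:
            return n
    return None


def union_replicability(
    curves: list[ReplicationCurve],
    threshold: float = 0.8,
    require_confident: bool = False,
) -> UnionReplicability:
    """A phenotype replicates if at least one metric's curve replicates."""
    if not curves:
        raise ValueError("need at least one curve")
    contributing = {}
    for curve in curves:
        n_e = min_replicable_n(curve, threshold, require_confident)
        if n_e is not None:
            contributing[curve.metric] = n_e
    return UnionReplicability(
        bool(contributing),
        contributing,
        min(contributing.values()) if contributing else None,
    )


def summarize_effects(curve: ReplicationCurve) -> tuple[pd.DataFrame, float]:
    """Per-n mean effect sizes and the cross-n discovery/replication corr.

    The table has, per grid n, the mean discovery and replication effect
    sizes, their difference ``delta_r = mean_r_dis - mean_r_rep`` and their
    average; the second return value is the Pearson correlation between
    mean discovery and replication effect sizes across the grid (nan when
    the grid has fewer than 2 points or either side is constant).
    """
    if not curve.records:
        raise ValueError("curve has no records")
    rows = []
    for n in curve.grid:
        recs = curve.records_at(n)
        r_dis = np.array([rec.r_dis for rec in recs], float)
        r_rep = np.array([rec.r_rep for rec in recs], float)
        est = curve.p_replicability.get(n)
        rows.append(
            {
                "n": n,
                "n_shuffles": len(recs),
                "p_replicability": None if est is None or est.value is None else est.value,
                "mean_r_dis": np.nanmean(r_dis),
                "mean_r_rep": np.nanmean(r_rep),
                "delta_r": np.nanmean(r_dis) - np.nanmean(r_rep),
                "mean_r": (np.nanmean(r_dis) + np.nanmean(r_rep)) / 2.0,
            }
        )
    table = pd.DataFrame(rows)
    a, b = table["mean_r_dis"].to_numpy(), table["mean_r_rep"].to_numpy()
    if len(table) >= 2 and np.ptp(a) > 0 and np.ptp(b) > 0:
        cross_corr = float(np.corrcoef(a, b)[0, 1])
    else:
        cross_corr = float("nan")
    return table, cross_corr
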