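"""End-to-end experiment driver and summary reporting.

``run_experiment`` takes a config (YAML file or dict), resolves the input
data (delimited feature/phenotype tables or a synthetic specification),
runs the split-resample engine for every phenotype-metric pair over the
sample-size grid, derives theoretical sample-size requirements from the
replication-half effect sizes, and writes all result surfaces as TSV plus
a JSON manifest.  ``report_summary`` recounts replicable phenotypes per
metric and under the at-least-one-metric union rule, split by trait/state
category.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import (
    DEFAULT_GRID,
    ReplicationCurve,
    min_replicable_n,
    run_curve,
    summarize_effects,
    union_replicability,
)
from .io import FeatureTable, align, filter_outliers, read_feature_table, read_phenotype_table
from .synthetic import SyntheticConfig, generate_features, generate_phenotype
from .theory import compare_empirical_theoretical, theoretical_n

__all__ = ["ConfigError", "ExperimentResult", "load_config", "run_experiment", "report_summary"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with the offending config path when the config is invalid."""


@dataclass
class ExperimentResult:
    """In-memory view of everything an experiment wrote to disk."""

    curves: list[ReplicationCurve]
    curve_table: pd.DataFrame
    comparison_table: pd.DataFrame
    union_table: pd.DataFrame
    empirical_theoretical_r: float | None
    manifest: dict = field(repr=False, default_factory=dict)
    output_dir: str | None = None


def load_config(source) -> dict:
    if isinstance(source, dict):
        return dict(source)
    with open(source) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config: top level must be a mapping")
    return cfg


def _grid_from(cfg: dict):
    grid = cfg.get("grid")
    if grid is None:
        return DEFAULT_GRID
    if isinstance(grid, dict):
        try:
            return tuple(range(int(grid["start"]), int(grid["stop"]) + 1, int(grid["step"])))
        except KeyError as exc:
            raise ConfigError(f"config: grid missing key {exc}") from exc
    return tuple(int(n) for n in grid)


def _resolve_inputs(cfg: dict, seed: int):
    """Return (features-by-metric, list of (name, y, category))."""
    if ("synthetic" in cfg) == ("inputs" in cfg):
        raise ConfigError("config: exactly one of 'synthetic' or 'inputs' is required")

    if "synthetic" in cfg:
        syn = cfg["synthetic"]
        phenos = syn.get("phenotypes")
        if not phenos:
            raise ConfigError("config: synthetic.phenotypes must be a non-empty list")
        base = dict(
            n_subjects=int(syn.get("n_subjects", 900)),
            n_nodes=int(syn.get("n_nodes", 84)),
            feature_model=syn.get("feature_model", "sparse-lognormal"),
        )
        for key in ("n_latent", "latent_share"):
            if key in syn:
                base[key] = syn[key]
        feat_cfg = SyntheticConfig(seed=seed, **base)
        features = {syn.get("metric", "sc"): generate_features(feat_cfg)}
        targets = []
        for i, ph in enumerate(phenos):
            child = int(
                np.random.SeedSequence(seed, spawn_key=(1000 + i,)).generate_state(1)[0] >> 1
            )
            pcfg = SyntheticConfig(
                seed=child,
                true_r2=float(ph.get("true_r2", 0.0)),
                reliability=float(ph.get("reliability", 1.0)),
                confound_weight=float(ph.get("confound_weight", 0.0)),
                n_informative=ph.get("n_informative"),
                **base,
            )
            planted = generate_phenotype(next(iter(features.values())), pcfg)
            targets.append(
                (ph.get("name", f"pheno{i}"), planted.y, ph.get("category", "unspecified"))
            )
        return features, targets

    inputs = cfg["inputs"]
    try:
        feature_paths = inputs["features"]
        pheno_path = inputs["phenotypes"]
    except KeyError as exc:
        raise ConfigError(f"config: inputs missing key {exc}") from exc
    if isinstance(feature_paths, str):
        feature_paths = {"sc": feature_paths}
    features = {m: read_feature_table(p) for m, p in feature_paths.items()}
    pheno = read_phenotype_table(pheno_path)
    targets = []
    for col in inputs.get("targets", pheno.columns):
        ftab = next(iter(features.values()))
        _, y, _ = align(ftab, pheno, col)
        targets.append((col, y, pheno.categories.get(col, "unspecified")))
    return features, targets


def run_experiment(config, output_dir=None) -> ExperimentResult:
    """Run the full replicability experiment described by ``config``.

    Idempotent under identical config and seed: record files are written
    incrementally and reused on rerun.
    """
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    grid = _grid_from(cfg)
    n_shuffles = int(cfg.get("n_shuffles", 100))
    alpha = float(cfg.get("alpha", 0.05))
    threshold = float(cfg.get("threshold", 0.8))
    # an n_E supported by fewer than min_denominator significant discoveries
    # is Monte-Carlo noise at modest shuffle counts; require confidence
    require_confident = bool(cfg.get("require_confident", True))
    # at a genuine crossing of the 0.8 threshold the discovery power is
    # >= ~85%, so an n_E whose denominator covers < 70% of the shuffles is
    # Monte-Carlo noise, not a crossing
    min_denominator = int(
        cfg.get("min_denominator", max(2, math.ceil(0.7 * n_shuffles)))
    )
    sided = cfg.get("sided", "one")
    theory_cfg = cfg.get("theory", {})
    out = output_dir or cfg.get("output_dir")
    t0 = time.time()

    features_by_metric, targets = _resolve_inputs(cfg, seed)

    outlier_cfg = cfg.get("outlier_filter", {})
    records_path = None
    if out is not None:
        import os

        os.makedirs(out, exist_ok=True)
        records_path = os.path.join(out, "records.tsv")

    max_grid = None
    curves: list[ReplicationCurve] = []
    curve_rows = []
    comp_rows = []
    for name, y, category in targets:
        for metric, ftab in features_by_metric.items():
            X = ftab.values
            yy = y
            if outlier_cfg.get("enabled", False):
                kept, rep = filter_outliers(yy, float(outlier_cfg.get("k", 3.0)))
                logger.info("outlier filter removed %d subjects for %s", rep["n_removed"], name)
                X, yy = X[kept], yy[kept]
            if 2 * min(grid) > len(yy):
                raise ConfigError(
                    f"config: smallest grid entry {min(grid)} needs 2n <= {len(yy)} subjects"
                )
            curve = run_curve(
                X,
                yy,
                phenotype=name,
                metric=metric,
                grid=grid,
                n_shuffles=n_shuffles,
                alpha=alpha,
                seed=seed,
                sided=sided,
                min_denominator=min_denominator,
                records_path=records_path,
            )
            curves.append(curve)
            table, cross_corr = summarize_effects(curve)
            n_e = min_replicable_n(curve, threshold, require_confident)
            max_grid = max(curve.grid)

            # theoretical requirement from the replication-half effect size
            # at the minimum replicable n (least biased available estimate)
            n_t = r_rep_at = None
            if n_e is not None:
                r_rep_at = float(table.loc[table["n"] == n_e, "mean_r_rep"].iloc[0])
                if 0.0 < r_rep_at < 1.0:
                    est = theoretical_n(
                        r_rep_at,
                        alpha=float(theory_cfg.get("alpha", alpha)),
                        target_prob=float(theory_cfg.get("target_prob", threshold)),
                        n_max=int(theory_cfg.get("n_max", 1000)),
                        sided=theory_cfg.get("sided", "two"),
                    )
                    n_t = est.n_required
            comp_rows.append(
                {
                    "phenotype": name,
                    "metric": metric,
                    "category": category,
                    "r_dis": None if n_e is None else float(
                        table.loc[table["n"] == n_e, "mean_r_dis"].iloc[0]
                    ),
                    "r_rep": r_rep_at,
                    "n_E": n_e,
                    "n_T": n_t,
                    "cross_n_effect_corr": cross_corr,
                }
            )
            for _, row in table.iterrows():
                curve_rows.append(
                    {"phenotype": name, "metric": metric, "category": category, **row}
                )

    curve_table = pd.DataFrame(curve_rows)
    comparison = pd.DataFrame(comp_rows)

    union_rows = []
    for name, _, category in targets:
        u = union_replicability(
            [c for c in curves if c.phenotype == name], threshold, require_confident
        )
        union_rows.append(
            {
                "phenotype": name,
                "category": category,
                "replicable": u.replicable,
                "contributing_metrics": ",".join(sorted(u.contributing)) or None,
                "min_n_E": u.min_n,
            }
        )
    union_table = pd.DataFrame(union_rows)

    finite = comparison.dropna(subset=["n_E", "n_T"])
    emp_theo_r = None
    if len(finite) >= 3:
        emp_theo_r, _ = compare_empirical_theoretical(
            list(zip(finite["n_E"], finite["n_T"]))
        )

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "grid": list(grid),
        "max_grid_n": max_grid,
        "n_shuffles": n_shuffles,
        "alpha": alpha,
        "threshold": threshold,
        "engine_sided": sided,
        "theory_sided": theory_cfg.get("sided", "two"),
        "empirical_theoretical_r": emp_theo_r,
        "elapsed_s": round(time.time() - t0, 2),
    }

    if out is not None:
        import os

        curve_table.to_csv(os.path.join(out, "curves.tsv"), sep="\t", index=False)
        comparison.to_csv(os.path.join(out, "comparison.tsv"), sep="\t", index=False)
        union_table.to_csv(os.path.join(out, "union.tsv"), sep="\t", index=False)
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return ExperimentResult(
        curves, curve_table, comparison, union_table, emp_theo_r, manifest, out
    )


def _pct(k: int, n: int) -> str:
    if n == 0:
        return "n/a"
    return f"{k}/{n} ({int(math.floor(k / n * 100 + 0.5))}%)"


def report_summary(result: ExperimentResult) -> dict:
    """Replicable-phenotype counts per metric and union, by category.

    Counts are recomputed from the union/comparison tables (never cached)
    and formatted as ``"k/N (pct)"``; empty categories report ``"n/a"``.
    """
    union = result.union_table
    out: dict[str, dict] = {"union": {}, "per_metric": {}}
    groups = {"overall": union, "trait": union[union["category"] == "trait"],
              "state": union[union["category"] == "state"]}
    for label, g in groups.items():
        out["union"][label] = _pct(int(g["replicable"].sum()), len(g))
    for metric, g in result.comparison_table.groupby("metric"):
        rep = g["n_E"].notna()
        out["per_metric"][metric] = {
            "overall": _pct(int(rep.sum()), len(g)),
            "trait": _pct(
                int(rep[g["category"] == "trait"].sum()),
                int((g["category"] == "trait").sum()),
            ),
            "state": _pct(
                int(rep[g["category"] == "state"].sum()),
                int((g["category"] == "state").sum()),
            ),
            "mean_n_E": None if not rep.any() else float(g.loc[rep, "n_E"].mean()),
        }
    return out
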