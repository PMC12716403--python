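"""In-silico experiments: force sweep, leader comparison, cell-line panel,
time course — full pipeline (simulate -> trace -> topology -> migration) with
seeded permutation statistics across replicates.

Replicate ``r`` of condition ``c`` runs with seed
``(seed_base + (crc32(c) % 100003) * n_replicates + r) % 2**31`` so that every
(condition, replicate) pair has a distinct, reproducible seed recorded in the
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .abm import ModelParams, SimConfig, TrajectorySet, run_simulation
from .migration import cohort_metrics
from .topology import TopologyMetrics, analyze_mask, metrics_report
from .trace import rasterize_trajectories, write_grid

logger = logging.getLogger(__name__)

EXPERIMENT_NAMES = ("force_sweep", "leader_comparison", "cellline_panel", "time_course")

#: Nominal force ladder mirroring the low/intermediate/control contractility
#: conditions of the blebbistatin experiments (labels only; not calibrated).
FORCE_LEVELS = {"low": 0.25, "middle": 1.0, "high": 2.0}

#: Editable per-cell-line presets ordered by the qualitative invasiveness
#: hierarchy (MCF-10A < T47D < MCF-7 < MDA-MB-231); no quantitative fidelity
#: is claimed. leader_fraction for MDA-MB-231 follows the ~16% leader share
#: measured in single channels.
CELL_LINE_PRESETS: dict[str, dict] = {
    "MCF-10A": {"params.f_base": 0.25, "v0": 0.01, "leader_fraction": 0.0},
    "T47D": {"params.f_base": 0.5, "v0": 0.015, "leader_fraction": 0.05},
    "MCF-7": {"params.f_base": 1.0, "v0": 0.02, "leader_fraction": 0.10},
    "MDA-MB-231": {"params.f_base": 2.0, "v0": 0.03, "leader_fraction": 0.16},
}

CELL_LINE_ORDER = ["MCF-10A", "T47D", "MCF-7", "MDA-MB-231"]


@dataclass
class ExperimentSpec:
    name: str
    base: SimConfig = field(default_factory=SimConfig)
    conditions: dict[str, dict] = field(default_factory=dict)
    n_replicates: int = 10
    seed_base: int = 0
    outdir: str | None = None
    pixel_size: float = 2.0
    channel_radius: float | None = None
    #: minimum detectable channel: spurs shorter than ~2x channel width are
    #: wall roughness / cell-sized pockets, not resolvable channels
    prune_px: float = 8.0
    robustness_trials: int = 50

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(
                f"unknown experiment {self.name!r}; valid: {EXPERIMENT_NAMES}"
            )


def condition_seed(seed_base: int, label: str, n_replicates: int, replicate: int) -> int:
    """Stable, documented seed for one (condition, replicate) run."""
    h = zlib.crc32(label.encode()) % 100003
    return int((seed_base + h * n_replicates + replicate) % (2**31))


def apply_overrides(config: SimConfig, overrides: dict) -> SimConfig:
    """Return a copy of config with flat-key overrides applied.

    Keys may be SimConfig fields ('v0', 'leader_fraction', ...) or
    ModelParams fields, optionally prefixed 'params.' ('f_base' or
    'params.f_base').
    """
    cfg = dataclasses.replace(config, params=dataclasses.replace(config.params))
    for key, value in overrides.items():
        name = key.removeprefix("params.")
        if key.startswith("params.") or hasattr(cfg.params, name):
            if not hasattr(cfg.params, name):
                raise KeyError(f"unknown ModelParams field {name!r}")
            setattr(cfg.params, name, value)
        elif hasattr(cfg, name):
            setattr(cfg, name, value)
        else:
            raise KeyError(f"unknown config field {key!r}")
    return cfg


def run_pipeline(
    config: SimConfig,
    pixel_size: float = 2.0,
    channel_radius: float | None = None,
    prune_px: float = 8.0,
    robustness_trials: int = 50,
) -> tuple[TopologyMetrics, pd.DataFrame, TrajectorySet]:
    """simulate -> rasterize -> skeleton topology + migration summary."""
    traj = run_simulation(config)
    grid = rasterize_trajectories(traj, channel_radius=channel_radius,
                                  pixel_size=pixel_size)
    metrics, _ = analyze_mask(
        grid, prune_px=prune_px,
        robustness_trials=robustness_trials, robustness_seed=config.seed,
    )
    _, summary = cohort_metrics(traj)
    return metrics, summary, traj


def run_experiment(spec: ExperimentSpec, save_masks: bool = False) -> pd.DataFrame:
    """Run all conditions x replicates; tidy (condition, replicate, metric, value).

    Migration summary statistics are included with a ``migration_`` prefix.
    A failing replicate is logged and skipped; the rest continue. When
    ``spec.outdir`` is set, a manifest JSON (configs, seeds) and the tidy CSV
    are written there, plus per-run masks if ``save_masks``.
    """
    outdir = Path(spec.outdir) if spec.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    manifest: dict = {"name": spec.name, "seed_base": spec.seed_base,
                      "n_replicates": spec.n_replicates, "runs": []}
    completed = 0
    for label, overrides in spec.conditions.items():
        cfg_c = apply_overrides(spec.base, overrides)
        for r in range(spec.n_replicates):
            seed = condition_seed(spec.seed_base, label, spec.n_replicates, r)
            cfg = dataclasses.replace(
                cfg_c, seed=seed, cellline_label=label,
                params=dataclasses.replace(cfg_c.params),
            )
            try:
                metrics, summary, traj = run_pipeline(
                    cfg,
                    pixel_size=spec.pixel_size,
                    channel_radius=spec.channel_radius,
                    prune_px=spec.prune_px,
                    robustness_trials=spec.robustness_trials,
                )
            except Exception:
                logger.exception("replicate failed: %s r=%d seed=%d", label, r, seed)
                continue
            completed += 1
            manifest["runs"].append(
                {"condition": label, "replicate": r, "seed": seed,
                 "config": cfg.to_dict()}
            )
            for metric, value in metrics.to_dict().items():
                rows.append((label, r, metric, value))
            all_row = summary[summary["role"] == "all"].iloc[0]
            for s in ("total_distance", "displacement", "mean_velocity",
                      "straightness"):
                rows.append((label, r, f"migration_{s}_mean", all_row[f"{s}_mean"]))
            if save_masks and outdir:
                grid = rasterize_trajectories(
                    traj, channel_radius=spec.channel_radius,
                    pixel_size=spec.pixel_size,
                )
                write_grid(grid, outdir / f"{label}_r{r}.tiff")
    logger.info("experiment %s: %d/%d runs completed", spec.name, completed,
                len(spec.conditions) * spec.n_replicates)
    results = pd.DataFrame(rows, columns=["condition", "replicate", "metric", "value"])
    if outdir:
        results.to_csv(outdir / "results.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        try:
            _write_heatmap(results, outdir / "heatmap.png",
                           outdir / "metrics_long.csv")
        except Exception:  # plotting must never kill an experiment
            logger.exception("heatmap rendering failed")
    return results


def _write_heatmap(results: pd.DataFrame, png: Path, csv: Path) -> None:
    means = (
        results.pivot_table(index="condition", columns="metric", values="value",
                            aggfunc="mean")
    )
    topo_cols = [c for c in means.columns if not c.startswith("migration_")]
    metrics_list, labels = [], []
    for label, row in means[topo_cols].iterrows():
        m = TopologyMetrics()
        for k, v in row.items():
            setattr(m, k, v)
        metrics_list.append(m)
        labels.append(str(label))
    metrics_report(metrics_list, labels, out_csv=csv, out_png=png)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class TrendResult:
    rho: float
    p_value: float
    n: int


def trend_test(
    results: pd.DataFrame,
    metric: str,
    ordered_conditions: list[str],
    n_permutations: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> TrendResult:
    """Spearman rank trend of a metric across ordered conditions.

    One-sided permutation p-value from ``n_permutations`` seeded shuffles of
    the metric values against condition ranks; ``alternative`` 'greater'
    tests for an increasing trend, 'less' for decreasing, 'two-sided' for
    either. Constant metric -> correlation undefined (NaN).
    """
    sub = results[results["metric"] == metric]
    ranks, values = [], []
    for k, cond in enumerate(ordered_conditions):
        v = sub[sub["condition"] == cond]["value"].to_numpy(dtype=float)
        ranks.extend([k] * len(v))
        values.extend(v)
    ranks = np.asarray(ranks, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(set(ordered_conditions) & set(sub["condition"])) < 2 or len(values) < 3:
        raise ValueError("need >= 2 ordered conditions with data")
    if np.all(values == values[0]):
        return TrendResult(np.nan, np.nan, len(values))
    rho = float(stats.spearmanr(ranks, values).statistic)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    v = values.copy()
    for i in range(n_permutations):
        rng.shuffle(v)
        perm[i] = stats.spearmanr(ranks, v).statistic
    if alternative == "greater":
        extreme = perm >= rho
    elif alternative == "less":
        extreme = perm <= rho
    else:
        extreme = np.abs(perm) >= abs(rho)
    p = (1.0 + extreme.sum()) / (n_permutations + 1.0)
    return TrendResult(rho, float(p), len(values))


@dataclass
class GroupComparison:
    effect: float  # mean(A) - mean(B)
    p_value: float
    n_a: int
    n_b: int


def compare_groups(
    results: pd.DataFrame,
    metric: str,
    condition_a: str,
    condition_b: str,
    n_permutations: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> GroupComparison:
    """Difference of means (A - B) with a permutation p-value.

    When the number of distinct group assignments C(n, n_a) is at most
    20000 the test enumerates them all (exact p); otherwise it draws
    ``n_permutations`` seeded random shuffles.
    """
    import itertools
    import math as _math

    sub = results[results["metric"] == metric]
    a = sub[sub["condition"] == condition_a]["value"].to_numpy(dtype=float)
    b = sub[sub["condition"] == condition_b]["value"].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both conditions must be present in the results")
    effect = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return GroupComparison(0.0, np.nan, len(a), len(b))

    def _p(perm_effects, include_observed):
        perm_effects = np.asarray(perm_effects)
        if alternative == "greater":
            extreme = perm_effects >= effect - 1e-12
        elif alternative == "less":
            extreme = perm_effects <= effect + 1e-12
        else:
            extreme = np.abs(perm_effects) >= abs(effect) - 1e-12
        if include_observed:  # observed assignment is one of the enumerated
            return extreme.sum() / len(perm_effects)
        return (1.0 + extreme.sum()) / (len(perm_effects) + 1.0)

    n, na = len(pooled), len(a)
    total = pooled.sum()
    if _math.comb(n, na) <= 20000:
        effects = [
            (s := pooled[list(idx)].sum()) / na - (total - s) / (n - na)
            for idx in itertools.combinations(range(n), na)
        ]
        return GroupComparison(effect, float(_p(effects, True)), na, n - na)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    for i in range(n_permutations):
        rng.shuffle(pooled)
        perm[i] = pooled[:na].mean() - pooled[na:].mean()
    return GroupComparison(effect, float(_p(perm, False)), na, n - na)


# ---------------------------------------------------------------------------
# canned experiment specs
# ---------------------------------------------------------------------------

def force_sweep_spec(
    base: SimConfig | None = None, n_replicates: int = 10, seed_base: int = 0,
    **kwargs,
) -> ExperimentSpec:
    """Low/middle/high interaction-force ladder (F_base x 0.25 / 1 / 2)."""
    base = base or SimConfig()
    conditions = {
        label: {"params.f_base": base.params.f_base * mult}
        for label, mult in FORCE_LEVELS.items()
    }
    return ExperimentSpec("force_sweep", base, conditions, n_replicates,
                          seed_base, **kwargs)


def leader_comparison_spec(
    base: SimConfig | None = None, n_replicates: int = 10, seed_base: int = 0,
    leader_fraction: float = 0.15, leader_factor: float = 2.0, **kwargs,
) -> ExperimentSpec:
    """With-leaders vs no-leaders at otherwise identical parameters."""
    base = base or SimConfig()
    conditions = {
        "no_leaders": {"leader_fraction": 0.0},
        "leaders": {"leader_fraction": leader_fraction,
                    "params.leader_factor": leader_factor},
    }
    return ExperimentSpec("leader_comparison", base, conditions, n_replicates,
                          seed_base, **kwargs)


def cellline_panel_spec(
    base: SimConfig | None = None, n_replicates: int = 5, seed_base: int = 0,
    presets: dict[str, dict] | None = None, **kwargs,
) -> ExperimentSpec:
    """Four-cell-line panel under the bundled parameter presets."""
    base = base or SimConfig()
    return ExperimentSpec(
        "cellline_panel", base, dict(presets or CELL_LINE_PRESETS),
        n_replicates, seed_base, **kwargs,
    )


def run_time_course(
    config: SimConfig,
    checkpoints: list[int] | None = None,
    n_replicates: int = 5,
    seed_base: int = 0,
    pixel_size: float = 2.0,
    channel_radius: float | None = None,
    prune_px: float = 8.0,
    robustness_trials: int = 50,
) -> pd.DataFrame:
    """Topology metrics at increasing recorded-frame checkpoints.

    Each replicate is simulated once; the cumulative occupancy map is cut at
    each checkpoint frame (channels are irreversible, so the pixel sets are
    nested). Returns tidy (checkpoint, replicate, metric, value).
    """
    rows = []
    for r in range(n_replicates):
        seed = condition_seed(seed_base, "time_course", n_replicates, r)
        cfg = dataclasses.replace(
            config, seed=seed, params=dataclasses.replace(config.params)
        )
        traj = run_simulation(cfg)
        frames = checkpoints or _default_checkpoints(traj.n_frames)
        for f in frames:
            grid = rasterize_trajectories(
                traj, channel_radius=channel_radius, pixel_size=pixel_size,
                max_frame=f,
            )
            metrics, _ = analyze_mask(
                grid, prune_px=prune_px,
                robustness_trials=robustness_trials, robustness_seed=seed,
            )
            for metric, value in metrics.to_dict().items():
                rows.append((f, r, metric, value))
    return pd.DataFrame(rows, columns=["checkpoint", "replicate", "metric", "value"])


def _default_checkpoints(n_frames: int, n: int = 4) -> list[int]:
    if n_frames <= 1:
        return [0]
    return sorted({int(round(f)) for f in np.linspace(n_frames / n, n_frames - 1, n)})
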