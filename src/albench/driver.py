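"""Active-learning campaign orchestration.

A campaign acquires a fixed total budget of compounds (360 by default) from a
pool in cycles. Each cycle selects a batch by the current phase's strategy,
reveals the (possibly noise-corrupted) labels of the batch, retrains the
surrogate from scratch on everything acquired so far, and predicts on the
remaining pool. Per-cycle metrics score two different things:

* retrieval — Recall and F1 of the cumulative acquired set against the TRUE
  (noiseless) top-2%/5% potency sets; noisy labels are used only for
  training, and
* regression — R2, Spearman rho and RMSE of the surrogate's predictions on
  the remaining (unacquired) pool against true potency.

Label noise emulates a noisy labeling method (assay or free-energy
calculation): additive Gaussian with sd = multiplier x the pool's potency sd,
drawn once per compound per campaign — a label, once measured, is fixed.

Seed policy: one master seed per campaign derives independent streams for the
random acquisition cycles and the noise draw, so campaigns are exactly
reproducible and repeats differ only through their master seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .acquisition import AcquisitionRequest, select_batch
from .metrics import make_topk_spec, recall_topk, f1_topk, regression_metrics
from .surrogate import GPHyperparams, SurrogatePosterior, TanimotoGP
from .synthetic import CompoundPool

DEFAULT_BUDGET = 360
TOPK_FRACTIONS = (0.02, 0.05)


# --------------------------------------------------------------------------
# protocols


@dataclass(frozen=True)
class Protocol:
    """An ordered list of acquisition phases under a fixed total budget."""

    name: str
    phases: Tuple[Tuple[str, int, int], ...]  # (strategy, batch_size, n_cycles)
    total_budget: int = DEFAULT_BUDGET

    def __post_init__(self) -> None:
        acquired = sum(b * c for _, b, c in self.phases)
        if acquired != self.total_budget:
            raise ValueError(
                f"protocol {self.name!r} phases acquire {acquired} compounds, "
                f"budget is {self.total_budget} (deficit {self.total_budget - acquired})"
            )
        if not self.phases or self.phases[0][0] != "random":
            raise ValueError("first phase must use the 'random' strategy")

    @property
    def n_cycles(self) -> int:
        return sum(c for _, _, c in self.phases)


_PROTOCOLS = {
    "random-exploit": (("random", 60, 1), ("exploit", 30, 10)),
    "random-explore-exploit": (("random", 60, 1), ("explore", 30, 2), ("exploit", 30, 8)),
    "random-random-exploit": (("random", 60, 2), ("exploit", 30, 8)),
    "batch-size-20": (("random", 60, 1), ("explore", 20, 3), ("exploit", 20, 12)),
    "batch-size-30": (("random", 60, 1), ("explore", 30, 2), ("exploit", 30, 8)),
    "batch-size-60": (("random", 60, 1), ("explore", 60, 1), ("exploit", 60, 4)),
    "batch-size-120": (("random", 60, 1), ("explore", 60, 1), ("exploit", 120, 2)),
}


def build_protocol(
    name: str,
    total_budget: int = DEFAULT_BUDGET,
    phases: Optional[Sequence[Tuple[str, int, int]]] = None,
) -> Protocol:
    """Expand a named protocol, or build a custom one from a phase list."""
    if phases is not None:
        return Protocol(name=name, phases=tuple(phases), total_budget=total_budget)
    if name not in _PROTOCOLS:
        raise ValueError(
            f"unknown protocol {name!r}; valid names: {sorted(_PROTOCOLS)}"
        )
    return Protocol(name=name, phases=_PROTOCOLS[name], total_budget=total_budget)


# --------------------------------------------------------------------------
# label noise


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian label noise scaled to the pool's potency sd.

    ``seed=None`` lets the campaign derive the noise stream from its master
    seed; an explicit seed pins the draw.
    """

    multiplier: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.multiplier < 0:
            raise ValueError("noise multiplier must be >= 0")


DEFAULT_NOISE_GRID = (0.0, 0.5, 1.0, 1.5, 2.0)


def add_label_noise(potency: np.ndarray, pool_sd: float, spec: NoiseSpec) -> np.ndarray:
    """potency + N(0, (multiplier * pool_sd)^2), one draw per compound.

    A zero multiplier returns the input values exactly.
    """
    potency = np.asarray(potency, dtype=float)
    if not np.all(np.isfinite(potency)):
        raise ValueError("potency values must be finite")
    if pool_sd < 0:
        raise ValueError("pool_sd must be >= 0")
    if spec.multiplier == 0.0:
        return potency.copy()
    rng = np.random.default_rng(spec.seed)
    return potency + rng.normal(0.0, spec.multiplier * pool_sd, size=len(potency))


# --------------------------------------------------------------------------
# surrogates


def make_surrogate(spec) -> object:
    """Resolve a surrogate spec to a fresh unfitted model.

    Accepts "gp" (Tanimoto GP, hyperparameters optimized), a
    :class:`GPHyperparams` (fixed hyperparameters), or a zero-argument
    factory returning any object with ``fit(X, y)`` / ``predict(X)``.
    """
    if spec == "gp" or spec is None:
        return TanimotoGP(hyper="optimize")
    if isinstance(spec, GPHyperparams):
        return TanimotoGP(hyper=spec)
    if callable(spec):
        return spec()
    raise ValueError(f"cannot interpret surrogate spec {spec!r}")


# --------------------------------------------------------------------------
# campaigns


@dataclass
class CycleRecord:
    cycle: int
    strategy: str
    acquired_ids: List
    noisy_labels: np.ndarray


@dataclass
class AcquisitionLog:
    """Which compounds were acquired in which cycle, by which strategy."""

    seed: int
    protocol: str
    noise_multiplier: float
    cycles: List[CycleRecord] = field(default_factory=list)
    truncated: bool = False

    @property
    def acquired_ids(self) -> List:
        return [cid for rec in self.cycles for cid in rec.acquired_ids]


def run_campaign(
    pool: CompoundPool,
    protocol: Protocol,
    surrogate_spec="gp",
    noise: NoiseSpec = NoiseSpec(0.0),
    seed: int = 0,
) -> Tuple[AcquisitionLog, pd.DataFrame]:
    """Run one active-learning campaign; returns the acquisition log and the
    per-cycle metrics trajectory (one row per cycle)."""
    if pool.fingerprints is None:
        raise ValueError("pool has no fingerprints; featurize first")

    master = np.random.SeedSequence(seed)
    ss_random, ss_noise = master.spawn(2)
    random_rng = np.random.default_rng(ss_random)

    noise_seed = noise.seed
    if noise_seed is None:
        noise_seed = int(ss_noise.generate_state(1)[0] % (2**31))
    noisy_potency = add_label_noise(
        pool.potency, pool.potency_sd, replace(noise, seed=noise_seed)
    )

    ids = list(pool.ids)
    index_of = {cid: i for i, cid in enumerate(ids)}
    topk_specs = {
        r: make_topk_spec(ids, pool.potency, r) for r in TOPK_FRACTIONS
    }

    log = AcquisitionLog(
        seed=seed, protocol=protocol.name, noise_multiplier=noise.multiplier
    )
    acquired: List = []
    remaining: List = list(ids)
    posterior: Optional[SurrogatePosterior] = None
    rows = []
    cycle = 0
    for strategy, batch_size, n_cycles in protocol.phases:
        for _ in range(n_cycles):
            if not remaining:
                log.truncated = True
                break
            bs = min(batch_size, len(remaining))
            if bs < batch_size:
                log.truncated = True
            if strategy == "random":
                request = AcquisitionRequest(
                    strategy="random",
                    batch_size=bs,
                    candidate_ids=remaining,
                    seed=int(random_rng.integers(2**31)),
                )
            else:
                if posterior is None:
                    raise RuntimeError(
                        f"cycle {cycle}: strategy {strategy!r} needs a posterior "
                        "but no model has been trained yet"
                    )
                request = AcquisitionRequest(
                    strategy=strategy,
                    batch_size=bs,
                    candidate_ids=remaining,
                    posterior=posterior,
                )
            batch = select_batch(request)
            acquired.extend(batch)
            batch_set = set(batch)
            remaining = [cid for cid in remaining if cid not in batch_set]

            train_idx = [index_of[cid] for cid in acquired]
            model = make_surrogate(surrogate_spec)
            try:
                model.fit(pool.fingerprints[train_idx], noisy_potency[train_idx])
                if remaining:
                    rem_idx = [index_of[cid] for cid in remaining]
                    mean, variance = model.predict(pool.fingerprints[rem_idx])
                    posterior = SurrogatePosterior(mean=mean, variance=variance)
                else:
                    posterior = None
            except Exception as exc:
                raise RuntimeError(
                    f"surrogate failure in cycle {cycle} "
                    f"(strategy {strategy!r}, {len(acquired)} acquired)"
                ) from exc

            log.cycles.append(
                CycleRecord(
                    cycle=cycle,
                    strategy=strategy,
                    acquired_ids=list(batch),
                    noisy_labels=noisy_potency[[index_of[c] for c in batch]].copy(),
                )
            )
            rows.append(
                _cycle_metrics(
                    cycle, strategy, acquired, remaining, posterior, pool,
                    topk_specs, seed,
                )
            )
            cycle += 1
        if not remaining and cycle < protocol.n_cycles:
            log.truncated = True
            break
    return log, pd.DataFrame(rows)


def _cycle_metrics(cycle, strategy, acquired, remaining, posterior, pool,
                   topk_specs, seed) -> dict:
    n_acq = len(acquired)
    row = {
        "seed": seed,
        "cycle": cycle,
        "strategy": strategy,
        "n_acquired": n_acq,
    }
    for r, spec in topk_specs.items():
        tag = f"top{int(round(r * 100))}"
        row[f"recall_{tag}"] = recall_topk(acquired, spec)
        row[f"f1_{tag}"] = f1_topk(acquired, spec)
        row[f"baseline_recall_{tag}"] = min(1.0, r * n_acq / spec.k)
    if posterior is not None and len(remaining) >= 2:
        index_of = {cid: i for i, cid in enumerate(pool.ids)}
        truth = pool.potency[[index_of[c] for c in remaining]]
        reg = regression_metrics(posterior.mean, truth)
        row["r2"] = reg["r2"]
        row["spearman"] = reg["spearman_rho"]
        row["rmse"] = reg["rmse"]
    else:
        row["r2"] = row["spearman"] = row["rmse"] = float("nan")
    return row


@dataclass
class RepeatedCampaigns:
    """Per-seed campaign results plus mean / min-max bands across seeds."""

    per_seed: dict  # seed -> (AcquisitionLog, trajectory DataFrame)
    aggregate: pd.DataFrame  # per-cycle mean and min-max band of each metric


def repeat_campaigns(
    pool: CompoundPool,
    protocol: Protocol,
    surrogate_spec="gp",
    noise: NoiseSpec = NoiseSpec(0.0),
    seeds: Sequence[int] = (1, 2, 3),
) -> RepeatedCampaigns:
    """Repeat a campaign over seeds and aggregate per-cycle metrics."""
    if not seeds:
        raise ValueError("need at least one seed")
    per_seed = {
        s: run_campaign(pool, protocol, surrogate_spec, noise, seed=s) for s in seeds
    }
    stacked = pd.concat([traj for _, traj in per_seed.values()], ignore_index=True)
    metric_cols = [
        c for c in stacked.columns if c not in ("seed", "cycle", "strategy")
    ]
    agg = stacked.groupby("cycle")[metric_cols].agg(["mean", "min", "max"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return RepeatedCampaigns(per_seed=per_seed, aggregate=agg.reset_index())


# --------------------------------------------------------------------------
# single-batch model benchmark


def benchmark_split(
    pool: CompoundPool,
    train_fraction: float = 0.2,
    n_folds: int = 5,
    surrogate_spec="gp",
    seed: int = 0,
) -> Tuple[pd.DataFrame, dict]:
    """Benchmark a surrogate on disjoint train partitions.

    The pool is shuffled once and cut into ``n_folds`` disjoint train sets of
    ``round(train_fraction * n)`` compounds; each fold trains on its partition
    and is scored on all remaining compounds (R2, Spearman rho, RMSE, and
    top-2%/5% Recall with the active sets defined within each test side).
    Returns per-fold metrics and a summary with the mean and 95% confidence
    half-width across folds.
    """
    if pool.fingerprints is None:
        raise ValueError("pool has no fingerprints; featurize first")
    n = len(pool)
    train_size = int(round(train_fraction * n))
    if train_size < 2:
        raise ValueError("pool too small: each fold's train set must have >= 2 compounds")
    if n_folds * train_size > n:
        raise ValueError(
            f"cannot cut {n_folds} disjoint train sets of {train_size} from {n} compounds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    rows = []
    for fold in range(n_folds):
        train_idx = order[fold * train_size : (fold + 1) * train_size]
        test_idx = np.setdiff1d(order, train_idx)
        model = make_surrogate(surrogate_spec)
        model.fit(pool.fingerprints[train_idx], pool.potency[train_idx])
        mean, _ = model.predict(pool.fingerprints[test_idx])
        truth = pool.potency[test_idx]
        reg = regression_metrics(mean, truth)
        row = {"fold": fold, "r2": reg["r2"], "spearman": reg["spearman_rho"],
               "rmse": reg["rmse"]}
        test_ids = list(pool.ids[test_idx])
        for r in TOPK_FRACTIONS:
            spec = make_topk_spec(test_ids, truth, r)
            ranked = sorted(
                range(len(test_ids)), key=lambda i: (-mean[i], test_ids[i])
            )
            selected = [test_ids[i] for i in ranked[: spec.k]]
            row[f"recall_top{int(round(r * 100))}"] = recall_topk(selected, spec)
        rows.append(row)
    folds = pd.DataFrame(rows)
    summary = {}
    tcrit = _stats.t.ppf(0.975, df=n_folds - 1) if n_folds > 1 else float("nan")
    for col in folds.columns.drop("fold"):
        vals = folds[col].to_numpy()
        half = tcrit * vals.std(ddof=1) / np.sqrt(n_folds) if n_folds > 1 else 0.0
        summary[col] = {"mean": float(vals.mean()), "ci95": float(half)}
    return folds, summary


# --------------------------------------------------------------------------
# cost model


def rbfe_cost(n_compounds: int, gpu_hours_each: float = 8.0, rate: float = 2.50) -> float:
    """Cost (USD) of labeling by relative binding free energy calculations:
    n_compounds x gpu_hours_each x rate."""
    if n_compounds < 0 or gpu_hours_each < 0 or rate < 0:
        raise ValueError("all cost inputs must be >= 0")
    return n_compounds * gpu_hours_each * rate
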