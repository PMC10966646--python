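"""Synthetic structure–activity libraries and compound-pool I/O.

The generator emulates the regimes an affinity pool can present to an
active-learning campaign: a congeneric combinatorial library with a few dense
scaffold clusters and the top binders concentrated in one or two of them, a
heterogeneous pool of many small congeneric series, and a small diverse pool
where a fixed acquisition budget covers more than half of the compounds.

Generative model
----------------
Compounds are assigned to ``n_clusters`` scaffold clusters. Each cluster owns
a set of "core" fingerprint bits (shared by all of its members, the scaffold)
and a set of "substituent" bits; a compound switches each substituent bit on
independently with probability 1/2 (a random R-group combination). Potency is

    potency = cluster_effect + sum_b (bit_b - 1/2) * beta_b + eps

with per-cluster substituent coefficients beta ~ N(0, substituent_effect_sd)
and residual eps ~ N(0, residual_sd). Centering the bits at 1/2 makes the
substituent term a pure within-cluster effect, so the pooled potency variance
decomposes as

    cluster_effect_sd^2 + substituent_bits/4 * substituent_effect_sd^2
    + residual_sd^2.

The generator is variance-targeted: the per-cluster effects are drawn
Gaussian, sorted so that the ``active_cluster_fraction`` lowest-numbered
clusters carry the largest effects (the top binders concentrate there, as in
a lead-optimization library), and then standardized so their size-weighted
sd is exactly ``cluster_effect_sd``; likewise each cluster's beta vector is
rescaled to its nominal mean square. This pins the pooled sd at the
scenario's nominal value even for scenarios with only a handful of clusters,
which the presets use to hit realistic pooled standard deviations (~1.4 pK
units for the large/heterogeneous regimes, ~0.9 for the small diverse one).

Free-energy conversion
----------------------
Relative binding free energies ddG (kJ/mol) against a reference compound with
absolute binding free energy dG_ref convert to pKi through dG = RT ln Ki and
pKi = -log10 Ki:

    pKi = -(dG_ref + ddG) * 1000 / (R * T * ln 10),   R = 8.314 J/(mol K).

The temperature is not part of the data; the default 298.15 K is the
standard-condition convention and can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

GAS_CONSTANT = 8.314  # J / (mol K)
DG_REF_DEFAULT = -47.778  # kJ/mol, absolute binding free energy of the reference
LN10 = math.log(10.0)


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the generative structure–activity model."""

    n_compounds: int
    n_clusters: int
    cluster_size_dispersion: float = 0.0
    core_bits_per_cluster: int = 40
    substituent_bits: int = 30
    fingerprint_length: int = 4096
    cluster_effect_sd: float = 1.0  # pK units
    substituent_effect_sd: float = 0.2  # pK units
    residual_sd: float = 0.3  # pK units
    active_cluster_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_compounds < self.n_clusters:
            raise ValueError("n_compounds must be >= n_clusters")
        if self.core_bits_per_cluster + self.substituent_bits > self.fingerprint_length:
            raise ValueError(
                "infeasible bit budget: core_bits_per_cluster + substituent_bits "
                f"= {self.core_bits_per_cluster + self.substituent_bits} exceeds "
                f"fingerprint_length = {self.fingerprint_length}"
            )
        for name in ("cluster_effect_sd", "substituent_effect_sd", "residual_sd",
                     "cluster_size_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.active_cluster_fraction <= 1:
            raise ValueError("active_cluster_fraction must be in (0, 1]")

    @property
    def expected_potency_sd(self) -> float:
        """Pooled potency sd implied by the additive model."""
        return math.sqrt(
            self.cluster_effect_sd**2
            + 0.25 * self.substituent_bits * self.substituent_effect_sd**2
            + self.residual_sd**2
        )


@dataclass
class CompoundPool:
    """A pool of compounds: ids, binary fingerprints and true potencies.

    ``fingerprints`` may be None for a pool read from CSV without a
    fingerprint matrix (the caller then featurizes from SMILES).
    ``potency_sd`` is always the population standard deviation recomputed
    from ``potency``.
    """

    ids: np.ndarray
    potency: np.ndarray
    fingerprints: Optional[np.ndarray] = None
    cluster_id: Optional[np.ndarray] = None
    smiles: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.potency = np.asarray(self.potency, dtype=float)
        n = len(self.ids)
        if len(np.unique(self.ids)) != n:
            raise ValueError("compound ids must be unique")
        if len(self.potency) != n:
            raise ValueError("ids and potency must have equal length")
        if not np.all(np.isfinite(self.potency)):
            raise ValueError("potency values must be finite")
        if self.fingerprints is not None:
            self.fingerprints = np.asarray(self.fingerprints)
            if self.fingerprints.ndim != 2 or self.fingerprints.shape[0] != n:
                raise ValueError("fingerprints must be an (n, d) matrix")
            if not np.isin(self.fingerprints, (0, 1)).all():
                raise ValueError("fingerprint entries must be 0 or 1")
        if self.cluster_id is not None:
            self.cluster_id = np.asarray(self.cluster_id, dtype=int)
            if len(self.cluster_id) != n:
                raise ValueError("cluster_id must have one entry per compound")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def potency_sd(self) -> float:
        return float(np.std(self.potency))


def generate_library(scenario: SyntheticScenario) -> CompoundPool:
    """Generate a synthetic pool under the scenario's structure–activity model.

    Deterministic: identical scenarios (including seed) give bit-identical
    pools.
    """
    rng = np.random.default_rng(scenario.seed)
    n, k = scenario.n_compounds, scenario.n_clusters

    sizes = _cluster_sizes(n, k, scenario.cluster_size_dispersion, rng)

    # Per-cluster effects, sorted so that active clusters (lowest ids) carry
    # the largest effects, then standardized so the size-weighted population
    # sd is exactly cluster_effect_sd. With few clusters the raw sample sd of
    # the draws fluctuates heavily; pinning it keeps the pooled potency sd at
    # the scenario's nominal value regardless of n_clusters.
    effects = np.sort(rng.normal(0.0, 1.0, size=k))[::-1]
    weights = sizes / n
    effects = effects - float(weights @ effects)
    wsd = float(np.sqrt(weights @ effects**2))
    effects = (
        effects * (scenario.cluster_effect_sd / wsd) if wsd > 0 else np.zeros(k)
    )

    n_bits_cluster = scenario.core_bits_per_cluster + scenario.substituent_bits
    fingerprints = np.zeros((n, scenario.fingerprint_length), dtype=np.uint8)
    potency = np.empty(n)
    cluster_id = np.empty(n, dtype=int)

    row = 0
    for c in range(k):
        bits = rng.choice(scenario.fingerprint_length, size=n_bits_cluster, replace=False)
        core = bits[: scenario.core_bits_per_cluster]
        subs = bits[scenario.core_bits_per_cluster:]
        beta = rng.normal(0.0, scenario.substituent_effect_sd, size=len(subs))
        norm = float(np.sqrt(np.mean(beta**2))) if len(beta) else 0.0
        if norm > 0:
            beta *= scenario.substituent_effect_sd / norm
        m = sizes[c]
        include = rng.random((m, len(subs))) < 0.5
        block = slice(row, row + m)
        fingerprints[block][:, core] = 1
        for j, bit in enumerate(subs):
            fingerprints[block, bit] = include[:, j]
        potency[block] = (
            effects[c]
            + (include - 0.5) @ beta
            + rng.normal(0.0, scenario.residual_sd, size=m)
        )
        cluster_id[block] = c
        row += m

    width = len(str(n - 1))
    ids = np.array([f"S{i:0{width}d}" for i in range(n)])
    return CompoundPool(
        ids=ids, potency=potency, fingerprints=fingerprints, cluster_id=cluster_id
    )


def _cluster_sizes(n: int, k: int, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Cluster sizes summing to n; dispersion 0 gives a deterministic even split,
    otherwise a multinomial draw with Dirichlet-perturbed probabilities."""
    if dispersion == 0:
        base = np.full(k, n // k, dtype=int)
        base[: n % k] += 1
        return base
    probs = rng.dirichlet(np.full(k, 1.0 / dispersion))
    sizes = rng.multinomial(n, probs)
    # every cluster keeps at least one member
    while (sizes == 0).any():
        sizes[int(np.argmax(sizes))] -= 1
        sizes[int(np.argmin(sizes))] += 1
    return sizes


_PRESETS = {
    # few large scaffold clusters, top binders in the 1-2 strongest ones;
    # pooled potency sd ~ sqrt(1.1^2 + 30/4*0.3^2 + 0.3^2) = 1.41 pK units
    "congeneric": SyntheticScenario(
        n_compounds=2000,
        n_clusters=8,
        cluster_size_dispersion=0.3,
        core_bits_per_cluster=40,
        substituent_bits=30,
        cluster_effect_sd=1.1,
        substituent_effect_sd=0.30,
        residual_sd=0.30,
        active_cluster_fraction=0.25,
    ),
    # many congeneric series of 10-20 compounds each; pooled sd ~ 1.39
    "heterogeneous": SyntheticScenario(
        n_compounds=2250,
        n_clusters=150,
        cluster_size_dispersion=0.0,
        core_bits_per_cluster=20,
        substituent_bits=20,
        cluster_effect_sd=1.0,
        substituent_effect_sd=0.36,
        residual_sd=0.55,
        active_cluster_fraction=0.05,
    ),
    # small pool, weak cluster signal; pooled sd ~ 0.90
    "small-diverse": SyntheticScenario(
        n_compounds=600,
        n_clusters=60,
        cluster_size_dispersion=0.0,
        core_bits_per_cluster=12,
        substituent_bits=24,
        cluster_effect_sd=0.35,
        substituent_effect_sd=0.234,
        residual_sd=0.60,
        active_cluster_fraction=0.2,
    ),
}


def scenario_preset(name: str, **overrides) -> SyntheticScenario:
    """A named scenario preset; overrides replace individual fields."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}"
        )
    scenario = _PRESETS[name]
    return replace(scenario, **overrides) if overrides else scenario


def ddg_to_pki(
    ddg, dg_ref: float = DG_REF_DEFAULT, temperature: float = 298.15
):
    """Convert relative binding free energy (kJ/mol) to pKi.

    pKi = -(dG_ref + ddG) * 1000 / (R * T * ln 10); strictly decreasing and
    affine in ddG. Scalar in, scalar out; array in, array out.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    arr = np.asarray(ddg, dtype=float)
    if not np.all(np.isfinite(arr)) or not np.isfinite(dg_ref):
        raise ValueError("free energies must be finite")
    pki = -(dg_ref + arr) * 1000.0 / (GAS_CONSTANT * temperature * LN10)
    return float(pki) if np.isscalar(ddg) else pki


def read_pool_csv(
    path,
    potency_column: str = "pKi",
    conversion: Optional[str] = None,
    fingerprint_path=None,
) -> CompoundPool:
    """Read a compound pool from CSV (columns: id, optional smiles,
    the potency column, optional cluster_id).

    ``conversion="ddg_to_pki"`` applies the free-energy conversion row-wise.
    Fingerprints are read from ``fingerprint_path`` if given (one line of
    0/1 characters per compound, column order = bit index); otherwise the
    pool is returned without fingerprints for the caller to featurize.
    """
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    for col in ("id", potency_column):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    dupes = df["id"][df["id"].duplicated()]
    if len(dupes):
        raise ValueError(
            f"duplicate id {dupes.iloc[0]!r} at row {int(dupes.index[0])}"
        )
    potency = pd.to_numeric(df[potency_column], errors="coerce").to_numpy()
    bad = np.flatnonzero(~np.isfinite(potency))
    if len(bad):
        raise ValueError(
            f"non-numeric potency {df[potency_column].iloc[bad[0]]!r} "
            f"at row {int(bad[0])}"
        )
    if conversion is not None:
        if conversion != "ddg_to_pki":
            raise ValueError(f"unknown conversion {conversion!r}")
        potency = ddg_to_pki(potency)

    fingerprints = None
    if fingerprint_path is not None:
        fingerprints = read_fingerprints(fingerprint_path)
    return CompoundPool(
        ids=df["id"].to_numpy(),
        potency=potency,
        fingerprints=fingerprints,
        cluster_id=df["cluster_id"].to_numpy(dtype=int) if "cluster_id" in df else None,
        smiles=df["smiles"].to_numpy() if "smiles" in df else None,
    )


def write_pool_csv(pool: CompoundPool, path, fingerprint_path=None,
                   potency_column: str = "pKi") -> None:
    """Write a pool to CSV (and optionally its fingerprint matrix).

    Round-trips exactly: ids, potencies and fingerprints read back equal.
    """
    data = {"id": pool.ids}
    if pool.smiles is not None:
        data["smiles"] = pool.smiles
    data[potency_column] = pool.potency
    if pool.cluster_id is not None:
        data["cluster_id"] = pool.cluster_id
    pd.DataFrame(data).to_csv(path, index=False)
    if fingerprint_path is not None:
        if pool.fingerprints is None:
            raise ValueError("pool has no fingerprints to write")
        write_fingerprints(pool.fingerprints, fingerprint_path)


def write_fingerprints(fingerprints: np.ndarray, path) -> None:
    """One line of 0/1 characters per compound; column order = bit index."""
    with open(path, "w") as fh:
        for row in np.asarray(fingerprints, dtype=np.uint8):
            fh.write("".join("1" if b else "0" for b in row) + "\n")


def read_fingerprints(path) -> np.ndarray:
    lines = Path(path).read_text().splitlines()
    return np.array(
        [[1 if ch == "1" else 0 for ch in line] for line in lines], dtype=np.uint8
    )
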