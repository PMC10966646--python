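"""Hashed circular fingerprints and Tanimoto similarity.

Ligands are featurized as binary Morgan (ECFP-style) fingerprints: radius 4
(the diameter-8 "ECFP8" convention), hashed to 4096 bits by default. Exact bit
positions are implementation-defined by the hashing toolkit; downstream code
relies only on the bits being a deterministic function of the molecule.

Tanimoto similarity |u ∧ v| / |u ∨ v| doubles as the GP covariance kernel, so
the convention for two all-zero vectors is fixed at 1 to keep the kernel
diagonal constant (all-zero fingerprints are pathological and rejected with a
warning upstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator


@dataclass(frozen=True)
class FingerprintConfig:
    """Morgan fingerprint settings; defaults follow the ECFP8/4096-bit setup."""

    radius: int = 4
    n_bits: int = 4096
    use_chirality: bool = False

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if self.n_bits < 1:
            raise ValueError(f"n_bits must be >= 1, got {self.n_bits}")


def featurize_smiles(
    smiles: Sequence[str], config: FingerprintConfig | None = None
) -> np.ndarray:
    """Convert SMILES strings to an (n, n_bits) binary fingerprint matrix.

    Raises ValueError naming the offending string and position if any SMILES
    fails to parse. Rows depend only on the molecule and the config.
    """
    config = config or FingerprintConfig()
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius,
        fpSize=config.n_bits,
        includeChirality=config.use_chirality,
    )
    out = np.zeros((len(smiles), config.n_bits), dtype=np.uint8)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES at position {i}: {smi!r}")
        out[i] = np.asarray(gen.GetFingerprint(mol), dtype=np.uint8)
        if not out[i].any():
            warnings.warn(
                f"all-zero fingerprint at position {i} ({smi!r})", stacklevel=2
            )
    return out


def tanimoto(u: np.ndarray, v: np.ndarray) -> float:
    """Tanimoto similarity of two equal-length binary vectors, in [0, 1].

    tanimoto(0, 0) is defined as 1 (identical empty bit sets).
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    ub = u.astype(bool)
    vb = v.astype(bool)
    inter = int(np.count_nonzero(ub & vb))
    union = int(np.count_nonzero(ub)) + int(np.count_nonzero(vb)) - inter
    if union == 0:
        return 1.0
    return inter / union


def tanimoto_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto similarity between rows of X and rows of Y.

    Vectorized via bit-count identities: |u ∧ v| = u·v and
    |u ∨ v| = |u| + |v| − u·v for binary vectors. Rows where both popcounts
    are zero get similarity 1 (same convention as :func:`tanimoto`).
    """
    X = np.asarray(X)
    Y = np.asarray(Y)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"fingerprint length mismatch: {X.shape} vs {Y.shape}"
        )
    Xf = X.astype(np.float32)
    Yf = Y.astype(np.float32)
    # popcounts are exact small integers in float32; divide in float64
    inter = (Xf @ Yf.T).astype(np.float64)
    px = Xf.sum(axis=1, dtype=np.float64)
    py = Yf.sum(axis=1, dtype=np.float64)
    union = px[:, None] + py[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim
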