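"""Batch-selection strategies for active-learning cycles.

Three pure strategies: "random" draws uniformly without replacement,
"exploit" takes the candidates with the highest posterior mean (greedy on
predicted potency), "explore" takes the highest posterior variance (broad
sampling of uncertain chemical space). Exploration ranks by variance rather
than standard deviation — a monotone transform, so the selected batch is the
same. Ties are broken by ascending compound id so a request is a pure
function of its inputs (including the seed for "random").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .surrogate import SurrogatePosterior

STRATEGIES = ("random", "explore", "exploit")


@dataclass
class AcquisitionRequest:
    """One batch request over the unlabeled candidate pool.

    ``posterior`` holds per-candidate mean/variance aligned with
    ``candidate_ids``; it must be present iff the strategy consults the model
    ("explore"/"exploit").
    """

    strategy: str
    batch_size: int
    candidate_ids: Sequence
    posterior: Optional[SurrogatePosterior] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; one of {STRATEGIES}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.batch_size > len(self.candidate_ids):
            raise ValueError(
                f"batch_size {self.batch_size} exceeds candidate pool "
                f"({len(self.candidate_ids)})"
            )
        if self.strategy == "random":
            if self.posterior is not None:
                raise ValueError("random strategy takes no posterior")
        else:
            if self.posterior is None:
                raise ValueError(f"strategy {self.strategy!r} requires a posterior")
            if len(self.posterior.mean) != len(self.candidate_ids):
                raise ValueError("posterior length must match candidate_ids")


def select_batch(request: AcquisitionRequest) -> list:
    """Select exactly ``batch_size`` distinct candidate ids.

    "exploit": top batch_size by posterior mean; "explore": top batch_size by
    posterior variance; "random": uniform without replacement under the seed.
    Ties broken by ascending id.
    """
    ids = list(request.candidate_ids)
    k = request.batch_size
    if request.strategy == "random":
        rng = np.random.default_rng(request.seed)
        chosen = rng.choice(len(ids), size=k, replace=False)
        return [ids[i] for i in chosen]
    score = (
        request.posterior.mean
        if request.strategy == "exploit"
        else request.posterior.variance
    )
    ranked = sorted(range(len(ids)), key=lambda i: (-score[i], ids[i]))
    return [ids[i] for i in ranked[:k]]
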