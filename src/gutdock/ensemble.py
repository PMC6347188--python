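"""Model-ensemble bookkeeping: steric filtering and representative selection.

Mirrors the pipeline used for receptor-model ensembles: half of a large
homology-model ensemble (e.g. 3000 -> 1500, or 2000 MD snapshots -> 1000) is
discarded on steric-hindrance score, the survivors are clustered and scored
with a knowledge-based potential elsewhere, and the lowest-energy member of
each of the k largest clusters is carried forward to virtual screening.
Cluster labels and energies are inputs here, not computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import InputError
from .stericgrid import StericScore

__all__ = ["ModelRecord", "filter_by_steric", "select_representatives"]


@dataclass(frozen=True)
class ModelRecord:
    """One ensemble member: steric score plus externally supplied annotations."""

    model_id: str
    steric: StericScore
    energy: Optional[float] = None  # knowledge-based potential; lower = better
    cluster_label: Optional[int] = None

    def __post_init__(self):
        if self.energy is not None and not math.isfinite(self.energy):
            raise InputError(f"model {self.model_id!r}: non-finite energy")


def filter_by_steric(
    models: Iterable[ModelRecord], keep_fraction: float
) -> list[ModelRecord]:
    """Retain the least pocket-intruding fraction of an ensemble.

    Keeps the ``floor(keep_fraction * N)`` models with the lowest
    steric-hindrance scores; ties at the cutoff break by model id so reruns
    are deterministic. Input order is preserved among the retained models.
    """
    models = list(models)
    if not models:
        raise InputError("cannot filter an empty ensemble")
    if not 0 < keep_fraction <= 1:
        raise InputError(
            f"keep_fraction must be in (0, 1], got {keep_fraction}"
        )
    n_keep = math.floor(keep_fraction * len(models))
    ranked = sorted(models, key=lambda m: (m.steric.score, m.model_id))
    kept_ids = {m.model_id for m in ranked[:n_keep]}
    return [m for m in models if m.model_id in kept_ids]


def select_representatives(
    models: Iterable[ModelRecord], k: int
) -> list[ModelRecord]:
    """Lowest-energy member of each of the ``k`` most populous clusters.

    Cluster-size ties break toward the cluster with lower mean energy, then
    lower label; within a cluster, energy ties break by model id. If fewer
    than ``k`` clusters exist, all are represented and a warning is issued.
    """
    models = list(models)
    if not models:
        raise InputError("cannot select representatives from an empty ensemble")
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    for m in models:
        if m.cluster_label is None or m.energy is None:
            raise InputError(
                f"model {m.model_id!r} lacks a cluster label or energy"
            )
    clusters: dict[int, list[ModelRecord]] = {}
    for m in models:
        clusters.setdefault(m.cluster_label, []).append(m)
    if len(clusters) < k:
        warnings.warn(
            f"only {len(clusters)} clusters available, requested {k} "
            "representatives",
            stacklevel=2,
        )
    ordered = sorted(
        clusters.items(),
        key=lambda item: (
            -len(item[1]),
            sum(m.energy for m in item[1]) / len(item[1]),
            item[0],
        ),
    )
    return [
        min(members, key=lambda m: (m.energy, m.model_id))
        for _, members in ordered[:k]
    ]
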