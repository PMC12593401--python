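"""Ensemble-uncertainty active learning over n-mer orders.

The uncertainty of a cluster is σ = E_std/√N, where E_std is the sample
standard deviation of the ensemble's energy predictions and N the number
of atoms.  Within each n-mer order, clusters whose σ strictly exceeds
twice the median σ of that order's full pool are labelled by the teacher
and added to the training set; the ensemble is then retrained before the
next order is processed (dimers, then trimers, and so on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .potentials import (
    LabeledSample,
    RadialDescriptor,
    SurrogateModel,
    ensemble_predict,
    train_ensemble,
)

__all__ = [
    "UncertaintyRecord",
    "ALConfig",
    "ALState",
    "uncertainty",
    "select_uncertain",
    "label_with_teacher",
    "run_al",
]


@dataclass(frozen=True)
class UncertaintyRecord:
    nmer_id: int
    E_std: float  # eV
    N: int  # atoms
    sigma: float  # eV, E_std/sqrt(N)

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not math.isclose(self.sigma, self.E_std / math.sqrt(self.N),
                            rel_tol=1e-12, abs_tol=1e-15):
            raise ValueError("sigma must equal E_std/sqrt(N)")


@dataclass
class ALConfig:
    ensemble_size: int = 4
    subset_fraction: float = 0.8
    regularization: float = 1e-8
    force_weight: float = 0.1
    descriptor: RadialDescriptor | None = None


@dataclass
class ALState:
    training_pool: list[LabeledSample]
    ensemble: list[SurrogateModel]
    current_order: int
    history: list[dict] = field(default_factory=list)


def uncertainty(ensemble: list[SurrogateModel], nmer,
                nmer_id: int = 0) -> UncertaintyRecord:
    """σ = sample-std of ensemble energies over √(atom count)."""
    if not ensemble:
        raise ValueError("untrained (empty) ensemble")
    _, e_std, _ = ensemble_predict(ensemble, nmer)
    n_atoms = nmer.n_atoms if hasattr(nmer, "n_atoms") else len(nmer.symbols)
    return UncertaintyRecord(nmer_id, e_std, n_atoms,
                             e_std / math.sqrt(n_atoms))


def select_uncertain(records: list[UncertaintyRecord]) -> list[int]:
    """Ids with σ strictly above twice the median σ of the whole set."""
    if not records:
        raise ValueError("no uncertainty records")
    sigmas = np.array([r.sigma for r in records])
    threshold = 2.0 * float(np.median(sigmas))
    return [r.nmer_id for r in records if r.sigma > threshold]


def label_with_teacher(teacher, geometry, name: str = "teacher"
                       ) -> LabeledSample:
    e, f = teacher.energy_forces(geometry)
    return LabeledSample(geometry, e, f, teacher=name)


def run_al(teacher, monomer_seed_set: list[LabeledSample],
           nmer_pools_by_order: dict[int, list],
           config: ALConfig = ALConfig(), seed: int = 0,
           log=None) -> ALState:
    """Iterative per-order active learning.

    Starting from an ensemble trained on the monomer seed set, each cycle
    predicts the current order's pool, selects clusters with σ > 2·median(σ),
    labels them with the teacher, appends them to the pool, and retrains
    every ensemble member on an independent seeded subset.  Teacher failures
    skip the sample (logged) without aborting the run.
    """
    pool = list(monomer_seed_set)
    ensemble = train_ensemble(pool, seed=seed, n_models=config.ensemble_size,
                              subset_fraction=config.subset_fraction,
                              regularization=config.regularization,
                              descriptor=config.descriptor,
                              force_weight=config.force_weight)
    state = ALState(pool, ensemble, current_order=0)
    for cycle, order in enumerate(sorted(nmer_pools_by_order)):
        pool_n = nmer_pools_by_order[order]
        state.current_order = order
        records = [uncertainty(state.ensemble, g, i)
                   for i, g in enumerate(pool_n)]
        selected = select_uncertain(records)
        n_labelled = 0
        for i in selected:
            try:
                state.training_pool.append(label_with_teacher(teacher, pool_n[i]))
                n_labelled += 1
            except Exception as exc:  # teacher failure: skip and log
                if log is not None:
                    log(f"teacher failed on order-{order} sample {i}: {exc}")
        if n_labelled:
            state.ensemble = train_ensemble(
                state.training_pool, seed=seed + 1000 * (cycle + 1),
                n_models=config.ensemble_size,
                subset_fraction=config.subset_fraction,
                regularization=config.regularization,
                descriptor=config.descriptor,
                force_weight=config.force_weight)
        state.history.append({
            "order": order,
            "n_pool": len(pool_n),
            "n_selected": len(selected),
            "n_labelled": n_labelled,
            "median_sigma": float(np.median([r.sigma for r in records])),
        })
    return state
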