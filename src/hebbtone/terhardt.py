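"""Memoryless co-occurrence baseline (Terhardt-style).

Identical stimuli and accumulation rule as the Hebbian model, but increments
never depend on the accumulated weights: there is no feedback step, which is
exactly the ``kappa = 0`` parameterization of the main simulator.  The final
association state is therefore a pure co-occurrence count — independent of
presentation order, and linear in the number of repetitions — and a
mid-spectrum tone acquires weight only toward its direct harmonic partners
(the six most consonant in-octave intervals for 5-harmonic sounds).
"""

from __future__ import annotations

from dataclasses import replace

from .hebbnet import SynapticState, TrainingParams, train
from .lattice import ToneLattice
from .stimuli import AmplitudeSignature, SweepSchedule

__all__ = ["terhardt_train"]


def terhardt_train(
    lattice: ToneLattice,
    signature: AmplitudeSignature,
    schedule: SweepSchedule,
    params: TrainingParams = TrainingParams(),
    storage: str = "auto",
    innate_diag: float = 1.0,
    progress: bool = False,
) -> SynapticState:
    """Train the no-feedback baseline; entry-for-entry equal to ``train(kappa=0)``.

    Any ``kappa``/``propagation_floor`` in ``params`` is ignored (forced to
    the memoryless setting); the returned state is labelled
    ``model="terhardt"`` so saved artifacts identify the baseline.
    """
    memoryless = replace(params, kappa=0.0, propagation_floor=0.0)
    return train(
        lattice,
        signature,
        schedule,
        memoryless,
        storage=storage,
        innate_diag=innate_diag,
        model="terhardt",
        progress=progress,
    )
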