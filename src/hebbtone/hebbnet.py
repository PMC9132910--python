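"""Core Hebbian simulator: excitation, weight-mediated feedback, training loop.

The network is a single vector of tonal neural correlates joined by a
symmetric association matrix.  Presenting a stimulus excites the correlates
of its components; a single propagation step passes a fraction ``kappa`` of
each direct excitation through every already-strengthened synapse; the
Hebbian rule then increases the weight of every pair of co-excited correlates
by ``eta * total_i * total_j``.  The weights are the model's entire memory —
excitation is reset between presentations — and they only ever grow.

Two interchangeable weight stores are provided: a dense NumPy matrix for
small lattices (fast, vectorized) and a sparse dict-of-dicts keyed on touched
pairs for large ones (the 12,000-tone cent-resolution lattice would need
~1.2 GB dense).  ``train`` picks one automatically unless told otherwise.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .lattice import ToneLattice
from .stimuli import (
    AmplitudeSignature,
    HarmonicStimulus,
    SweepSchedule,
    build_stimulus,
    iter_base_indices,
)

__all__ = [
    "TrainingParams",
    "SynapticState",
    "DenseSynapticState",
    "SparseSynapticState",
    "ResourceGuardError",
    "excite",
    "propagate",
    "hebbian_update",
    "propagation_counts",
    "train",
]

logger = logging.getLogger(__name__)

#: Above this many lattice tones, ``storage="auto"`` switches to the sparse
#: store; an explicit dense request beyond the hard limit is refused.
DENSE_AUTO_LIMIT = 4096
DENSE_HARD_LIMIT = 16384


class ResourceGuardError(RuntimeError):
    """Refused allocation of a dense matrix beyond the configured size."""


@dataclass(frozen=True)
class TrainingParams:
    """Learning-rule constants.

    eta
        Hebbian learning rate (> 0).  Rescaling eta rescales all weight
        magnitudes of a given emergence order uniformly; rank orderings are
        the meaningful output.
    kappa
        Feedback transfer coefficient (>= 0): the fraction of a correlate's
        direct excitation passed through each strengthened synapse in the
        single propagation step.  ``kappa = 0`` disables feedback entirely
        and reduces the model to the memoryless co-occurrence baseline.
    propagation_floor
        Weights at or below this value do not propagate excitation.
    transfer
        How much excitation a strengthened synapse carries, as a fraction of
        ``kappa * direct_i``:

        ``"relative"`` (default)
            ``w / w_max``, the link weight relative to the current strongest
            Hebbian weight anywhere in the network.  Faint links conduct
            faintly for as long as they *are* faint relative to the
            well-established associations, so higher-order partners emerge
            slowly and with small magnitudes; the carry is bounded by 1, so
            excitations (and hence weight increments) stay bounded on
            arbitrarily long trains; and because only weight ratios enter
            the dynamics, the entire weight trajectory scales exactly
            linearly with eta (rank orderings are exactly eta-invariant).
        ``"gated"``
            1 for any link above the floor — the weight decides *whether*
            the link conducts, not how much.  Stable, but on long trains it
            equalizes all orders of emergence.
        ``"linear"``
            ``w`` itself.  Feeds the weights back into their own growth law
            and diverges super-exponentially on long trains; provided for
            small-scale exploration only.
    seed
        Recorded for provenance; randomness only enters via a shuffled
        schedule, which carries its own seed.
    """

    eta: float = 1.0
    kappa: float = 0.02
    propagation_floor: float = 0.0
    transfer: str = "relative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.propagation_floor < 0:
            raise ValueError("propagation_floor must be non-negative")
        if self.transfer not in ("relative", "gated", "linear"):
            raise ValueError(f"unknown transfer {self.transfer!r}")


class SynapticState:
    """Symmetric non-negative association matrix plus the innate diagonal.

    Off-diagonal entries are the Hebbian weights (initialized 0, monotonically
    growing, arbitrary units).  The diagonal synapse is innate and static: it
    simply carries direct excitation with gain ``innate_diag`` and is never
    part of the Hebbian sum.  Self-coincidence (the accumulated
    ``eta * total_i**2`` a correlate would assign to itself) is tracked
    separately so the unison can be ranked alongside real intervals.
    """

    n_tones: int
    innate_diag: float
    model: str

    # -- interface -------------------------------------------------------
    def weight(self, i: int, j: int) -> float:
        raise NotImplementedError

    def self_coincidence(self, i: int) -> float:
        raise NotImplementedError

    def neighbors(self, i: int) -> Iterator[tuple[int, float]]:
        raise NotImplementedError

    def iter_pairs(self) -> Iterator[tuple[int, int, float]]:
        """Yield (i, j, weight) with i < j, ascending, nonzero entries only."""
        raise NotImplementedError

    @property
    def nnz_pairs(self) -> int:
        raise NotImplementedError

    @property
    def max_weight(self) -> float:
        """Largest off-diagonal Hebbian weight (0 for an untrained state)."""
        raise NotImplementedError

    def apply_hebbian(self, total: dict[int, float], eta: float) -> None:
        raise NotImplementedError

    # -- common helpers --------------------------------------------------
    def _check_pair(self, i: int, j: int) -> None:
        if not (0 <= i < self.n_tones and 0 <= j < self.n_tones):
            raise IndexError(f"indices ({i}, {j}) outside [0, {self.n_tones})")


class SparseSynapticState(SynapticState):
    """Weights stored as touched (i, j) entries in a dict-of-dicts."""

    def __init__(self, n_tones: int, innate_diag: float = 1.0, model: str = "hebb"):
        self.n_tones = int(n_tones)
        self.innate_diag = float(innate_diag)
        self.model = model
        self._adj: dict[int, dict[int, float]] = {}
        self._self: dict[int, float] = {}
        self._wmax = 0.0

    def weight(self, i: int, j: int) -> float:
        self._check_pair(i, j)
        if i == j:
            return self.innate_diag
        return self._adj.get(i, {}).get(j, 0.0)

    def self_coincidence(self, i: int) -> float:
        return self._self.get(i, 0.0)

    def neighbors(self, i: int) -> Iterator[tuple[int, float]]:
        return iter(self._adj.get(i, {}).items())

    def iter_pairs(self) -> Iterator[tuple[int, int, float]]:
        for i in sorted(self._adj):
            row = self._adj[i]
            for j in sorted(row):
                if i < j and row[j] != 0.0:
                    yield i, j, row[j]

    @property
    def nnz_pairs(self) -> int:
        return sum(1 for i, row in self._adj.items() for j in row if i < j)

    @property
    def max_weight(self) -> float:
        return self._wmax

    def set_weight(self, i: int, j: int, value: float) -> None:
        """Direct assignment (used when loading saved weights)."""
        self._check_pair(i, j)
        if i == j:
            raise ValueError("the diagonal is innate-static; cannot assign")
        if value < 0:
            raise ValueError("weights are non-negative")
        self._adj.setdefault(i, {})[j] = value
        self._adj.setdefault(j, {})[i] = value
        self._wmax = max(self._wmax, value)

    def set_self_coincidence(self, i: int, value: float) -> None:
        self._self[i] = value

    def apply_hebbian(self, total: dict[int, float], eta: float) -> None:
        items = [(i, v) for i, v in total.items() if v > 0.0]
        for idx, (i, vi) in enumerate(items):
            self._self[i] = self._self.get(i, 0.0) + eta * vi * vi
            row_i = self._adj.setdefault(i, {})
            for j, vj in items[idx + 1:]:
                inc = eta * vi * vj
                w = row_i.get(j, 0.0) + inc
                row_i[j] = w
                row_j = self._adj.setdefault(j, {})
                row_j[i] = w
                if w > self._wmax:
                    self._wmax = w


class DenseSynapticState(SynapticState):
    """Weights in a dense symmetric NumPy matrix (diagonal held at zero)."""

    def __init__(self, n_tones: int, innate_diag: float = 1.0, model: str = "hebb"):
        if n_tones > DENSE_HARD_LIMIT:
            raise ResourceGuardError(
                f"dense storage refused for {n_tones} tones "
                f"(limit {DENSE_HARD_LIMIT}); use the sparse store"
            )
        self.n_tones = int(n_tones)
        self.innate_diag = float(innate_diag)
        self.model = model
        self.matrix = np.zeros((n_tones, n_tones), dtype=np.float64)
        self._self = np.zeros(n_tones, dtype=np.float64)
        self._wmax = 0.0

    def weight(self, i: int, j: int) -> float:
        self._check_pair(i, j)
        if i == j:
            return self.innate_diag
        return float(self.matrix[i, j])

    def self_coincidence(self, i: int) -> float:
        return float(self._self[i])

    def neighbors(self, i: int) -> Iterator[tuple[int, float]]:
        row = self.matrix[i]
        for j in np.nonzero(row)[0]:
            yield int(j), float(row[j])

    def iter_pairs(self) -> Iterator[tuple[int, int, float]]:
        ii, jj = np.nonzero(np.triu(self.matrix, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            yield i, j, float(self.matrix[i, j])

    @property
    def nnz_pairs(self) -> int:
        return int(np.count_nonzero(np.triu(self.matrix, k=1)))

    @property
    def max_weight(self) -> float:
        return self._wmax

    def apply_hebbian(self, total: dict[int, float], eta: float) -> None:
        idx = np.array([i for i, v in total.items() if v > 0.0], dtype=np.intp)
        if idx.size == 0:
            return
        vals = np.array([total[int(i)] for i in idx], dtype=np.float64)
        self._apply_hebbian_arrays(idx, vals, eta)

    def _apply_hebbian_arrays(self, idx: np.ndarray, vals: np.ndarray, eta: float) -> None:
        self._self[idx] += eta * vals * vals
        if idx.size > self.n_tones // 3:
            full = np.zeros(self.n_tones)
            full[idx] = vals
            self.matrix += eta * np.outer(full, full)
            self.matrix[idx, idx] = 0.0
        else:
            self.matrix[np.ix_(idx, idx)] += eta * np.outer(vals, vals)
            self.matrix[idx, idx] = 0.0
        if idx.size > 1:
            block_max = float(self.matrix[np.ix_(idx, idx)].max())
            if block_max > self._wmax:
                self._wmax = block_max

    def _propagate_arrays(
        self, idx: np.ndarray, vals: np.ndarray, params: "TrainingParams"
    ) -> np.ndarray:
        """Dense one-step propagation; returns the full total-excitation vector."""
        total = np.zeros(self.n_tones)
        total[idx] = vals
        if params.kappa > 0.0 and self._wmax > 0.0:
            cols = self.matrix[:, idx]
            if params.propagation_floor > 0.0:
                cols = np.where(cols > params.propagation_floor, cols, 0.0)
            if params.transfer == "relative":
                cols = cols / self._wmax
            elif params.transfer == "gated":
                cols = (cols > params.propagation_floor).astype(np.float64)
            total += params.kappa * (cols @ vals)
        return total


def excite(stimulus: HarmonicStimulus) -> dict[int, float]:
    """Direct excitation: the stimulus amplitude at each component correlate."""
    return {i: a for i, a in stimulus.components}


def propagate(
    state: SynapticState, direct: dict[int, float], params: TrainingParams
) -> dict[int, float]:
    """One feedback step through the strengthened synapses.

    Every synapse above the propagation floor conducts
    ``kappa * direct[i] * carry(w)``, where ``carry`` is the transfer law of
    ``params`` (relative ``w / w_max`` by default), so
    ``total[j] = direct[j] + kappa * sum_i direct[i] * carry(w[i, j])`` over
    i != j.  No cascading: propagated excitation does not itself propagate.
    With zero weights (or kappa = 0) the output equals the input.
    """
    if params.kappa == 0.0 or state.max_weight == 0.0:
        return dict(direct)
    total = dict(direct)
    for i, a in direct.items():
        for j, w in state.neighbors(i):
            if j != i and w > params.propagation_floor:
                if params.transfer == "relative":
                    carry = w / state.max_weight
                elif params.transfer == "gated":
                    carry = 1.0
                else:
                    carry = w
                total[j] = total.get(j, 0.0) + params.kappa * a * carry
    return total


def hebbian_update(state: SynapticState, total: dict[int, float], eta: float) -> SynapticState:
    """Strengthen every co-excited pair by ``eta * total_i * total_j`` (in place).

    Both directed entries (i, j) and (j, i) grow by the same amount; the
    diagonal is untouched (its self-coincidence is tracked separately).
    """
    if any(v < 0 for v in total.values()):
        raise ValueError("excitation must be non-negative (violated upstream contract)")
    state.apply_hebbian(total, eta)
    return state


def propagation_counts(
    state: SynapticState, direct: dict[int, float], params: TrainingParams
) -> dict[str, int]:
    """Count how far one propagation step reaches from a direct excitation.

    Returns both counting conventions for "additionally excited" correlates:
    ``directed_edges`` counts every (source, partner) link that carries
    excitation (partners shared by several sources count with multiplicity);
    ``distinct_new`` counts distinct correlates excited beyond the directly
    excited set.
    """
    directed = 0
    reached: set[int] = set()
    for i, a in direct.items():
        if a <= 0:
            continue
        for j, w in state.neighbors(i):
            if j != i and w > params.propagation_floor:
                directed += 1
                reached.add(j)
    return {
        "directed_edges": directed,
        "distinct_new": len(reached - {i for i, a in direct.items() if a > 0}),
    }


def train(
    lattice: ToneLattice,
    signature: AmplitudeSignature,
    schedule: SweepSchedule,
    params: TrainingParams = TrainingParams(),
    storage: str = "auto",
    innate_diag: float = 1.0,
    model: str = "hebb",
    progress: bool = False,
) -> SynapticState:
    """Run the full training loop and return the final synaptic state.

    For every presentation, in schedule order: reset excitation -> excite the
    stimulus components -> one propagation step through the current weights ->
    Hebbian update on the post-propagation totals.  Deterministic given the
    schedule (including its seed) and parameters.

    ``storage`` is ``"auto"`` (dense up to 4096 tones, sparse beyond),
    ``"dense"`` or ``"sparse"``; an explicit dense request above the hard
    limit raises :class:`ResourceGuardError`.
    """
    n = lattice.n_tones
    if storage == "auto":
        storage = "dense" if n <= DENSE_AUTO_LIMIT else "sparse"
    if storage not in ("dense", "sparse"):
        raise ValueError(f"unknown storage {storage!r}")

    state: SynapticState
    if storage == "dense":
        state = DenseSynapticState(n, innate_diag=innate_diag, model=model)
    else:
        state = SparseSynapticState(n, innate_diag=innate_diag, model=model)

    # Pre-snap one stimulus per base tone; the train reuses them.
    stim_cache: dict[int, HarmonicStimulus] = {}
    arr_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    per_sweep = n * schedule.repetitions
    presented = 0
    sweep_no = 1
    t0 = time.perf_counter()
    dense = isinstance(state, DenseSynapticState)
    for base in iter_base_indices(schedule, n):
        stim = stim_cache.get(base)
        if stim is None:
            stim = stim_cache[base] = build_stimulus(lattice, base, signature)
            if dense:
                arr_cache[base] = (
                    np.array(stim.indices, dtype=np.intp),
                    np.array(stim.amplitudes, dtype=np.float64),
                )
        if dense:
            idx, vals = arr_cache[base]
            total = state._propagate_arrays(idx, vals, params)
            nz = np.nonzero(total)[0]
            state._apply_hebbian_arrays(nz, total[nz], params.eta)
        else:
            direct = excite(stim)
            total_d = propagate(state, direct, params)
            state.apply_hebbian(total_d, params.eta)
        presented += 1
        if presented % per_sweep == 0:
            if progress:
                logger.info(
                    "sweep %d/%d done: %d presentations, %d nonzero weight pairs, %.1fs",
                    sweep_no, schedule.n_sweeps, presented, state.nnz_pairs,
                    time.perf_counter() - t0,
                )
            sweep_no += 1
    return state
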