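"""Harmonic-complex stimuli and the sweep schedule that trains the network.

Each stimulus is a base tone plus its integer harmonics ``k*f`` (k = 1..H)
with amplitudes in descending order, every partial snapped to the nearest
lattice tone.  A sweep presents one stimulus per lattice tone over the whole
spectrum, optionally repeated per sound and repeated over several sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .lattice import OutOfRangeError, ToneLattice, ratio_to_cents

__all__ = [
    "AmplitudeSignature",
    "HarmonicStimulus",
    "SweepSchedule",
    "build_stimulus",
    "generate_sweep",
    "sounds_containing",
    "iter_base_indices",
]


@dataclass(frozen=True)
class AmplitudeSignature:
    """Per-harmonic amplitudes (arbitrary units), one entry per k = 1..H.

    The default signature is a linear descent ``(H+1-k)/H`` — the base tone
    loudest, every higher harmonic strictly quieter — which realizes the
    "descending order of amplitudes" spectral shape the model assumes for
    natural harmonic sounds.  Any positive sequence is accepted so other
    spectral shapes can be explored.
    """

    amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.amplitudes) == 0:
            raise ValueError("amplitude signature must contain at least one harmonic")
        if any(a <= 0 for a in self.amplitudes):
            raise ValueError("all harmonic amplitudes must be positive")
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))

    @property
    def n_harmonics(self) -> int:
        return len(self.amplitudes)

    @property
    def is_descending(self) -> bool:
        return all(a > b for a, b in zip(self.amplitudes, self.amplitudes[1:]))

    @classmethod
    def linear(cls, n_harmonics: int = 5) -> "AmplitudeSignature":
        """Default descending signature: amplitude (H+1-k)/H for harmonic k."""
        if n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        h = n_harmonics
        return cls(tuple((h + 1 - k) / h for k in range(1, h + 1)))


@dataclass(frozen=True)
class HarmonicStimulus:
    """One complex sound: lattice indices and amplitudes of base tone + harmonics.

    Harmonics that would map above the lattice top are dropped, so stimuli
    near the top of the spectrum carry fewer than H components; the base tone
    is always present.
    """

    base_index: int
    components: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("a stimulus must contain at least its base tone")
        idx = [i for i, _ in self.components]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("component indices must be strictly increasing")

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(i for i, _ in self.components)

    @property
    def amplitudes(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.components)


@dataclass(frozen=True)
class SweepSchedule:
    """Presentation order of the training train.

    ``order`` is one of ``"ascending"``, ``"descending"`` or ``"shuffled"``
    (seed-reproducible permutation, re-drawn each sweep from one generator).
    Each base tone appears ``repetitions`` consecutive times per sweep; the
    repeated consecutive presentation of the same sound is what lets freshly
    adjusted weights feed back into the very next presentation.
    """

    order: str = "ascending"
    n_sweeps: int = 8
    repetitions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in ("ascending", "descending", "shuffled"):
            raise ValueError(f"unknown order {self.order!r}")
        if self.n_sweeps < 1 or self.repetitions < 1:
            raise ValueError("n_sweeps and repetitions must be positive integers")


def build_stimulus(
    lattice: ToneLattice, base_index: int, signature: AmplitudeSignature
) -> HarmonicStimulus:
    """Snap the harmonics of the base tone to the lattice.

    Harmonic k sits ``1200*log2(k)`` cents above the base and is represented
    by the nearest lattice tone; harmonics beyond the lattice top are dropped.
    The resulting cent offsets are independent of the base index (translation
    invariance on the log-frequency lattice) until clipping sets in.
    """
    base_cents = lattice.cents_of(base_index)
    components: list[tuple[int, float]] = []
    for k, amp in enumerate(signature.amplitudes, start=1):
        try:
            idx = lattice.nearest_index_cents(base_cents + ratio_to_cents(k, 1))
        except OutOfRangeError:
            break  # higher harmonics only go further above the top
        if components and idx <= components[-1][0]:
            raise ValueError(
                f"lattice resolution {lattice.resolution_cents} cents too coarse "
                f"to separate harmonics {k - 1} and {k}"
            )
        components.append((idx, amp))
    return HarmonicStimulus(base_index=base_index, components=tuple(components))


def iter_base_indices(schedule: SweepSchedule, n_tones: int) -> Iterator[int]:
    """Yield the base index of every presentation, across all sweeps.

    Length is ``n_tones * repetitions * n_sweeps``.  Shuffled order draws an
    independent permutation per sweep from a single seeded generator, so the
    whole train is reproducible from the schedule alone.
    """
    rng = np.random.default_rng(schedule.seed)
    for _ in range(schedule.n_sweeps):
        if schedule.order == "ascending":
            bases: Sequence[int] = range(n_tones)
        elif schedule.order == "descending":
            bases = range(n_tones - 1, -1, -1)
        else:
            bases = rng.permutation(n_tones).tolist()
        for base in bases:
            for _ in range(schedule.repetitions):
                yield int(base)


def generate_sweep(
    lattice: ToneLattice, signature: AmplitudeSignature, schedule: SweepSchedule
) -> list[HarmonicStimulus]:
    """The full training train as an ordered list of stimuli."""
    cache: dict[int, HarmonicStimulus] = {}
    train = []
    for base in iter_base_indices(schedule, lattice.n_tones):
        if base not in cache:
            cache[base] = build_stimulus(lattice, base, signature)
        train.append(cache[base])
    return train


def sounds_containing(
    lattice: ToneLattice, signature: AmplitudeSignature, target_index: int
) -> list[HarmonicStimulus]:
    """All stimuli whose component set includes ``target_index``.

    A mid-spectrum tone appears in exactly H sounds — once per divisor
    k = 1..H, as harmonic k of the base ``f/k``.  Near the bottom of the
    lattice some of those bases do not exist and fewer sounds are returned.
    """
    lattice._check_index(target_index)
    target_cents = lattice.cents_of(target_index)
    found: dict[int, HarmonicStimulus] = {}
    for k in range(1, signature.n_harmonics + 1):
        approx = (target_cents - ratio_to_cents(k, 1)) / lattice.resolution_cents
        for base in (math.floor(approx) - 1, math.floor(approx), math.floor(approx) + 1,
                     math.floor(approx) + 2):
            if not (0 <= base < lattice.n_tones) or base in found:
                continue
            stim = build_stimulus(lattice, base, signature)
            if target_index in stim.indices:
                found[base] = stim
    return [found[b] for b in sorted(found)]
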