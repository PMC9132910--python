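"""Tone-lattice geometry, cents/frequency arithmetic and reference interval tables.

The model discretizes the audible spectrum into a lattice of tones spaced
uniformly in cents (1 cent = 1/1200 of an octave).  Index 0 of the lattice is
anchored at C0, derived from concert pitch A4 = 440 Hz in equal temperament,
and every lattice index maps bijectively to a cent offset and a frequency.
All interval arithmetic in the package goes through the three conversion
functions defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "C0_HZ",
    "OutOfRangeError",
    "cents_to_freq",
    "freq_to_cents",
    "ratio_to_cents",
    "prime_limit",
    "is_five_limit",
    "ToneLattice",
    "ReferenceInterval",
    "reference_table",
]

#: C0 anchor: 440 Hz * 2**(-57/12)  (A4 = 440, equal temperament, C0 is 57
#: semitones below A4).  Evaluates to 16.35159783 Hz to the printed precision
#: of standard pitch tables.
C0_HZ: float = 440.0 * 2.0 ** (-57.0 / 12.0)


class OutOfRangeError(ValueError):
    """A frequency falls outside the lattice (caller decides whether to drop)."""


def cents_to_freq(f_ref: float, cents: float) -> float:
    """Frequency `cents` above (or below, if negative) the reference ``f_ref``.

    ``f_ref * 2 ** (cents / 1200)``.
    """
    if f_ref <= 0:
        raise ValueError(f"reference frequency must be positive, got {f_ref}")
    return f_ref * 2.0 ** (cents / 1200.0)


def freq_to_cents(f_ref: float, f: float) -> float:
    """Signed cent span from ``f_ref`` up to ``f``: ``1200*log2(f/f_ref)``."""
    if f_ref <= 0 or f <= 0:
        raise ValueError(f"frequencies must be positive, got f_ref={f_ref}, f={f}")
    return 1200.0 * math.log2(f / f_ref)


def ratio_to_cents(num: int, den: int) -> float:
    """Cent span of the frequency ratio ``num/den`` (e.g. 3/2 -> 701.955)."""
    if num <= 0 or den <= 0:
        raise ValueError(f"ratio terms must be positive, got {num}/{den}")
    return 1200.0 * math.log2(num / den)


def prime_limit(num: int, den: int) -> int:
    """Largest prime factor appearing in ``num`` or ``den`` (1/1 -> 1)."""
    largest = 1
    for value in (num, den):
        v = value
        p = 2
        while p * p <= v:
            while v % p == 0:
                largest = max(largest, p)
                v //= p
            p += 1
        if v > 1:
            largest = max(largest, v)
    return largest


def is_five_limit(num: int, den: int) -> bool:
    """True when all prime factors of ``num`` and ``den`` lie in {2, 3, 5}."""
    return prime_limit(num, den) <= 5


@dataclass(frozen=True)
class ToneLattice:
    """Uniform cent-spaced discretization of ``n_octaves`` octaves above ``f_ref``.

    Index ``n`` corresponds to ``n * resolution_cents`` cents above the anchor,
    so ``frequency(n) = f_ref * 2 ** (n * resolution_cents / 1200)``.  The
    number of lattice tones is ``n_octaves * 1200 / resolution_cents`` (12,000
    at the default 1-cent resolution over 10 octaves).
    """

    f_ref: float = C0_HZ
    resolution_cents: float = 1.0
    n_octaves: int = 10

    def __post_init__(self) -> None:
        if self.f_ref <= 0:
            raise ValueError("f_ref must be positive")
        if self.resolution_cents <= 0:
            raise ValueError("resolution_cents must be positive")
        if self.n_octaves <= 0:
            raise ValueError("n_octaves must be a positive integer")
        n = self.n_octaves * 1200.0 / self.resolution_cents
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "resolution_cents must divide the octave span evenly "
                f"({self.n_octaves * 1200} / {self.resolution_cents} is not integral)"
            )

    @property
    def n_tones(self) -> int:
        return round(self.n_octaves * 1200.0 / self.resolution_cents)

    @property
    def steps_per_octave(self) -> int:
        return round(1200.0 / self.resolution_cents)

    def cents_of(self, index: int) -> float:
        """Cent offset of lattice ``index`` above the anchor."""
        self._check_index(index)
        return index * self.resolution_cents

    def frequency(self, index: int) -> float:
        """Frequency in Hz of lattice ``index``."""
        self._check_index(index)
        return cents_to_freq(self.f_ref, index * self.resolution_cents)

    def nearest_index_cents(self, cents: float) -> int:
        """Nearest lattice index to a cent offset; ties break to the lower index.

        Raises :class:`OutOfRangeError` when the offset lies more than half a
        lattice step outside the spectrum.
        """
        x = cents / self.resolution_cents
        lo = math.floor(x)
        idx = lo if (x - lo) <= 0.5 else lo + 1
        if idx < 0 or idx >= self.n_tones:
            raise OutOfRangeError(
                f"{cents} cents is outside the lattice [0, {self.n_tones - 1}]"
            )
        return idx

    def nearest_index(self, f: float) -> int:
        """Nearest lattice index to frequency ``f`` (Hz); ties break lower."""
        return self.nearest_index_cents(freq_to_cents(self.f_ref, f))

    def _check_index(self, index: int) -> None:
        if not (0 <= index < self.n_tones):
            raise OutOfRangeError(
                f"index {index} outside lattice [0, {self.n_tones - 1}]"
            )


@dataclass(frozen=True)
class ReferenceInterval:
    """A named tuning-theory interval used as a comparison anchor.

    ``cents`` is always derived from the integer ratio; ``helmholtz_rank`` is
    the interval's position (1..13) in Helmholtz's consonance ordering where
    one is configured, and ``five_limit`` records whether the ratio factors
    entirely over the primes {2, 3, 5}.
    """

    name: str
    ratio_num: int
    ratio_den: int
    helmholtz_rank: Optional[int] = None
    cents: float = field(init=False)
    five_limit: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.ratio_num <= 0 or self.ratio_den <= 0:
            raise ValueError("ratio terms must be positive integers")
        object.__setattr__(self, "cents", ratio_to_cents(self.ratio_num, self.ratio_den))
        object.__setattr__(self, "five_limit", is_five_limit(self.ratio_num, self.ratio_den))


def _bundled_table_path():
    return resources.files("hebbtone").joinpath("data/reference_intervals.csv")


def reference_table(
    limit: Optional[int] = None, path: Optional[str] = None
) -> list[ReferenceInterval]:
    """Load the bundled (or a user-supplied) reference interval table.

    The bundled table holds the 5-limit Just Intonation intervals of one
    octave — including both major seconds (9/8, 10/9) and both minor sevenths
    (9/5, 16/9) — with Helmholtz consonance ranks attached to the thirteen
    classically ranked entries.  The CSV is user-editable; rows are validated
    on load (cents consistent with the ratio, five-limit flag consistent with
    the factorization).

    Parameters
    ----------
    limit
        If given, keep only intervals whose prime limit is <= ``limit``
        (e.g. ``limit=3`` keeps Pythagorean ratios only).
    path
        Optional CSV path overriding the bundled table.  Columns:
        ``name,num,den,cents,helmholtz_rank,five_limit``.
    """
    source = path if path is not None else _bundled_table_path()
    frame = pd.read_csv(source)
    intervals: list[ReferenceInterval] = []
    for row in frame.itertuples(index=False):
        rank = None if pd.isna(row.helmholtz_rank) else int(row.helmholtz_rank)
        interval = ReferenceInterval(
            name=str(row.name), ratio_num=int(row.num), ratio_den=int(row.den),
            helmholtz_rank=rank,
        )
        if abs(interval.cents - float(row.cents)) > 1e-9:
            raise ValueError(
                f"reference table row {row.name!r}: cents {row.cents} inconsistent "
                f"with ratio {row.num}/{row.den} ({interval.cents})"
            )
        if bool(row.five_limit) != interval.five_limit:
            raise ValueError(
                f"reference table row {row.name!r}: five_limit flag inconsistent "
                f"with factorization of {row.num}/{row.den}"
            )
        if limit is None or prime_limit(interval.ratio_num, interval.ratio_den) <= limit:
            intervals.append(interval)
    return intervals
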