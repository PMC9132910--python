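"""Interval profiles, partner classification and ranking comparison statistics.

After training, the model's "opinion" of an interval is the synaptic weight
between the tonic's correlate and the correlate a given cent span away.  This
module reads that row of the weight matrix into an :class:`IntervalProfile`,
ranks the spans by descending magnitude (the consonance proxy), splits the
ranking at the widest multiplicative gap into First-/Second-Order Partners,
and compares the emergent ordering against a reference consonance table with
Kendall's tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hebbnet import SynapticState, TrainingParams, train
from .lattice import ReferenceInterval, ToneLattice
from .stimuli import AmplitudeSignature, SweepSchedule

__all__ = [
    "IntervalProfile",
    "PartnerClassification",
    "RankAgreementReport",
    "SymmetryReport",
    "ResolutionInvarianceReport",
    "HarmonicSweepResult",
    "extract_profile",
    "count_emerged",
    "classify_partners",
    "compare_reference",
    "symmetry_report",
    "resolution_invariance",
    "harmonic_count_experiment",
]


@dataclass(frozen=True)
class IntervalProfile:
    """The tonic's signed-cent weight profile.

    ``spans`` are signed cent offsets from the tonic at lattice resolution;
    ``magnitudes`` the corresponding synaptic weights (the unison magnitude is
    the innate diagonal plus the tonic's accumulated self-coincidence, which
    makes the unison the top-ranked span of any trained state).
    """

    tonic_index: int
    resolution_cents: float
    spans: np.ndarray  # signed cents, ascending
    magnitudes: np.ndarray

    def magnitude_of(self, span: float) -> float:
        hit = np.isclose(self.spans, span)
        if not hit.any():
            raise KeyError(f"span {span} not in profile window")
        return float(self.magnitudes[hit][0])

    def ranking(self, lo: float = 0.0, hi: float = 1200.0) -> pd.DataFrame:
        """Spans in [lo, hi] with positive magnitude, ranked 1 = largest.

        Ties break deterministically: smaller ``|span|`` first, then positive
        before negative.
        """
        mask = (self.spans >= lo) & (self.spans <= hi) & (self.magnitudes > 0)
        spans = self.spans[mask]
        mags = self.magnitudes[mask]
        # lexsort: last key is primary
        order = np.lexsort((spans < 0, np.abs(spans), -mags))
        frame = pd.DataFrame(
            {"span_cents": spans[order], "magnitude": mags[order]}
        )
        frame.insert(0, "rank", np.arange(1, len(frame) + 1))
        return frame

    def emerged_spans(
        self, lo: float = 0.0, hi: float = 1200.0, epsilon: float = 0.0
    ) -> np.ndarray:
        mask = (self.spans >= lo) & (self.spans <= hi) & (self.magnitudes > epsilon)
        return self.spans[mask]


@dataclass(frozen=True)
class PartnerClassification:
    """Split of the in-octave ranking at the widest multiplicative gap."""

    boundary_rank: int
    first_order: tuple[float, ...]
    second_order: tuple[float, ...]
    gap_ratio: float
    degenerate: bool = False


@dataclass(frozen=True)
class RankAgreementReport:
    """Agreement between the emergent ranking and a reference consonance order."""

    rows: pd.DataFrame  # name, ref_rank, ref_cents, matched_span, emergent_rank, delta_cents
    top_k: int
    top_k_overlap: int
    kendall_tau: float
    n_matched: int


@dataclass(frozen=True)
class SymmetryReport:
    """Mirror comparison of the emerged spans below vs above the tonic."""

    set_symmetric: bool
    max_relative_asymmetry: float
    unmatched_spans: tuple[float, ...] = ()


@dataclass(frozen=True)
class ResolutionInvarianceReport:
    span_sets: dict[float, tuple[float, ...]]
    tolerance_cents: float
    invariant: bool
    flagged: bool = False


@dataclass(frozen=True)
class HarmonicSweepResult:
    profiles: dict[int, IntervalProfile]
    first_order_sets: dict[int, tuple[float, ...]]
    containment: dict[int, bool]  # H -> first_order(H-1) contained in emerged(H)


def extract_profile(
    state: SynapticState,
    lattice: ToneLattice,
    tonic_index: int,
    window: tuple[float, float] = (-1200.0, 1200.0),
) -> IntervalProfile:
    """Read the tonic's weight row over a signed-cent window (inclusive ends).

    The tonic should sit at least a window's width from both lattice edges
    (the analyses use C4, mid-spectrum); a boundary warning is issued
    otherwise and out-of-lattice spans are omitted.
    """
    lo, hi = window
    res = lattice.resolution_cents
    steps_lo = int(np.ceil(lo / res - 1e-9))
    steps_hi = int(np.floor(hi / res + 1e-9))
    tonic_cents = lattice.cents_of(tonic_index)
    top_cents = (lattice.n_tones - 1) * res
    if tonic_cents + lo < 0 or tonic_cents + hi > top_cents:
        warnings.warn(
            f"tonic at {tonic_cents} cents is within the {window} window of a "
            "lattice edge; out-of-range spans omitted",
            stacklevel=2,
        )
    spans: list[float] = []
    mags: list[float] = []
    for step in range(steps_lo, steps_hi + 1):
        j = tonic_index + step
        if not (0 <= j < lattice.n_tones):
            continue
        spans.append(step * res)
        if step == 0:
            mags.append(state.innate_diag + state.self_coincidence(tonic_index))
        else:
            mags.append(state.weight(tonic_index, j))
    return IntervalProfile(
        tonic_index=tonic_index,
        resolution_cents=res,
        spans=np.asarray(spans, dtype=np.float64),
        magnitudes=np.asarray(mags, dtype=np.float64),
    )


def count_emerged(profile: IntervalProfile, epsilon: float = 0.0) -> int:
    """Number of spans in [0, 1200] with magnitude above ``epsilon``."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    return int(profile.emerged_spans(0.0, 1200.0, epsilon).size)


def classify_partners(
    profile: IntervalProfile, max_rank: int = 30
) -> PartnerClassification:
    """Place the First-/Second-Order boundary at the largest adjacent magnitude
    ratio within the top ``max_rank`` in-octave ranks.

    First-Order Partners are the spans above the boundary — the intervals
    linked directly by co-sounding harmonics of single stimuli; everything
    below emerged only through feedback.  When all adjacent ratios are equal
    (a geometric magnitude sequence) the split is degenerate: the boundary
    falls after rank 1 and the result is flagged.
    """
    ranking = profile.ranking(0.0, 1200.0)
    if len(ranking) < 7:
        raise ValueError(
            f"classification unavailable: only {len(ranking)} emerged spans (need >= 7)"
        )
    mags = ranking["magnitude"].to_numpy()
    upto = min(max_rank, len(mags))
    ratios = mags[: upto - 1] / mags[1:upto]
    boundary = int(np.argmax(ratios)) + 1  # first occurrence wins ties
    degenerate = bool(np.allclose(ratios, ratios[0], rtol=1e-12, atol=0.0))
    spans = ranking["span_cents"].to_numpy()
    return PartnerClassification(
        boundary_rank=boundary,
        first_order=tuple(float(s) for s in np.sort(spans[:boundary])),
        second_order=tuple(float(s) for s in np.sort(spans[boundary:])),
        gap_ratio=float(ratios[boundary - 1]),
        degenerate=degenerate,
    )


def compare_reference(
    profile: IntervalProfile,
    reference: Sequence[ReferenceInterval],
    tolerance_cents: Optional[float] = None,
    top_k: Optional[int] = None,
) -> RankAgreementReport:
    """Match reference intervals to the emergent in-octave ranking.

    Each reference interval is matched within ``tolerance_cents`` (default:
    half the lattice resolution, the nearest-lattice rounding bound) to its
    strongest emerged representative — the candidate span with the best
    emergent rank, ties broken by cent distance — since lattice rounding can
    scatter an interval across adjacent spans of very different prominence.
    Kendall's tau-b is computed between the reference consonance ranks and
    the emergent ranks over the matched subset that carries a reference rank.
    """
    if tolerance_cents is None:
        tolerance_cents = profile.resolution_cents / 2.0
    if tolerance_cents < profile.resolution_cents / 2.0:
        raise ValueError("tolerance must be at least half the lattice resolution")
    if top_k is None:
        top_k = len(reference)
    ranking = profile.ranking(0.0, 1200.0)
    spans = ranking["span_cents"].to_numpy()
    rows = []
    for ref in reference:
        matched_span = np.nan
        emergent_rank: Optional[int] = None
        delta = np.nan
        if len(spans):
            d = np.abs(spans - ref.cents)
            candidates = np.nonzero(d <= tolerance_cents)[0]
            if candidates.size:
                # spans are already in rank order; ranks are unique, so the
                # first candidate is the strongest representative
                best = int(candidates[0])
                matched_span = float(spans[best])
                emergent_rank = int(ranking["rank"].iloc[best])
                delta = float(spans[best] - ref.cents)
        rows.append(
            {
                "name": ref.name,
                "ref_rank": ref.helmholtz_rank,
                "ref_cents": ref.cents,
                "matched_span": matched_span,
                "emergent_rank": emergent_rank,
                "delta_cents": delta,
            }
        )
    frame = pd.DataFrame(rows)
    matched = frame.dropna(subset=["emergent_rank"])
    overlap = int((matched["emergent_rank"] <= top_k).sum())
    ranked = matched.dropna(subset=["ref_rank"])
    if len(ranked) >= 2:
        tau = float(
            stats.kendalltau(
                ranked["ref_rank"].to_numpy(dtype=float),
                ranked["emergent_rank"].to_numpy(dtype=float),
            ).statistic
        )
    else:
        tau = float("nan")
    return RankAgreementReport(
        rows=frame,
        top_k=top_k,
        top_k_overlap=overlap,
        kendall_tau=tau,
        n_matched=int(len(matched)),
    )


def symmetry_report(
    state: SynapticState,
    lattice: ToneLattice,
    tonic_index: int,
    epsilon: float = 0.0,
) -> SymmetryReport:
    """Mirror symmetry of the emerged spans about the tonic.

    Compares the emerged sets {+c} vs {-c} over c in (0, 1200] and, where both
    sides emerged, the relative magnitude mismatch
    ``|m(+c) - m(-c)| / max(m(+c), m(-c))``.
    """
    if lattice.cents_of(tonic_index) < 1200 or (
        (lattice.n_tones - 1 - tonic_index) * lattice.resolution_cents < 1200
    ):
        raise ValueError("tonic must sit at least 1200 cents from both lattice edges")
    profile = extract_profile(state, lattice, tonic_index, window=(-1200.0, 1200.0))
    pos = {
        float(s): profile.magnitude_of(s)
        for s in profile.spans
        if s > 0 and profile.magnitude_of(s) > epsilon
    }
    neg = {
        float(-s): profile.magnitude_of(s)
        for s in profile.spans
        if s < 0 and profile.magnitude_of(s) > epsilon
    }
    unmatched = tuple(sorted(set(pos) ^ set(neg)))
    common = set(pos) & set(neg)
    max_asym = 0.0
    for c in common:
        a, b = pos[c], neg[c]
        max_asym = max(max_asym, abs(a - b) / max(a, b))
    return SymmetryReport(
        set_symmetric=(len(unmatched) == 0),
        max_relative_asymmetry=max_asym,
        unmatched_spans=unmatched,
    )


def resolution_invariance(
    profiles: dict[float, IntervalProfile], k_top: int = 6
) -> ResolutionInvarianceReport:
    """Do the top-k in-octave spans agree across lattice resolutions?

    Each profile's top-k spans are taken in exact cents; the sets are declared
    invariant when every span in every set has a partner within half the
    coarsest resolution in every other set.  If a profile has fewer than
    ``k_top`` emerged spans the verdict is computed on the smaller set and
    flagged.
    """
    tolerance = max(profiles) / 2.0
    flagged = False
    span_sets: dict[float, tuple[float, ...]] = {}
    for res, profile in profiles.items():
        ranking = profile.ranking(0.0, 1200.0)
        if len(ranking) < k_top:
            flagged = True
        span_sets[res] = tuple(ranking["span_cents"].head(k_top).tolist())
    sets = list(span_sets.values())
    invariant = True
    for a in sets:
        for b in sets:
            for s in a:
                if not any(abs(s - t) <= tolerance for t in b):
                    invariant = False
    return ResolutionInvarianceReport(
        span_sets=span_sets, tolerance_cents=tolerance, invariant=invariant,
        flagged=flagged,
    )


def harmonic_count_experiment(
    h_values: Iterable[int] = range(5, 11),
    resolution_cents: float = 10.0,
    n_octaves: int = 10,
    n_sweeps: int = 3,
    repetitions: int = 2,
    params: TrainingParams = TrainingParams(),
    tonic_index: Optional[int] = None,
    match_tolerance: Optional[float] = None,
) -> HarmonicSweepResult:
    """Rank the tonic's intervals for stimuli of H = 5..10 harmonics.

    Trains one model per harmonic count on the same lattice and schedule and
    checks the containment property: each H's First-Order (most consonant)
    spans reappear, within ``match_tolerance`` (default one lattice step, the
    bound for two-fold harmonic rounding), among the spans emerged with H+1
    harmonics.
    """
    from .lattice import ToneLattice  # local alias for signature clarity

    lattice = ToneLattice(resolution_cents=resolution_cents, n_octaves=n_octaves)
    if tonic_index is None:
        tonic_index = lattice.n_tones // 2  # mid-spectrum
    if match_tolerance is None:
        match_tolerance = resolution_cents
    schedule = SweepSchedule(order="ascending", n_sweeps=n_sweeps, repetitions=repetitions)
    profiles: dict[int, IntervalProfile] = {}
    first_order: dict[int, tuple[float, ...]] = {}
    for h in h_values:
        if not 1 <= h:
            raise ValueError(f"invalid harmonic count {h}")
        state = train(lattice, AmplitudeSignature.linear(h), schedule, params)
        profile = extract_profile(state, lattice, tonic_index)
        profiles[h] = profile
        first_order[h] = classify_partners(profile).first_order
    containment: dict[int, bool] = {}
    hs = sorted(profiles)
    for prev, cur in zip(hs, hs[1:]):
        emerged = profiles[cur].emerged_spans(0.0, 1200.0)
        containment[cur] = all(
            np.min(np.abs(emerged - s)) <= match_tolerance for s in first_order[prev]
        )
    return HarmonicSweepResult(
        profiles=profiles, first_order_sets=first_order, containment=containment
    )
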