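# Methods

## Model

The model is a minimal association-learning account of interval consonance.
A single layer of tonal neural correlates stands in for the paper-and-pencil
two-layer picture (layer 1 → layer 2 with a static one-to-one diagonal): since
the innate diagonal synapse only relays direct excitation and all read-outs
are the off-diagonal Hebbian weights, the two formulations are equivalent, and
the implementation keeps one correlate vector plus a symmetric weight matrix.

**Lattice.** Tones are spaced uniformly in cents, index *n* sitting
*n*·Δ cents above the anchor C0 = 440·2^(−57/12) Hz ≈ 16.35159783 Hz
(A4 = 440 equal temperament). Defaults: Δ = 1 cent, 10 octaves, 12,000 tones.
All frequency↔cents↔index conversions are exact closed forms; `nearest_index`
breaks exact midpoints toward the lower index so that results are
deterministic and byte-stable.

**Stimuli.** Each sound is a base tone plus harmonics *k·f*, *k* = 1…H
(H = 5 default, up to 10), each snapped to the nearest lattice tone in cents;
harmonics above the lattice top are dropped rather than clamped, because
clamping would concentrate spurious weight mass at the top edge. The default
amplitude signature is the linear descent (H+1−k)/H — base loudest, strictly
descending — which encodes the "natural harmonic sound" assumption; it is a
config parameter, and any positive signature can be supplied. A sweep presents
one sound per lattice tone; repetitions of a sound are consecutive (the reset
of excitation happens between *every* presentation, including between
repetitions — the weights are the only inter-presentation memory).

**Learning rule.** Per presentation: excite the components with the stimulus
amplitudes; run exactly one propagation step (no recurrent cascade — cascade
depth beyond 1 adds mechanism without being needed for any of the observed
effects); then strengthen every co-excited pair (i ≠ j) by η·tᵢ·tⱼ. Weights
are symmetric, non-negative, monotonically growing, unbounded, in arbitrary
units, stored in double precision. There is no decay, LTD, normalization of
the weights themselves, or saturation of the stored values.

**The feedback transfer law.** The propagation step is the design decision
that was genuinely open. The qualitative requirement is that correlates pass
a portion of their excitement through previously strengthened links, so that
intervals never co-sounding in one stimulus can still become associated
(second-order emergence). Three concrete laws were examined:

- *linear* (carry = w): the weights feed back into their own growth law;
  the increment grows like (κ·w·d)², i.e. w′ = w + c·w², which diverges in
  finite time and overflows double precision well within a desk-scale run.
  Kept as an option for short exploratory trains only.
- *gated* (carry = 1 for any link above the floor): stable, but a link
  conducts identically whether it is faint or strong, so within a few sweeps
  every order of emergence equalizes and the first/second-order magnitude
  gap disappears — contrary to the phenomenon being modelled.
- *relative* (carry = w / w_max, the default): each synapse conducts in
  proportion to its weight **relative to the strongest association in the
  network**. Faint links conduct faintly for as long as they are faint in
  relative terms, so emergence decays geometrically with order (the
  higher-order intervals appear with "most negligible" magnitudes); the
  carry is bounded by 1, so excitations and increments stay bounded on
  arbitrarily long trains; and because only weight *ratios* enter the
  dynamics, the entire trajectory is exactly homogeneous in η.

The relative law can be read as a homeostatic normalization of synaptic
efficacy: transmission strength is expressed on the scale of the strongest
learned association rather than in absolute units.

**Parameters.**

| parameter | default | units | role |
| --- | --- | --- | --- |
| Δ (`resolution_cents`) | 1 (analysis runs: 10) | cents | lattice spacing |
| H (`n_harmonics`) | 5 | — | harmonics per sound |
| `n_sweeps` | 8 (desk-scale runs: 3) | — | spectrum sweeps |
| `repetitions` | 2 | — | consecutive presentations per sound |
| η (`eta`) | 1.0 | arbitrary | learning rate; rescales all weights linearly, ranks invariant |
| κ (`kappa`) | 0.02 | — | feedback fraction; 0 disables feedback (baseline) |
| `propagation_floor` | 0 | weight units | minimum weight that conducts |
| `innate_diag` | 1.0 | weight units | static self-synapse gain |

κ sets the ratio between first- and second-order magnitudes. It was fixed
once by requiring the model to show the structure the model exists to
explain — a
wide multiplicative gap *between* the six first-order spans and the
second-order regime, with all the named second-order intervals present but
faint: at κ = 0.1 the second-order magnitudes crowd the weakest first-order
pair and the largest adjacent-ratio gap falls inside the first-order set; at
κ = 0.05 it falls below the second-order set; κ = 0.02 places the gap exactly
at rank 6 with a ≈6.6× drop. The value is not tuned per experiment.

**Unison handling.** The diagonal synapse is innate and static and never
enters the Hebbian sum. So that the unison can still be ranked alongside real
intervals (it heads every classical consonance ranking), the state tracks the
*self-coincidence* each correlate would accumulate (η·tᵢ² per presentation)
and reports `innate_diag + self_coincidence` as the span-0 magnitude. This
quantity provably dominates every pair weight (each pair increment tᵢtⱼ is
bounded by the larger of the two self increments, and the unison accumulates
over every presentation containing the tonic), so the unison is rank 1 in any
trained state and the octave leads the true intervals.

## Analysis conventions

- The interval profile is the tonic's weight row over a signed window
  (default ±1200 cents, both ends inclusive — 1201 spans at 1 cent, with
  in-octave counts taken over [0, 1200]).
  The analysis tonic is C4 (4800 cents), mid-spectrum, clear of edge effects.
- Ranking ties break deterministically: smaller |span| first, then positive
  before negative.
- The First/Second-Order boundary is the largest adjacent magnitude ratio
  within the top 30 ranks; a geometric (uniform-ratio) sequence is degenerate
  and flagged, with the boundary defaulting to the first pair.
- Reference matching tolerance defaults to half the lattice step for the raw
  operation (single-rounding bound); pipeline reports use one full step,
  because an emerged span is the *difference of two independently rounded*
  harmonic positions. Each reference interval is matched to the *strongest*
  emerged span within tolerance (ties by distance), not the cent-nearest:
  lattice rounding scatters an interval across adjacent spans of very
  different prominence, and the prominent span is the interval's emergent
  representative.
- Rank agreement uses Kendall's tau-b (scipy) restricted to the matched,
  consonance-ranked subset.
- Resolution invariance compares top-k span sets in exact cents with a
  tolerance of half the *coarsest* resolution in the comparison.

## Study conditions and what the tests show

The full-scale configuration (1-cent lattice, 8 sweeps, feedback on) is an
overnight computation (12,000 correlates, ~192,000 presentations with dense
propagation); it is supported through the sparse weight store but is not a
test condition. The tests and the acceptance script use:

- **First-sweep table**: full 12,000-tone 1-cent lattice, one sweep, one
  repetition, κ = 0 — the single-presentation pass isolates pure
  co-occurrence, the regime in which the first-sweep interval table is
  exact. The tonic's emerged offsets are exactly the 18 mirror-symmetric
  signed spans {±386, ±498, ±702, ±884, ±1200, ±1586, ±1902, ±2400, ±2786}.
- **Desk-scale feedback run**: 10-cent lattice, 3 sweeps, 2 repetitions,
  κ = 0.02 — small enough for the dense vectorized path (~1 minute), large
  enough to show the second-order emergence, the rank-6 magnitude gap, the
  τ ≈ 0.95 Helmholtz agreement, and the 5-limit character of the top ranks.
- **Resolution sweep**: the same schedule at 100/50/25/10 cents; top-6 span
  sets agree within half the coarsest step.

Note that with feedback on, within-sweep propagation already links distant
pairs during sweep 1 (consecutive repetitions conduct through weights updated
moments earlier), so sweep-1 weights are order-independent only at κ = 0, and
the in-octave emerged *count* saturates quickly at coarse resolutions (all
121 spans nonzero after one 10-cent sweep). The meaningful sweep-to-sweep
signal at desk scale is the magnitude structure, not the bare count; the
count properties tested are monotone non-decrease and the strict excess over
the six-interval no-feedback ceiling.

## What the generator does and does not emulate

All inputs are synthetic by design — the model's claim is about what emerges
from idealized harmonic sounds, not about fitting data. The stimulus
generator emulates: exact integer-harmonic complexes, strictly descending
spectral envelopes, uniform coverage of the spectrum, and noiseless
amplitudes. It does not emulate inharmonicity, spectral variability across
instruments or voices, loudness context, masking, or any statistics of real
musical corpora. Passing tests therefore demonstrate the *mechanism* —
co-occurrence plus weight-mediated feedback suffices to produce discrete,
Just-Intonation-dominated consonance rankings — and say nothing about how the
mechanism fares on ecological auditory input.

## Numerical choices

- Double precision throughout; the dense path uses vectorized outer-product
  updates (identical to the brute-force loop to ≤1e-9 relative; exact for
  integer-scaled amplitudes at κ = 0).
- Dense storage is selected automatically up to 4,096 tones (a 1200-tone
  matrix is ~11 MB); explicit dense requests are refused above 16,384 tones.
  The sparse store keys touched unordered pairs and mirrors them on read.
- Weight CSVs print floats with `repr` (shortest round-trip), giving
  byte-identical files for identical configurations.
- Degenerate inputs: empty signatures, non-positive amplitudes or
  frequencies, off-lattice tonics and uneven resolutions are rejected with
  explicit errors; harmonics that collide on an absurdly coarse lattice
  raise rather than merge.

## Known limitations

- The feedback transfer law is a contract-level reconstruction constrained
  by the required qualitative behaviour (stability, faint higher-order
  emergence, wide first/second-order gap), not a transcription of the
  original implementation's equations; absolute weight values are therefore
  not comparable across implementations — rank orderings are.
- In-octave emergence counts on long fine-resolution trains depend
  sensitively on the exact feedback constants and repetition count, so they
  are not comparable across implementations; this package reports its own
  counts with the parameterization printed alongside, and its desk-scale
  counts saturate quickly (see above).
- No inhibition, spike timing, LTD, or biophysical neuron detail; one
  correlate per frequency band.
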