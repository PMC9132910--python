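"""High-level run orchestration behind the command-line interface.

``run_simulate`` executes one full train-and-analyze pipeline and writes the
standard artifact set (weights triplet CSV + sidecar, ranked-interval CSV,
JSON report).  ``run_experiments`` drives the two comparative presets
(resolution sweep, harmonic-count sweep).  ``make_fixture`` emits tiny
deterministic assets for debugging and regression testing.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import analysis, io
from .config import ConfigError, RunConfig
from .hebbnet import train
from .lattice import reference_table
from .stimuli import generate_sweep
from .terhardt import terhardt_train

__all__ = ["run_simulate", "run_experiments", "make_fixture", "FIXTURES"]

logger = logging.getLogger(__name__)


def _train_for(config: RunConfig, progress: bool = True):
    lattice = config.lattice()
    signature = config.signature()
    schedule = config.schedule()
    params = config.params()
    if config.model == "terhardt":
        return lattice, terhardt_train(
            lattice, signature, schedule, params,
            storage=config.storage, progress=progress,
        )
    if config.model != "hebb":
        raise ConfigError(f"model: unknown model {config.model!r}")
    return lattice, train(
        lattice, signature, schedule, params,
        storage=config.storage, progress=progress,
    )


def run_simulate(config: RunConfig, progress: bool = True) -> dict[str, Any]:
    """Train per the config, analyze the tonic, write all artifacts.

    Returns a summary dict (also written as ``report.json``); artifact paths
    are under the returned ``"paths"`` key.
    """
    lattice, state = _train_for(config, progress=progress)
    tonic = config.tonic_index()
    window = (-config.window_cents, config.window_cents)
    profile = analysis.extract_profile(state, lattice, tonic, window=window)
    out = Path(config.out_dir)
    paths = io.save_state(state, out, config_echo=config.to_dict())

    ranked = _ranked_intervals_frame(profile, config)
    ranked_path = out / "ranked_intervals.csv"
    ranked.to_csv(ranked_path, index=False)
    paths["ranked_intervals"] = ranked_path

    report = _analysis_report(state, lattice, profile, config)
    report_path = io.write_report(report, out / "report.json")
    paths["report"] = report_path
    report["paths"] = {k: str(v) for k, v in paths.items()}
    return report


def _ranked_intervals_frame(profile, config: RunConfig) -> pd.DataFrame:
    refs = reference_table()
    ranking = profile.ranking(0.0, 1200.0)
    names, ref_cents, deltas, five = [], [], [], []
    for span in ranking["span_cents"]:
        nearest = min(refs, key=lambda r: abs(r.cents - span))
        names.append(nearest.name)
        ref_cents.append(nearest.cents)
        deltas.append(float(span - nearest.cents))
        five.append(nearest.five_limit)
    ranking = ranking.copy()
    ranking["nearest_reference_name"] = names
    ranking["reference_cents"] = ref_cents
    ranking["delta_cents"] = deltas
    ranking["five_limit"] = five
    return ranking


def _analysis_report(state, lattice, profile, config: RunConfig) -> dict[str, Any]:
    emerged = analysis.count_emerged(profile)
    tolerance = config.tolerance_cents
    if tolerance is None:
        # emerged spans are differences of two independently rounded harmonic
        # positions, so their deviation from just cents is bounded by one
        # full lattice step, not half
        tolerance = lattice.resolution_cents
    agreement = analysis.compare_reference(
        profile, reference_table(), tolerance_cents=tolerance, top_k=config.k_top
    )
    try:
        partners = analysis.classify_partners(profile)
        partner_block: Optional[dict[str, Any]] = {
            "boundary_rank": partners.boundary_rank,
            "first_order": list(partners.first_order),
            "gap_ratio": partners.gap_ratio,
            "degenerate": partners.degenerate,
        }
    except ValueError:
        partner_block = None
    try:
        sym = analysis.symmetry_report(state, lattice, profile.tonic_index)
        sym_block: Optional[dict[str, Any]] = {
            "set_symmetric": sym.set_symmetric,
            "max_relative_asymmetry": sym.max_relative_asymmetry,
        }
    except ValueError:
        sym_block = None
    return {
        "model": state.model,
        "emerged_in_octave": emerged,
        "nnz_weight_pairs": state.nnz_pairs,
        "partners": partner_block,
        "symmetry": sym_block,
        "kendall_tau": agreement.kendall_tau,
        "top_k_overlap": agreement.top_k_overlap,
        "n_reference_matched": agreement.n_matched,
        "config": config.to_dict(),
    }


def run_experiments(config: RunConfig, preset: str, progress: bool = True) -> dict[str, Any]:
    """Comparative presets: ``resolution_sweep`` or ``harmonic_sweep``."""
    if preset == "resolution_sweep":
        resolutions = (100.0, 50.0, 25.0, 10.0)
        profiles = {}
        for res in resolutions:
            member = replace(config, resolution_cents=res)
            lattice, state = _train_for(member, progress=progress)
            profiles[res] = analysis.extract_profile(
                state, lattice, member.tonic_index()
            )
        verdict = analysis.resolution_invariance(profiles, k_top=config.k_top)
        report = {
            "preset": preset,
            "resolutions": list(resolutions),
            "span_sets": {str(r): list(s) for r, s in verdict.span_sets.items()},
            "tolerance_cents": verdict.tolerance_cents,
            "invariant": verdict.invariant,
            "flagged": verdict.flagged,
            "config": config.to_dict(),
        }
    elif preset == "harmonic_sweep":
        result = analysis.harmonic_count_experiment(
            resolution_cents=config.resolution_cents,
            n_octaves=config.n_octaves,
            n_sweeps=config.n_sweeps,
            repetitions=config.repetitions,
            params=config.params(),
        )
        report = {
            "preset": preset,
            "first_order_sets": {str(h): list(s) for h, s in result.first_order_sets.items()},
            "containment": {str(h): bool(v) for h, v in result.containment.items()},
            "config": config.to_dict(),
        }
    else:
        raise ConfigError(f"unknown experiments preset {preset!r}")
    out = Path(config.out_dir)
    io.write_report(report, out / f"experiments_{preset}.json")
    return report


#: Registry of tiny deterministic fixtures.
FIXTURES: dict[str, RunConfig] = {
    "tiny-3oct": RunConfig(
        resolution_cents=100.0, n_octaves=3, n_harmonics=5,
        order="ascending", n_sweeps=1, repetitions=1,
        eta=1.0, kappa=0.02, model="hebb", storage="dense",
        tonic_cents=1800.0,
    ),
}


def make_fixture(name: str, out_dir: str | Path) -> dict[str, Path]:
    """Emit a small deterministic asset set for the named fixture.

    Writes the stimulus train (one row per presentation), the trained weights
    from the dense code path as ``expected_weights.csv``, and the fixture's
    config echo.  Regeneration is idempotent: identical bytes every time.
    """
    if name not in FIXTURES:
        raise ConfigError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    config = replace(FIXTURES[name], out_dir=str(out_dir))
    lattice = config.lattice()
    signature = config.signature()
    schedule = config.schedule()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    train_rows = []
    stimuli = generate_sweep(lattice, signature, schedule)
    per_sweep = lattice.n_tones * schedule.repetitions
    for pos, stim in enumerate(stimuli):
        train_rows.append(
            {
                "sweep": pos // per_sweep + 1,
                "position": pos % per_sweep,
                "base_index": stim.base_index,
                "component_indices": ";".join(str(i) for i in stim.indices),
                "component_amplitudes": ";".join(repr(a) for a in stim.amplitudes),
            }
        )
    train_path = out / "train.csv"
    pd.DataFrame(train_rows).to_csv(train_path, index=False)

    state = train(lattice, signature, schedule, config.params(), storage="dense")
    paths = io.save_state(state, out, config_echo=config.to_dict(), prefix="expected_weights")
    paths["train"] = train_path
    return paths
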