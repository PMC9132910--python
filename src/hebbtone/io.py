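"""Weight persistence and report writers.

Weights are saved as a sorted triplet CSV ``i,j,weight`` (i < j, ascending)
with a JSON sidecar echoing every run parameter, so two runs with the same
configuration produce byte-identical files.  The tonic's self-coincidence
values (needed to rank the unison on reload) go to a companion CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Optional

from .hebbnet import SparseSynapticState, SynapticState

__all__ = ["save_state", "load_state", "write_report"]


def _fmt(x: float) -> str:
    return repr(float(x))


def save_state(
    state: SynapticState,
    out_dir: str | Path,
    config_echo: Optional[dict[str, Any]] = None,
    prefix: str = "weights",
) -> dict[str, Path]:
    """Write ``<prefix>.csv``, ``<prefix>_self.csv`` and ``<prefix>.json``.

    Returns the paths written.  The sidecar records the model label, lattice
    size, innate diagonal and the caller's full config echo.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{prefix}.csv"
    self_path = out / f"{prefix}_self.csv"
    json_path = out / f"{prefix}.json"

    with open(csv_path, "w") as fh:
        fh.write("i,j,weight\n")
        for i, j, w in state.iter_pairs():
            fh.write(f"{i},{j},{_fmt(w)}\n")
    with open(self_path, "w") as fh:
        fh.write("i,self_coincidence\n")
        for i in range(state.n_tones):
            v = state.self_coincidence(i)
            if v != 0.0:
                fh.write(f"{i},{_fmt(v)}\n")
    sidecar = {
        "model": state.model,
        "n_tones": state.n_tones,
        "innate_diag": state.innate_diag,
        "nnz_pairs": state.nnz_pairs,
        "config": config_echo or {},
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"weights": csv_path, "self": self_path, "sidecar": json_path}


def load_state(
    weights_csv: str | Path, sidecar_json: str | Path
) -> tuple[SparseSynapticState, dict[str, Any]]:
    """Rebuild a sparse synaptic state from the triplet CSV + sidecar."""
    with open(sidecar_json) as fh:
        sidecar = json.load(fh)
    state = SparseSynapticState(
        n_tones=int(sidecar["n_tones"]),
        innate_diag=float(sidecar["innate_diag"]),
        model=str(sidecar.get("model", "hebb")),
    )
    with open(weights_csv) as fh:
        header = fh.readline()
        if header.strip() != "i,j,weight":
            raise ValueError(f"unexpected weights CSV header: {header!r}")
        for line in fh:
            i_s, j_s, w_s = line.rstrip("\n").split(",")
            state.set_weight(int(i_s), int(j_s), float(w_s))
    self_path = Path(weights_csv).with_name(Path(weights_csv).stem + "_self.csv")
    if self_path.exists():
        with open(self_path) as fh:
            fh.readline()
            for line in fh:
                i_s, v_s = line.rstrip("\n").split(",")
                state.set_self_coincidence(int(i_s), float(v_s))
    return state, sidecar


def write_report(report: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj: Any) -> Any:
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
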