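"""Plain-text formats: sequences, bitmaps, and model checkpoints.

* ``.seq.txt``  — one line per time step, ``N`` characters from ``{0,1}``;
  optional first line ``#N=<n> period=<p>``.
* ``.bmp.txt``  — a bitmap: ``R`` equal-length rows over ``{0,1}`` (``.``/``#``
  also accepted on read); columns map to time steps, rows to neurons
  (top row = neuron 0).
* checkpoint    — JSON carrying the architecture, the learnable parameters,
  optionally the dynamic state and optimiser accumulators, and the seeds
  used; round-trips bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import DynamicState, ModelStructure, Parameters, PatternSequence, init_state

CHECKPOINT_FORMAT = "dybm-checkpoint-1"


# -- sequences --------------------------------------------------------------

def write_sequence(path, seq: PatternSequence) -> None:
    lines = []
    header = f"#N={seq.n_neurons}"
    if seq.period is not None:
        header += f" period={seq.period}"
    lines.append(header)
    for row in seq.values:
        lines.append("".join("1" if v else "0" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_sequence(path) -> PatternSequence:
    text = Path(path).read_text()
    period = None
    n = None
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line.lstrip("#").split():
                key, _, val = tok.partition("=")
                if key == "N":
                    n = int(val)
                elif key == "period":
                    period = int(val)
            continue
        if not set(line) <= {"0", "1"}:
            raise ValueError(f"{path}:{lineno}: sequence lines must be over {{0,1}}")
        rows.append([int(c) for c in line])
    if rows and any(len(r) != len(rows[0]) for r in rows):
        raise ValueError(f"{path}: ragged sequence lines")
    values = np.array(rows, dtype=np.uint8) if rows else np.zeros((0, n or 0), dtype=np.uint8)
    if n is not None and values.size and values.shape[1] != n:
        raise ValueError(f"{path}: header says N={n} but lines have {values.shape[1]} bits")
    return PatternSequence(values, period)


# -- bitmaps ----------------------------------------------------------------

def write_bitmap(path, seq: PatternSequence) -> None:
    rows = seq.values.T  # row = neuron, column = time step
    Path(path).write_text(
        "\n".join("".join("1" if v else "0" for v in row) for row in rows) + "\n")


def read_bitmap(path) -> PatternSequence:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if not set(line) <= {"0", "1", ".", "#"}:
            raise ValueError(f"{path}:{lineno}: bitmap rows must be over 0/1 or ./#")
        rows.append([1 if c in "1#" else 0 for c in line])
    if not rows:
        return PatternSequence(np.zeros((0, 0), dtype=np.uint8))
    if any(len(r) != len(rows[0]) for r in rows):
        raise ValueError(f"{path}: ragged bitmap rows")
    return PatternSequence(np.array(rows, dtype=np.uint8).T)


# -- checkpoints ------------------------------------------------------------

@dataclass
class Checkpoint:
    structure: ModelStructure
    params: Parameters
    state: DynamicState | None = None
    optimizer: dict | None = None   # AdaGrad accumulators, if saved
    seeds: dict | None = None


def _state_to_dict(state: DynamicState) -> dict:
    return {
        "synaptic_trace": state.synaptic_trace.tolist(),
        "neural_trace": state.neural_trace.tolist(),
        "history": state.past_matrix().tolist(),  # lag-ordered, most recent first
        "clock": state.clock,
    }


def _state_from_dict(d: dict, structure: ModelStructure) -> DynamicState:
    state = init_state(structure)
    state.synaptic_trace[:] = np.asarray(d["synaptic_trace"], dtype=np.float64)
    state.neural_trace[:] = np.asarray(d["neural_trace"], dtype=np.float64)
    past = np.asarray(d["history"], dtype=np.float64)
    r_max = structure.history_depth
    idx = (0 - np.arange(r_max)) % r_max
    state.history[idx] = past
    state.history_pos = 0
    state.clock = int(d["clock"])
    return state


def save_checkpoint(path, structure: ModelStructure, params: Parameters,
                    state: DynamicState | None = None,
                    optimizer: dict | None = None,
                    seeds: dict | None = None) -> None:
    doc = {
        "format": CHECKPOINT_FORMAT,
        "structure": {
            "n_neurons": structure.n_neurons,
            "delays": structure.delays.tolist(),
            "synaptic_decay": structure.synaptic_decay.tolist(),
            "neural_decay": structure.neural_decay.tolist(),
            "temperature": structure.temperature,
        },
        "parameters": {
            "bias": params.bias.tolist(),
            "ltp_weight": params.ltp_weight.tolist(),
            "ltd_weight": params.ltd_weight.tolist(),
        },
        "state": _state_to_dict(state) if state is not None else None,
        "optimizer": ({k: np.asarray(val).tolist() for k, val in optimizer.items()}
                      if optimizer is not None else None),
        "seeds": seeds,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def load_checkpoint(path) -> Checkpoint:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(f"{path}: not a recognised checkpoint file")
    s = doc["structure"]
    structure = ModelStructure(
        s["n_neurons"], np.asarray(s["delays"], dtype=np.int64),
        np.asarray(s["synaptic_decay"]), np.asarray(s["neural_decay"]),
        s.get("temperature", 1.0),
    )
    p = doc["parameters"]
    params = Parameters(np.asarray(p["bias"]), np.asarray(p["ltp_weight"]),
                        np.asarray(p["ltd_weight"]))
    params.check_compatible(structure)
    state = _state_from_dict(doc["state"], structure) if doc.get("state") else None
    opt = doc.get("optimizer")
    if opt is not None:
        opt = {k: np.asarray(v, dtype=np.float64) for k, v in opt.items()}
    return Checkpoint(structure, params, state, opt, doc.get("seeds"))
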