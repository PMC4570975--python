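"""Scoring: per-step negative log-likelihood profiles and generation fidelity.

The anomaly score of a pattern is its negative log-likelihood under the
trained model given everything presented before it; scoring updates the
eligibility traces and FIFO queues (no learning), so the profile of a
sequence is exactly the chained decomposition of its total log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    DynamicState,
    ModelStructure,
    Parameters,
    PatternSequence,
    advance_state,
    init_state,
    log_likelihood_step,
)

__all__ = ["NllProfile", "nll_profile", "mismatch_count"]


@dataclass
class NllProfile:
    per_step: np.ndarray       # negative log-likelihood of each presented pattern
    clock_offsets: np.ndarray  # time indices scored (state clock at presentation)

    def __len__(self) -> int:
        return self.per_step.size

    @property
    def total(self) -> float:
        return float(self.per_step.sum())


def nll_profile(params: Parameters, structure: ModelStructure, seq: PatternSequence,
                initial_state: DynamicState | None = None) -> NllProfile:
    """Score each pattern of ``seq`` at temperature 1, advancing the state
    (but never the parameters) between steps.

    ``initial_state`` selects the protocol: ``None`` scores from a blank
    state, while passing the post-training live state continues the training
    dynamics.  The caller's state object is not modified (a copy is scored).
    """
    if len(seq) == 0:
        raise ValueError("cannot score an empty sequence")
    if seq.n_neurons != structure.n_neurons:
        raise ValueError("sequence and model disagree on the neuron count")
    state = init_state(structure) if initial_state is None else initial_state.copy()
    params.check_compatible(structure)
    nll = np.empty(len(seq))
    clocks = np.empty(len(seq), dtype=np.int64)
    for t in range(len(seq)):
        clocks[t] = state.clock
        nll[t] = -log_likelihood_step(seq.values[t], state, params, tau=1.0)
        advance_state(state, seq.values[t])
    return NllProfile(nll, clocks)


def mismatch_count(generated, target) -> int:
    """Hamming distance between two equally shaped binary sequences."""
    a = generated.values if isinstance(generated, PatternSequence) else np.asarray(generated)
    b = target.values if isinstance(target, PatternSequence) else np.asarray(target)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return int(np.sum(a != b))
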