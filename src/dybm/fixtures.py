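"""Experiment inputs, regenerated from scratch.

The alphabetical-image experiments encode text rendered in a 7-row by
5-column block font as a binary sequence: each bitmap column is the 7-bit
pattern of one moment, so "SCIENCE" becomes a periodic sequence of 35
patterns over 7 neurons.  The glyphs live in a packaged text file
(``data/font5x7.txt``) so that every bit-level target is stable.

Also provides the random generators used across the experiments and tests:
densely connected architectures with uniform integer conduction delays,
Gaussian parameter initialisation, and Bernoulli test sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .model import ModelStructure, Parameters, PatternSequence

__all__ = [
    "GlyphFont",
    "default_font",
    "render_text",
    "mirror_sequence",
    "make_anomalous_science",
    "random_structure",
    "random_parameters",
    "random_sequence",
    "named_streams",
    "science_sequence",
    "forward_cue",
    "reverse_cue",
]

DEFAULT_DECAY = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class GlyphFont:
    """Map from character to an equal-sized binary bitmap (rows x columns)."""

    glyphs: dict

    def __post_init__(self):
        shapes = {g.shape for g in self.glyphs.values()}
        if len(shapes) > 1:
            raise ValueError("all glyphs must share one bitmap size")

    @property
    def n_rows(self) -> int:
        return next(iter(self.glyphs.values())).shape[0]

    @property
    def n_cols(self) -> int:
        return next(iter(self.glyphs.values())).shape[1]

    def __getitem__(self, char: str) -> np.ndarray:
        try:
            return self.glyphs[char]
        except KeyError:
            raise KeyError(f"font has no glyph for {char!r}") from None


def _parse_font(text: str) -> GlyphFont:
    glyphs = {}
    name = None
    rows = []
    for line in text.splitlines() + [""]:
        line = line.rstrip()
        if line.startswith(";"):  # comment ('#' is a glyph pixel)
            continue
        if not line:
            if name is not None and rows:
                bitmap = np.array([[1 if c in "1#" else 0 for c in r] for r in rows],
                                  dtype=np.uint8)
                bitmap.flags.writeable = False
                glyphs[name] = bitmap
            name, rows = None, []
            continue
        if name is None:
            name = line
        else:
            rows.append(line)
    return GlyphFont(glyphs)


@lru_cache(maxsize=1)
def default_font() -> GlyphFont:
    """The packaged 5x7 block font (letters S, C, I, E, N)."""
    text = resources.files("dybm").joinpath("data/font5x7.txt").read_text()
    return _parse_font(text)


def render_text(text: str, font: GlyphFont | None = None) -> PatternSequence:
    """Render ``text`` column-wise: time step ``t`` is bitmap column ``t``,
    neuron ``j`` is row ``j`` (top row first); the period is the total
    column count."""
    font = font or default_font()
    if not text:
        return PatternSequence(np.zeros((0, font.n_rows), dtype=np.uint8))
    columns = np.concatenate([font[c].T for c in text], axis=0)  # (T, N)
    return PatternSequence(columns, period=columns.shape[0])


def mirror_sequence(seq: PatternSequence) -> PatternSequence:
    """Time-reverse the sequence (mirror image of the rendered text)."""
    return PatternSequence(seq.values[::-1].copy(), seq.period)


def make_anomalous_science(font: GlyphFont | None = None) -> PatternSequence:
    """The 70-column anomaly-detection input "SCIENSESCIENCE": the second
    "C" of the first "SCIENCE" is replaced by "S" (columns 25-29)."""
    return render_text("SCIENSESCIENCE", font)


def science_sequence(font: GlyphFont | None = None) -> PatternSequence:
    """The canonical 7x35 "SCIENCE" target."""
    return render_text("SCIENCE", font)


def forward_cue(font: GlyphFont | None = None) -> PatternSequence:
    """Prefix cue for the forward sequence: "SCIEN" (25 columns)."""
    cue = render_text("SCIEN", font)
    return PatternSequence(cue.values, period=None)


def reverse_cue(font: GlyphFont | None = None) -> PatternSequence:
    """Prefix cue for the reverse sequence: the mirror image of "IENCE"
    (25 columns), i.e. the first 25 columns of the reversed target."""
    cue = mirror_sequence(render_text("IENCE", font))
    return PatternSequence(cue.values, period=None)


def random_structure(n_neurons: int, delay_low: int = 1, delay_high: int = 9,
                     rng: np.random.Generator | None = None,
                     synaptic_decay=DEFAULT_DECAY,
                     neural_decay=DEFAULT_DECAY) -> ModelStructure:
    """Densely connected architecture (self-connections included) with
    i.i.d. uniform integer conduction delays on [delay_low, delay_high]."""
    if not 1 <= delay_low <= delay_high:
        raise ValueError("need 1 <= delay_low <= delay_high")
    rng = rng or np.random.default_rng()
    delays = rng.integers(delay_low, delay_high + 1, size=(n_neurons, n_neurons))
    return ModelStructure(n_neurons, delays, np.asarray(synaptic_decay),
                          np.asarray(neural_decay))


def random_parameters(structure: ModelStructure, mean: float = 0.0, sd: float = 0.1,
                      rng: np.random.Generator | None = None) -> Parameters:
    """Every learnable scalar i.i.d. Normal(mean, sd)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = rng or np.random.default_rng()
    n, k, l = structure.n_neurons, structure.n_synaptic_traces, structure.n_neural_traces
    return Parameters(rng.normal(mean, sd, n),
                      rng.normal(mean, sd, (n, n, k)),
                      rng.normal(mean, sd, (n, n, l)))


def random_sequence(n_neurons: int, n_steps: int, density: float,
                    rng: np.random.Generator | None = None) -> PatternSequence:
    """i.i.d. Bernoulli(density) binary sequence for tests."""
    if not 0 <= density <= 1:
        raise ValueError("density must lie in [0, 1]")
    rng = rng or np.random.default_rng()
    return PatternSequence((rng.random((n_steps, n_neurons)) < density).astype(np.uint8))


def named_streams(seed: int) -> dict:
    """Independent, reproducible RNG streams for the distinct sources of
    randomness: delay sampling, parameter initialisation, and stochastic
    sampling.  One master seed fixes them all."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("delays", "params", "sampling")
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}
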