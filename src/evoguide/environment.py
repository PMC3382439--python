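"""Temporal logic-gate environments.

Two binary environmental signals ``s1`` and ``s2`` are emitted as square
pulses within a repeating epoch.  Nutrient presence is a *delayed* boolean
function of the two signals — one of the gates AND, OR, A (= s1 AND NOT s2),
B (= NOT s1 AND s2) or XOR — so that cells can only anticipate nutrients by
processing the signals through their regulatory networks.  One epoch is 4,500
discrete time steps and the delay defaults to 500 steps.

The default waveform places three equal pulses of width 500 inside each
epoch, with signal levels (s1, s2) = (1, 0), (0, 1) and (1, 1).  Under this
waveform the five gates produce 1 (AND), 3 (OR), 1 (A), 1 (B) and 2 (XOR)
nutrient pulses per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GATES",
    "SignalWaveformSpec",
    "EnvironmentSpec",
    "EnvironmentTrace",
    "generate_signals",
    "gate_output",
    "environment_trace",
    "environment_similarity",
    "default_waveform",
    "default_environments",
    "similarity_matrix",
]

GATES = ("AND", "OR", "A", "B", "XOR")

#: truth tables, indexed by (s1, s2)
_GATE_TABLES = {
    "AND": np.array([[0, 0], [0, 1]], dtype=np.int8),
    "OR": np.array([[0, 1], [1, 1]], dtype=np.int8),
    "A": np.array([[0, 0], [1, 0]], dtype=np.int8),  # s1 AND NOT s2
    "B": np.array([[0, 1], [0, 0]], dtype=np.int8),  # NOT s1 AND s2
    "XOR": np.array([[0, 1], [1, 0]], dtype=np.int8),
}

DEFAULT_EPOCH_LENGTH = 4500
DEFAULT_DELAY = 500
DEFAULT_PULSE_WIDTH = 500
#: (start, s1 level, s2 level) for the three default pulses
DEFAULT_PULSES = ((500, 1, 0), (1750, 0, 1), (3000, 1, 1))


class ZeroVarianceError(ValueError):
    """A correlation was requested on a constant sequence."""


@dataclass(frozen=True)
class SignalWaveformSpec:
    """Pulse-train description of the two signals within one epoch.

    Parameters
    ----------
    epoch_length : int
        Number of time steps per epoch.
    pulse_width : int
        Width (steps) of every pulse window.
    pulse_starts : sequence of (start, s1_level, s2_level)
        Non-overlapping windows, sorted by start, each within the epoch.
        Outside all windows both signals are 0.
    """

    epoch_length: int = DEFAULT_EPOCH_LENGTH
    pulse_width: int = DEFAULT_PULSE_WIDTH
    pulse_starts: tuple = field(default_factory=lambda: DEFAULT_PULSES)

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        prev_end = -1
        for start, lv1, lv2 in self.pulse_starts:
            if start < 0 or start + self.pulse_width > self.epoch_length:
                raise ValueError(
                    f"pulse window [{start}, {start + self.pulse_width}) lies "
                    f"outside the epoch [0, {self.epoch_length})"
                )
            if start <= prev_end:
                raise ValueError("pulse windows must be sorted and non-overlapping")
            if lv1 not in (0, 1) or lv2 not in (0, 1):
                raise ValueError("signal levels must be binary")
            prev_end = start + self.pulse_width - 1


@dataclass(frozen=True)
class EnvironmentSpec:
    """A gate identity plus delay applied to a signal waveform."""

    gate: str
    delay: int = DEFAULT_DELAY
    waveform: SignalWaveformSpec = field(default_factory=SignalWaveformSpec)

    def __post_init__(self) -> None:
        if self.gate not in GATES:
            raise ValueError(f"unknown gate {self.gate!r}; expected one of {GATES}")
        if not 0 <= self.delay < self.waveform.epoch_length:
            raise ValueError("delay must satisfy 0 <= delay < epoch_length")


@dataclass(frozen=True)
class EnvironmentTrace:
    """Per-time-step environment state over one epoch.

    ``nutrient[t] = nutrient_unshifted[t - delay]`` for ``t >= delay`` and 0
    before; there is no wrap-around within an epoch.  Shifting ``nutrient``
    back by ``delay`` recovers the undelayed gate output (``N_shifted``),
    which is what the information metrics pair with the signals.
    """

    s1: np.ndarray
    s2: np.ndarray
    nutrient: np.ndarray
    nutrient_unshifted: np.ndarray
    gate: str = "?"
    delay: int = 0

    @property
    def epoch_length(self) -> int:
        return len(self.s1)


def generate_signals(spec: SignalWaveformSpec) -> tuple[np.ndarray, np.ndarray]:
    """Expand a waveform spec into binary s1 and s2 sequences."""
    s1 = np.zeros(spec.epoch_length, dtype=np.int8)
    s2 = np.zeros(spec.epoch_length, dtype=np.int8)
    for start, lv1, lv2 in spec.pulse_starts:
        s1[start : start + spec.pulse_width] = lv1
        s2[start : start + spec.pulse_width] = lv2
    return s1, s2


def gate_output(gate: str, s1, s2):
    """Truth-table value of ``gate`` on binary inputs (scalar or array)."""
    if gate not in _GATE_TABLES:
        raise ValueError(f"unknown gate {gate!r}; expected one of {GATES}")
    table = _GATE_TABLES[gate]
    out = table[np.asarray(s1, dtype=np.intp), np.asarray(s2, dtype=np.intp)]
    if np.isscalar(s1) or np.ndim(s1) == 0:
        return int(out)
    return out


def environment_trace(spec: EnvironmentSpec) -> EnvironmentTrace:
    """Generate the full environment trace for one epoch.

    The gate is applied pointwise to the signals and the result is shifted
    forward by ``spec.delay`` steps, zero-padding the start of the epoch.
    """
    s1, s2 = generate_signals(spec.waveform)
    unshifted = gate_output(spec.gate, s1, s2).astype(np.int8)
    nutrient = np.zeros_like(unshifted)
    if spec.delay == 0:
        nutrient[:] = unshifted
    else:
        nutrient[spec.delay :] = unshifted[: -spec.delay]
    return EnvironmentTrace(
        s1=s1,
        s2=s2,
        nutrient=nutrient,
        nutrient_unshifted=unshifted,
        gate=spec.gate,
        delay=spec.delay,
    )


def environment_similarity(env_a: EnvironmentTrace, env_b: EnvironmentTrace) -> float:
    """Pearson correlation between the nutrient-presence traces of two environments."""
    a = np.asarray(env_a.nutrient, dtype=float)
    b = np.asarray(env_b.nutrient, dtype=float)
    if a.shape != b.shape:
        raise ValueError("nutrient traces must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ZeroVarianceError(
            "nutrient trace has zero variance; similarity is undefined"
        )
    return float(np.corrcoef(a, b)[0, 1])


def default_waveform() -> SignalWaveformSpec:
    """The package's default three-pulse waveform."""
    return SignalWaveformSpec()


def default_environments(
    delay: int = DEFAULT_DELAY,
    waveform: SignalWaveformSpec | None = None,
    gates: Sequence[str] = GATES,
) -> dict[str, EnvironmentTrace]:
    """Traces for the five default environments keyed by gate name."""
    wf = waveform if waveform is not None else default_waveform()
    return {
        g: environment_trace(EnvironmentSpec(gate=g, delay=delay, waveform=wf))
        for g in gates
    }


def similarity_matrix(traces: dict[str, EnvironmentTrace]):
    """Pairwise nutrient-presence Pearson correlations as a nested dict."""
    names = list(traces)
    return {
        a: {b: environment_similarity(traces[a], traces[b]) for b in names}
        for a in names
    }


def pulse_count(sequence: np.ndarray) -> int:
    """Number of contiguous runs of 1s in a binary sequence."""
    x = np.asarray(sequence, dtype=np.int8)
    if len(x) == 0:
        return 0
    rises = int(x[0] == 1) + int(np.sum((x[1:] == 1) & (x[:-1] == 0)))
    return rises
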