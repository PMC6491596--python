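"""Burst statistics and synchrony measures for simulated spike trains.

The simulator's oscillation vocabulary is operationalised here: a *burst* is
a maximal run of firing steps separated by at most ``max_gap`` silent steps;
the *inter-burst interval* is the onset-to-onset spacing in milliseconds;
and ensemble synchrony is summarised by a phase-coherence order parameter
``R``: each neuron is assigned a phase that interpolates linearly between
its bracketing burst onsets, and ``R`` is the magnitude of the ensemble mean
of ``exp(i * phase)`` (1 = perfect synchrony, 0 = incoherence).  ``R`` is
this package's quantitative stand-in for raster-based synchrony judgements;
the underlying model makes no reference to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError

__all__ = [
    "BurstTrain",
    "detect_bursts",
    "inter_burst_intervals",
    "order_parameter",
    "order_parameter_trace",
    "resynchronization_time",
    "NO_RECOVERY",
]

#: Sentinel returned when the order parameter never regains its baseline.
NO_RECOVERY = float("nan")


@dataclass(frozen=True)
class BurstTrain:
    """Burst onsets (time steps, 0-based) and durations (steps) of one train."""

    onsets: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    durations: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int)
    )

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=int)
        durations = np.asarray(self.durations, dtype=int)
        if onsets.shape != durations.shape:
            raise DomainError("onsets and durations must have equal length")
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise DomainError("burst onsets must be strictly increasing")
        if np.any(durations < 1):
            raise DomainError("burst durations must be >= 1")
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)

    def __len__(self) -> int:
        return len(self.onsets)


def detect_bursts(spike_train: np.ndarray, max_gap: int = 2) -> BurstTrain:
    """Group spikes into bursts, merging runs separated by short gaps.

    Parameters
    ----------
    spike_train : 1-d binary array
    max_gap : int
        Silent stretches of at most this many steps are absorbed into the
        surrounding burst.

    Returns
    -------
    BurstTrain
        Onset = index of the first spike of each burst; duration = last
        spike index - first spike index + 1.
    """
    if max_gap < 0:
        raise DomainError("max_gap must be >= 0")
    spikes = np.flatnonzero(np.asarray(spike_train) > 0)
    if len(spikes) == 0:
        return BurstTrain()
    breaks = np.flatnonzero(np.diff(spikes) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(spikes) - 1]))
    onsets = spikes[starts]
    durations = spikes[ends] - spikes[starts] + 1
    return BurstTrain(onsets=onsets, durations=durations)


def inter_burst_intervals(bursts: BurstTrain, dt_ms: float) -> np.ndarray:
    """Successive burst-onset differences in milliseconds.

    Returns an empty array when fewer than two bursts were detected.
    """
    if len(bursts) < 2:
        return np.array([])
    return np.diff(bursts.onsets).astype(float) * dt_ms


def _phase_at(bursts: BurstTrain, t: int) -> float | None:
    """Linear-interpolation phase in [0, 2pi) at step t, or None if t is not
    bracketed by two onsets."""
    onsets = bursts.onsets
    if len(onsets) < 2 or t < onsets[0] or t >= onsets[-1]:
        return None
    k = int(np.searchsorted(onsets, t, side="right")) - 1
    last, nxt = onsets[k], onsets[k + 1]
    return 2.0 * np.pi * (t - last) / (nxt - last)


def order_parameter(bursts_per_neuron: list[BurstTrain], t: int) -> float:
    """Phase-coherence order parameter ``R`` across neurons at step ``t``.

    Neurons without bracketing bursts around ``t`` are excluded; with fewer
    than two includable neurons the value is undefined and reported as NaN.
    """
    phases = [
        p for p in (_phase_at(b, t) for b in bursts_per_neuron) if p is not None
    ]
    if len(phases) < 2:
        return float("nan")
    z = np.exp(1j * np.asarray(phases)).mean()
    return float(abs(z))


def order_parameter_trace(
    bursts_per_neuron: list[BurstTrain], n_steps: int
) -> np.ndarray:
    """``order_parameter`` evaluated at every step ``0 .. n_steps-1``."""
    return np.array(
        [order_parameter(bursts_per_neuron, t) for t in range(n_steps)]
    )


def resynchronization_time(
    r_trace: np.ndarray,
    baseline: float,
    t_offset: int,
    dt_ms: float,
    sustain_steps: int = 25,
    threshold_frac: float = 0.9,
) -> float:
    """Time for ``R`` to regain its pre-stimulus level after a perturbation.

    Parameters
    ----------
    r_trace : array
        Order-parameter trace (may contain NaN where undefined).
    baseline : float
        Pre-stimulus synchrony level (e.g. mean R over a pre-stimulus
        window).
    t_offset : int
        Step at which the perturbation ended; recovery is sought at
        ``t >= t_offset``.
    dt_ms : float
        Milliseconds per step, for the returned value.
    sustain_steps : int
        R must stay above threshold for this many consecutive steps (about
        one intrinsic cycle) before recovery is declared.
    threshold_frac : float
        Recovery threshold as a fraction of baseline.

    Returns
    -------
    float
        ``(first sustained recovery step - t_offset) * dt_ms``, or
        ``NO_RECOVERY`` (NaN) if the trace never recovers.
    """
    if t_offset < 0 or t_offset >= len(r_trace):
        raise DomainError("t_offset outside the trace")
    thr = threshold_frac * baseline
    above = np.asarray(r_trace) >= thr  # NaN compares False
    run = 0
    for t in range(t_offset, len(r_trace)):
        run = run + 1 if above[t] else 0
        if run >= sustain_steps:
            return float(t - sustain_steps + 1 - t_offset) * dt_ms
    return NO_RECOVERY
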