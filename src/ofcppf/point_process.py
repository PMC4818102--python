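"""Log-linear point-process encoding model of motor cortical spiking.

Spikes are binned in intervals of width ``delta`` small enough to contain
at most one spike, giving a binary time series per unit.  Each unit's
instantaneous rate is log-linear in 2D velocity,

    lambda_c(v) = exp(beta_c + alpha_c . v) = exp([1, v'] phi_c),

equivalent to a cosine tuning curve with preferred direction angle(alpha),
modulation depth ||alpha|| and baseline rate exp(beta).  Units are
conditionally independent given velocity, so the ensemble likelihood of a
binary observation vector is a product of Bernoulli-like point-process
terms (lambda*Delta)^N exp(-lambda*Delta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "TuningDescription",
    "SpikeEvents",
    "conditional_intensity",
    "tuning_from_params",
    "params_from_tuning",
    "bin_spikes",
    "sample_spikes",
    "log_likelihood",
]

#: Cap on the per-bin spike probability lambda*Delta; keeps the Bernoulli
#: approximation of the point process valid and the filters stable.
P_MAX = 0.98

#: Observed clipped-bin fraction above which binning warns (multi-spike bins
#: should be rare when delta is well chosen).
CLIP_WARN_FRACTION = 0.006


@dataclass(frozen=True)
class NeuronParams:
    """One unit's tuning parameters ``phi = [beta, alpha_x, alpha_y]``."""

    baseline: float  # beta, log spikes/s
    velocity_coeffs: np.ndarray  # alpha, per cm/s

    @property
    def phi(self) -> np.ndarray:
        return np.concatenate([[self.baseline], np.asarray(self.velocity_coeffs, dtype=float)])


@dataclass(frozen=True)
class TuningDescription:
    """Polar view of a unit's tuning."""

    preferred_direction: float  # radians in (-pi, pi]
    modulation_depth: float  # ||alpha||
    baseline_rate: float  # exp(beta), spikes/s
    tuned: bool = True


@dataclass
class SpikeEvents:
    """Binary spike events, one row per unit, one column per bin."""

    events: np.ndarray  # C x T, uint8 in {0,1}
    bin_width: float  # delta, s
    unit_ids: list = field(default_factory=list)
    clipped_count: int = 0

    def __post_init__(self):
        self.events = np.asarray(self.events)
        if self.events.ndim == 1:
            self.events = self.events[None, :]
        if not self.unit_ids:
            self.unit_ids = list(range(self.events.shape[0]))

    @property
    def n_units(self) -> int:
        return self.events.shape[0]

    @property
    def n_bins(self) -> int:
        return self.events.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width


def _phi_matrix(params) -> np.ndarray:
    """Stack an ensemble (or single unit) into a C x 3 parameter matrix."""
    if isinstance(params, NeuronParams):
        return params.phi[None, :]
    if isinstance(params, np.ndarray):
        return np.atleast_2d(params)
    return np.stack([p.phi for p in params])


def conditional_intensity(params, velocity: np.ndarray, delta: float | None = None) -> np.ndarray:
    """Rate ``exp([1, v'] phi)`` in spikes/s (scalar for a single unit).

    The exponent is capped so the per-bin probability never exceeds
    ``P_MAX``; pass ``delta`` to apply the cap on the lambda*Delta scale
    (without it, a 5 ms default scale is used).
    """
    phi = _phi_matrix(params)
    v = np.asarray(velocity, dtype=float)
    exponent = phi[:, 0] + phi[:, 1:] @ v
    d = delta if delta is not None else 0.005
    np.clip(exponent, None, np.log(P_MAX / d), out=exponent)
    rate = np.exp(exponent)
    if isinstance(params, NeuronParams):
        return float(rate[0])
    return rate


def tuning_from_params(params: NeuronParams) -> TuningDescription:
    """Convert ``phi`` to preferred direction, modulation depth, baseline rate."""
    alpha = np.asarray(params.velocity_coeffs, dtype=float)
    depth = float(np.linalg.norm(alpha))
    if depth == 0.0:
        return TuningDescription(0.0, 0.0, float(np.exp(params.baseline)), tuned=False)
    theta = float(np.arctan2(alpha[1], alpha[0]))
    return TuningDescription(theta, depth, float(np.exp(params.baseline)))


def params_from_tuning(
    preferred_direction: float,
    modulation_depth: float,
    baseline_rate: float,
) -> NeuronParams:
    """Inverse of :func:`tuning_from_params`."""
    alpha = modulation_depth * np.array(
        [np.cos(preferred_direction), np.sin(preferred_direction)]
    )
    return NeuronParams(baseline=float(np.log(baseline_rate)), velocity_coeffs=alpha)


def bin_spikes(spike_times, delta: float, duration: float, unit_ids=None) -> SpikeEvents:
    """Bin per-unit sorted spike times into binary events.

    Bin k covers ``[k*delta, (k+1)*delta)``; a bin is 1 iff at least one
    spike falls in it.  Bins that would hold more than one spike are
    clipped to 1 and counted in ``clipped_count``; a warning fires when
    the clipped fraction of occupied bins exceeds 0.6%.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if isinstance(spike_times, np.ndarray) and spike_times.ndim == 1:
        spike_times = [spike_times]
    n_bins = int(np.ceil(duration / delta - 1e-12))
    events = np.zeros((len(spike_times), n_bins), dtype=np.uint8)
    clipped = 0
    total_spikes = 0
    for c, times in enumerate(spike_times):
        t = np.asarray(times, dtype=float)
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError(f"spike times for unit index {c} are not sorted")
        if t.size and (t[0] < 0 or t[-1] >= duration):
            raise ValueError(f"spike times for unit index {c} outside [0, duration)")
        total_spikes += t.size
        idx = np.floor(t / delta).astype(int)
        counts = np.bincount(idx, minlength=n_bins)
        clipped += int(np.sum(np.maximum(counts - 1, 0)))
        events[c] = (counts > 0).astype(np.uint8)
    occupied = int(events.sum())
    if occupied and clipped / max(total_spikes, 1) > CLIP_WARN_FRACTION:
        warnings.warn(
            f"{clipped} of {total_spikes} spikes fell in already-occupied bins "
            f"(> {CLIP_WARN_FRACTION:.1%}); consider a smaller bin width",
            stacklevel=2,
        )
    return SpikeEvents(
        events=events,
        bin_width=delta,
        unit_ids=list(unit_ids) if unit_ids is not None else [],
        clipped_count=clipped,
    )


def sample_spikes(
    params,
    velocity_trajectory: np.ndarray,
    delta: float,
    rng,
) -> SpikeEvents:
    """Draw Bernoulli spike events from the encoding model along a trajectory.

    Each bin draws independently with success probability
    ``min(lambda_c(v_t) * delta, P_MAX)``.
    """
    rng = np.random.default_rng(rng)
    phi = _phi_matrix(params)
    v = np.atleast_2d(np.asarray(velocity_trajectory, dtype=float))  # T x 2
    exponent = phi[:, 0][:, None] + phi[:, 1:] @ v.T  # C x T
    p = np.minimum(np.exp(exponent) * delta, P_MAX)
    events = (rng.random(p.shape) < p).astype(np.uint8)
    return SpikeEvents(events=events, bin_width=delta)


def log_likelihood(events: SpikeEvents, velocity_trajectory: np.ndarray, params) -> float:
    """Point-process log likelihood ``sum_c sum_t [N log(lambda*D) - lambda*D]``.

    Returns ``-inf`` when a spike lands in a bin with zero predicted rate.
    """
    phi = _phi_matrix(params)
    v = np.atleast_2d(np.asarray(velocity_trajectory, dtype=float))
    N = events.events
    if N.shape[0] != phi.shape[0] or N.shape[1] != v.shape[0]:
        raise ValueError("events, velocities and parameters have inconsistent shapes")
    exponent = phi[:, 0][:, None] + phi[:, 1:] @ v.T
    np.clip(exponent, None, np.log(P_MAX / events.bin_width), out=exponent)
    lam_d = np.exp(exponent) * events.bin_width
    with np.errstate(divide="ignore"):
        log_lam_d = np.log(lam_d)
    if np.any((N == 1) & ~np.isfinite(log_lam_d)):
        return float("-inf")
    return float(np.sum(np.where(N == 1, log_lam_d, 0.0)) - np.sum(lam_d))
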