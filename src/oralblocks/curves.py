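"""Time-intensity release curves and their two-phase parameterization.

A nosespace recording tracks the in-nose intensity of one volatile
compound while a subject eats. The curve is split at the first swallow
into a chewing phase and a post-swallowing phase that ends when the
signal returns to baseline. Each phase is summarized by its area under
the curve (quantity released), maximum intensity, time of maximum, and
release rate; together with the phase-area ratio these form the nine
response variables of the multiblock analysis.

Conventions: input time axes are in seconds with t = 0 at mouth entry;
reported times are in minutes and rates in a.u./min. Times of maxima
are measured from mouth entry for both phases. Areas are computed by
the trapezoid rule above baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_SECONDS_PER_MINUTE = 60.0


@dataclass
class ReleaseCurve:
    """One time-intensity recording with its first-swallow annotation.

    ``time`` (s) must be strictly increasing; ``swallow_time`` (s) must
    fall strictly inside the recording. ``baseline`` is the resting
    signal level (a.u.), typically the pre-consumption mean.
    """

    time: np.ndarray
    intensity: np.ndarray
    swallow_time: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise ValueError("a release curve needs at least 2 samples")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not (self.time[0] < self.swallow_time < self.time[-1]):
            raise ValueError("swallow_time must lie strictly inside the recording")

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass
class ReleaseParameters:
    """The nine per-curve response variables.

    Areas in a.u.·min, intensities in a.u., times in minutes from mouth
    entry, rates in a.u./min. NaN flags a quantity that is undefined for
    the curve at hand (e.g. the phase maximum never rises above
    baseline, or the post-swallow area is zero so the ratio is
    undefined).
    """

    A1: float = math.nan
    A2: float = math.nan
    A1_over_A2: float = math.nan
    Imax1: float = math.nan
    Tmax1: float = math.nan
    rate1: float = math.nan
    Imax2: float = math.nan
    Tmax2: float = math.nan
    rate2: float = math.nan

    #: Output column names, matching the response-block schema.
    COLUMNS = (
        "A1", "A2", "A1/A2",
        "Imax1", "Tmax1", "Imax1/Tmax1",
        "Imax2", "Tmax2", "Imax2/Tmax2",
    )

    def to_row(self) -> dict[str, float]:
        vals = (
            self.A1, self.A2, self.A1_over_A2,
            self.Imax1, self.Tmax1, self.rate1,
            self.Imax2, self.Tmax2, self.rate2,
        )
        return dict(zip(self.COLUMNS, vals))


def smooth_curve(curve: ReleaseCurve, window: int) -> ReleaseCurve:
    """Centered moving average to suppress breathing oscillations.

    The window shrinks symmetrically near the boundaries (edge
    truncation), so constants are preserved exactly and the time axis
    and annotations are unchanged. ``window`` must be odd; 1 is the
    identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd sample count")
    if window == 1:
        return ReleaseCurve(
            curve.time.copy(), curve.intensity.copy(), curve.swallow_time, curve.baseline
        )
    half = window // 2
    n = curve.n_samples
    smoothed = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        smoothed[i] = curve.intensity[i - k : i + k + 1].mean()
    return ReleaseCurve(curve.time.copy(), smoothed, curve.swallow_time, curve.baseline)


def detect_baseline_return(
    curve: ReleaseCurve, epsilon: float, k: int = 3
) -> float:
    """Earliest post-swallow time at which the signal stays within
    ``baseline ± epsilon`` for ``k`` consecutive samples.

    The scan starts only after the post-swallow signal has risen above
    baseline + epsilon, so the shallow onset of the second release phase
    is not mistaken for an immediate return. If the signal never rises,
    the second phase is empty and the first post-swallow sample's time
    is returned. Falls back to the recording end time (with a logged
    warning) when the signal never settles back.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    post = np.nonzero(curve.time > curve.swallow_time)[0]
    if len(post) == 0:
        return float(curve.time[-1])
    within = np.abs(curve.intensity - curve.baseline) <= epsilon
    risen = np.nonzero(
        (curve.intensity > curve.baseline + epsilon) & (curve.time > curve.swallow_time)
    )[0]
    if len(risen) == 0:
        return float(curve.time[post[0]])
    for i in post[post >= risen[0]]:
        if i + k <= curve.n_samples and within[i : i + k].all():
            return float(curve.time[i])
    logger.warning(
        "signal never returned to baseline +/- %g; using recording end %g s",
        epsilon,
        curve.time[-1],
    )
    return float(curve.time[-1])


def segment_phases(
    curve: ReleaseCurve,
    epsilon: float | None = None,
    k: int = 3,
) -> tuple[ReleaseCurve | None, ReleaseCurve | None]:
    """Split the recording at the first swallow.

    Phase 1 contains samples with time <= swallow_time (a sample at
    exactly the swallow instant belongs to phase 1 only); phase 2 runs
    from the next sample up to the baseline-return time found by
    :func:`detect_baseline_return`. A phase with fewer than 2 samples is
    returned as None and its parameters are later flagged missing.

    ``epsilon`` defaults to 0.5% of the peak excursion above baseline.
    """
    if epsilon is None:
        peak = float(np.max(np.abs(curve.intensity - curve.baseline)))
        epsilon = max(5e-3 * peak, 1e-12)
    mask1 = curve.time <= curve.swallow_time
    post = curve.time > curve.swallow_time
    rose = bool(np.any(post & (curve.intensity > curve.baseline + epsilon)))
    if rose:
        t_return = detect_baseline_return(curve, epsilon=epsilon, k=k)
        mask2 = post & (curve.time <= t_return)
    else:
        # no second release phase: the flat tail carries zero area/max
        mask2 = post
    return _segment(curve, mask1), _segment(curve, mask2)


def _segment(curve: ReleaseCurve, mask: np.ndarray) -> ReleaseCurve | None:
    """Slice without re-validating the swallow-inside-recording invariant
    (a segment legitimately lies entirely on one side of the swallow)."""
    if mask.sum() < 2:
        return None
    seg = object.__new__(ReleaseCurve)
    seg.time = curve.time[mask]
    seg.intensity = curve.intensity[mask]
    seg.swallow_time = curve.swallow_time
    seg.baseline = curve.baseline
    return seg


def _phase_parameters(seg: ReleaseCurve | None) -> tuple[float, float, float, float]:
    """(area a.u.·min, Imax a.u., Tmax min, rate a.u./min) for one phase."""
    if seg is None:
        return math.nan, math.nan, math.nan, math.nan
    above = np.clip(seg.intensity - seg.baseline, 0.0, None)
    area = float(np.trapezoid(above, seg.time)) / _SECONDS_PER_MINUTE
    imax = float(above.max())
    if imax <= 0.0:
        return area, imax, math.nan, math.nan
    tmax = float(seg.time[int(np.argmax(above))]) / _SECONDS_PER_MINUTE
    rate = imax / tmax if tmax > 0 else math.nan
    return area, imax, tmax, rate


def extract_release_parameters(
    curve: ReleaseCurve,
    smoothing_window: int = 1,
    epsilon: float | None = None,
    k: int = 3,
) -> ReleaseParameters:
    """Smooth, segment, and summarize a recording into the nine
    response variables.

    ``smoothing_window`` is the odd moving-average width in samples
    (1 = no smoothing; for real breath-modulated recordings choose a
    window spanning roughly one breathing cycle). Ties in the phase
    maximum break to the earliest sample. ``A1/A2`` is flagged missing
    when the post-swallow area is zero.
    """
    smoothed = smooth_curve(curve, smoothing_window)
    phase1, phase2 = segment_phases(smoothed, epsilon=epsilon, k=k)
    a1, imax1, tmax1, rate1 = _phase_parameters(phase1)
    a2, imax2, tmax2, rate2 = _phase_parameters(phase2)
    ratio = a1 / a2 if (a1 == a1 and a2 == a2 and a2 > 0) else math.nan
    return ReleaseParameters(
        A1=a1, A2=a2, A1_over_A2=ratio,
        Imax1=imax1, Tmax1=tmax1, rate1=rate1,
        Imax2=imax2, Tmax2=tmax2, rate2=rate2,
    )
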