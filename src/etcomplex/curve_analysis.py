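"""Rupture-event detection and interaction-probability statistics.

Events are located as abrupt force drops on the retract trace: a local force
maximum well above the baseline followed by a fall back to within threshold
of the baseline.  The baseline and its noise level are estimated from the
far-from-surface tail of the curve, so detection is equivariant under force
offsets.  Specific (tether-mediated) unbinding is separated from nonspecific
surface adhesion by the separation window at which it occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .synthetic_smfs import AcquisitionParams, CurveBundle, ForceCurve

__all__ = [
    "DetectionParams",
    "RuptureEvent",
    "detect_ruptures",
    "classify_specific",
    "analyze_bundle",
    "cumulative_probability",
    "loading_rate_mode",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detector settings.

    ``force_threshold_multiple`` scales the estimated baseline noise SD; the
    ``specific_window_nm`` (closed interval) is set slightly wider than the
    ~10-20 nm tether offset to tolerate linker polydispersity.
    """

    force_threshold_multiple: float = 5.0
    specific_window_nm: tuple[float, float] = (8.0, 25.0)
    slope_fit_window: int = 8
    baseline_tail_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.force_threshold_multiple < 3:
            raise ValueError("threshold multiple must be >= 3")
        if self.specific_window_nm[0] <= 0:
            raise ValueError("specific window lower bound must be positive")
        if self.slope_fit_window < 3:
            raise ValueError("slope_fit_window must be >= 3")


@dataclass
class RuptureEvent:
    """A detected unbinding event on one curve."""

    curve_id: str
    force_pN: float
    separation_nm: float
    loading_rate_pN_per_s: float
    specific: bool


def _baseline_and_noise(curve: ForceCurve, det: DetectionParams) -> tuple[float, float]:
    """Median baseline and robust noise SD from the outer tail of the trace."""
    sep = curve.separation_nm
    lo, hi = sep.min(), sep.max()
    tail = curve.force_pN[sep >= hi - det.baseline_tail_fraction * (hi - lo)]
    baseline = float(np.median(tail))
    mad = float(np.median(np.abs(tail - baseline)))
    return baseline, max(1.4826 * mad, 1e-9)


def detect_ruptures(
    curve: ForceCurve,
    det: DetectionParams = DetectionParams(),
    params: AcquisitionParams | None = None,
) -> list[RuptureEvent]:
    """Detect rupture events on a retract curve.

    An event index ``i`` must satisfy both: force[i] exceeds baseline by the
    noise threshold, and the one-sample forward drop force[i] - force[i+1]
    exceeds the same threshold.  Event force is peak minus baseline; the
    loading rate is the local force-vs-separation slope at the peak (fit
    over ``slope_fit_window`` samples) times the retract velocity.
    """
    if curve.separation_nm.size < det.slope_fit_window + 2:
        raise ValueError("curve shorter than slope_fit_window")
    sep = curve.separation_nm
    force = curve.force_pN
    if sep[0] > sep[-1]:  # store retract traces with increasing separation
        sep, force = sep[::-1], force[::-1]

    baseline, sigma = _baseline_and_noise(curve, det)
    thr = det.force_threshold_multiple * sigma
    drop = force[:-1] - force[1:]
    above = force[:-1] - baseline > thr
    cand = np.flatnonzero((drop > thr) & above)

    velocity = params.retract_velocity_nm_per_s if params is not None else 1.0
    events: list[RuptureEvent] = []
    last_idx = -10
    for i in cand:
        if i - last_idx < 3:  # merge adjacent candidates into one event
            last_idx = i
            continue
        last_idx = i
        w = det.slope_fit_window
        j0 = max(0, i - w + 1)
        # instantaneous slope just prior to rupture: local quadratic fit
        # evaluated at the peak (the tether stiffens sharply, so a straight
        # line over the window underestimates the loading rate)
        xs, ys = sep[j0 : i + 1], force[j0 : i + 1]
        if len(xs) >= 4:
            a2, a1, _ = np.polyfit(xs, ys, 2)
            slope = 2 * a2 * sep[i] + a1
        else:
            slope = np.polyfit(xs, ys, 1)[0]
        events.append(
            RuptureEvent(
                curve_id=curve.curve_id,
                force_pN=float(force[i] - baseline),
                separation_nm=float(sep[i]),
                loading_rate_pN_per_s=float(max(slope, 0.0) * velocity),
                specific=classify_specific_separation(float(sep[i]), det),
            )
        )
    return events


def classify_specific_separation(separation_nm: float, det: DetectionParams) -> bool:
    """True iff the rupture separation falls in the closed specific window."""
    lo, hi = det.specific_window_nm
    return lo <= separation_nm <= hi


def classify_specific(event: RuptureEvent, det: DetectionParams) -> bool:
    """Specific vs nonspecific classification of a detected event."""
    return classify_specific_separation(event.separation_nm, det)


def analyze_bundle(
    bundle: CurveBundle, det: DetectionParams = DetectionParams()
) -> pd.DataFrame:
    """Run detection over a bundle; one row per detected event.

    A curve with several events counts once toward the cumulative interaction
    probability, and only its final (largest-separation) specific event
    enters the force histogram; the returned table carries all events with a
    ``histogram_event`` flag implementing that rule.
    """
    rows = []
    for curve in bundle.curves:
        events = detect_ruptures(curve, det, bundle.params)
        spec = [e for e in events if e.specific]
        keep = max(spec, key=lambda e: e.separation_nm) if spec else None
        for e in events:
            rows.append(
                {
                    "curve_id": e.curve_id,
                    "force_pN": e.force_pN,
                    "separation_nm": e.separation_nm,
                    "loading_rate_pN_per_s": e.loading_rate_pN_per_s,
                    "specific": e.specific,
                    "histogram_event": e is keep,
                }
            )
    cols = [
        "curve_id",
        "force_pN",
        "separation_nm",
        "loading_rate_pN_per_s",
        "specific",
        "histogram_event",
    ]
    return pd.DataFrame(rows, columns=cols)


def cumulative_probability(n_event_curves: int, n_complexes: int) -> float:
    """Cumulative interaction probability in percent.

    Ratio of curves displaying an unbinding event to complexes imaged.
    """
    if n_complexes < 1:
        raise ValueError("n_complexes must be >= 1")
    if n_event_curves < 0:
        raise ValueError("n_event_curves must be >= 0")
    return 100.0 * n_event_curves / n_complexes


def bundle_cumulative_probability(
    events: pd.DataFrame, n_complexes: int
) -> float:
    """Cumulative probability from an event table: specific-event curves / complexes."""
    n = events.loc[events["specific"], "curve_id"].nunique() if len(events) else 0
    return cumulative_probability(int(n), n_complexes)


def loading_rate_mode(loading_rates_pN_per_s) -> float:
    """Most probable loading rate via kernel density on log10(rate).

    The distribution is broad and right-skewed, so the mode is located in log
    space, matching how force-spectroscopy loading rates are reported.
    """
    rates = np.asarray(loading_rates_pN_per_s, dtype=float)
    rates = rates[rates > 0]
    if rates.size < 30:
        raise ValueError("need at least 30 events for a mode estimate")
    logs = np.log10(rates)
    if np.ptp(logs) < 1e-12:
        return float(rates[0])
    kde = gaussian_kde(logs)
    grid = np.linspace(logs.min(), logs.max(), 512)
    return float(10.0 ** grid[np.argmax(kde(grid))])
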