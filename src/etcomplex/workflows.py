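"""End-to-end convenience workflows over the SMFS chain.

One call runs generate -> detect -> classify -> histogram -> deconvolve for
a packaged condition and reports the recovered observables on the scales
the experiment uses (pN peak positions, percent probabilities, pN/s
loading-rate mode).
"""

from __future__ import annotations

import numpy as np

from .curve_analysis import (
    DetectionParams,
    analyze_bundle,
    bundle_cumulative_probability,
    loading_rate_mode,
)
from .force_deconvolution import build_histogram, component_probabilities, fit_mixture
from .synthetic_smfs import AcquisitionParams, generate_dataset, get_preset

__all__ = ["smfs_condition_summary"]


def smfs_condition_summary(
    preset_label: str,
    n_curves: int = 2000,
    seed: int = 0,
    bin_width_pN: float = 20.0,
    acquisition: AcquisitionParams | None = None,
    detection: DetectionParams | None = None,
) -> dict:
    """Blind parameter recovery for one condition.

    Generates a synthetic dataset from the packaged preset, detects and
    classifies rupture events without looking at the generator truth, and
    returns the fitted peak positions, component and cumulative interaction
    probabilities, and the loading-rate mode.
    """
    preset = get_preset(preset_label)
    acquisition = acquisition or AcquisitionParams()
    detection = detection or DetectionParams()
    bundle = generate_dataset(preset, acquisition, n_curves, seed=seed)
    events = analyze_bundle(bundle, detection)
    spec = events[events["histogram_event"]]
    cumulative = bundle_cumulative_probability(events, bundle.n_complexes)
    hist = build_histogram(spec["force_pN"].to_numpy(), cumulative, bin_width_pN)
    fit = fit_mixture(hist, k=2)
    low_pct, high_pct = component_probabilities(fit, hist)
    return {
        "preset": preset_label,
        "n_curves": n_curves,
        "n_events": int(len(spec)),
        "mean_low_pN": fit.mean_low,
        "mean_high_pN": fit.mean_high,
        "sd_low_pN": float(fit.sds_pN[0]),
        "sd_high_pN": float(fit.sds_pN[-1]),
        "cumulative_percent": cumulative,
        "p_low_percent": low_pct,
        "p_high_percent": high_pct,
        "loading_rate_mode_pN_per_s": float(
            loading_rate_mode(spec["loading_rate_pN_per_s"].to_numpy())
        )
        if len(spec) >= 30
        else float("nan"),
    }
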