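"""Synthetic single-molecule force-spectroscopy (PF-QNM style) curve generator.

Emulates retract force-distance curves for a cytochrome-functionalized AFM
probe mapping surface-bound reaction-center complexes: Gaussian baseline
noise, a worm-like-chain (WLC) tether stretch terminating in an instantaneous
rupture whose force is drawn from a two-component Gaussian mixture (encounter
vs productive electron-transfer complex), plus occasional nonspecific
adhesion close to the surface.  Every curve carries a ground-truth record so
the downstream detector and deconvolution stages can be validated blind.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import kbt_pn_nm

__all__ = [
    "ConditionPreset",
    "AcquisitionParams",
    "ForceCurve",
    "CurveBundle",
    "builtin_presets",
    "get_preset",
    "tether_force",
    "wlc_inverse_extension",
    "sample_rupture_forces",
    "generate_curve",
    "generate_dataset",
]


@dataclass(frozen=True)
class ConditionPreset:
    """One experimental condition: construct x salt x redox pair.

    ``mu``/``sigma`` parameterize the two-component rupture-force mixture
    (low = encounter complex, high = productive ET complex); ``p_event`` is
    the per-curve probability of a specific unbinding event, i.e. the
    cumulative interaction probability the condition should reproduce.
    """

    label: str
    construct: str
    salt_mM: float
    redox_pair: str  # "ox/red" or "ox/ox"
    p_event: float
    w_low: float
    mu_low_pN: float
    sigma_low_pN: float
    mu_high_pN: float
    sigma_high_pN: float
    p_nonspecific: float = 0.10
    offset_range_nm: tuple[float, float] = (10.0, 20.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_event <= 1.0:
            raise ValueError("p_event must lie in [0, 1]")
        if not 0.0 <= self.w_low <= 1.0:
            raise ValueError("w_low must lie in [0, 1]")
        if self.mu_low_pN >= self.mu_high_pN:
            raise ValueError("low-force mean must be below high-force mean")
        lo, hi = self.offset_range_nm
        if lo < 0 or hi < lo:
            raise ValueError("offset_range_nm must be a non-negative interval")


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition settings of the emulated PF-QNM experiment.

    Defaults follow the instrument regime of the study: cantilever spring
    constant in the 0.087-0.262 N/m range, Z-modulation 20-25 nm, a ~9.5 nm
    PEG linker (contour includes an allowance for protein height), and a
    retract velocity calibrated so the most probable loading rate sits at
    ~2.5e6 pN/s.
    """

    spring_constant_N_per_m: float = 0.15
    modulation_amplitude_nm: float = 25.0
    retract_velocity_nm_per_s: float = 5.8e3
    samples_per_curve: int = 512
    baseline_noise_pN: float = 8.0
    temperature_K: float = 298.0
    tether_contour_nm: float = 13.0
    tether_persistence_nm: float = 0.38

    def __post_init__(self) -> None:
        if not 0.01 <= self.spring_constant_N_per_m <= 10.0:
            raise ValueError("spring constant outside plausible range")
        if self.modulation_amplitude_nm < self.tether_contour_nm:
            raise ValueError("modulation amplitude must exceed tether contour")
        if min(self.tether_contour_nm, self.tether_persistence_nm) <= 0:
            raise ValueError("tether lengths must be positive")
        if self.samples_per_curve < 8:
            raise ValueError("need at least 8 samples per curve")


@dataclass
class ForceCurve:
    """One retract (or approach) trace: separation vs force."""

    separation_nm: np.ndarray
    force_pN: np.ndarray
    segment: str = "retract"
    curve_id: str = ""
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.separation_nm = np.asarray(self.separation_nm, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        if self.separation_nm.shape != self.force_pN.shape:
            raise ValueError("separation and force series must have equal length")
        d = np.diff(self.separation_nm)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("separation must be strictly monotone within a segment")


@dataclass
class CurveBundle:
    """A dataset of curves for one condition plus the generator truth table."""

    curves: list[ForceCurve]
    truth: pd.DataFrame
    preset: ConditionPreset
    params: AcquisitionParams
    seed: int
    n_complexes: int

    def __len__(self) -> int:
        return len(self.curves)


# --------------------------------------------------------------------------
# condition presets
#
# Peak positions and cumulative probabilities follow the printed values for
# each condition; the per-condition low/high component weights w_low are
# documented defaults (the study reports only graphical trends): the high
# force component dominates, and the low force (encounter) component is
# attenuated by salt, by oxidation of the cytochrome, and by the D(M184)K
# charge reversal.

_SALTS = (10.0, 50.0, 100.0, 200.0)

_P_EVENT_OXRED = {
    "WT": {10: 0.34, 50: 0.32, 100: 0.28, 200: 0.26},
    "N(M188)D": {10: 0.40, 50: 0.36, 100: 0.27, 200: 0.24},
    "Q(L264)E": {10: 0.39, 50: 0.35, 100: 0.26, 200: 0.23},
    "D(M184)K": {10: 0.24, 50: 0.22, 100: 0.20, 200: 0.18},
}
_P_EVENT_OXOX_10MM = {"WT": 0.32, "N(M188)D": 0.37, "Q(L264)E": 0.36, "D(M184)K": 0.20}

# peak positions drift only weakly with salt (120-150 / 320-340 pN)
_PEAKS_OXRED = {10: (154.0, 332.0), 50: (145.0, 335.0), 100: (135.0, 325.0), 200: (128.0, 322.0)}
_PEAKS_OXOX_WT = (173.0, 370.0)
_PEAKS_RC_ONLY = (124.0, 247.0)

_W_LOW = {
    "WT": {10: 0.45, 50: 0.40, 100: 0.35, 200: 0.30},
    "N(M188)D": {10: 0.50, 50: 0.45, 100: 0.38, 200: 0.32},
    "Q(L264)E": {10: 0.50, 50: 0.45, 100: 0.38, 200: 0.32},
    "D(M184)K": {10: 0.35, 50: 0.30, 100: 0.26, 200: 0.22},
}
_W_LOW_OXOX = {"WT": 0.35, "N(M188)D": 0.40, "Q(L264)E": 0.40, "D(M184)K": 0.28}

SIGMA_LOW_PN = 30.0
SIGMA_HIGH_PN = 42.0


def _slug(construct: str) -> str:
    return construct.replace("(", "").replace(")", "").replace("/", "")


def builtin_presets() -> list[ConditionPreset]:
    """All packaged condition presets.

    One per construct x salt at ox/red, one per construct at ox/ox (10 mM),
    plus the RC-only (no LH1 ring) condition at 10 mM ox/red.
    """
    presets: list[ConditionPreset] = []
    for construct, by_salt in _P_EVENT_OXRED.items():
        for salt in _SALTS:
            mu_lo, mu_hi = _PEAKS_OXRED[int(salt)]
            presets.append(
                ConditionPreset(
                    label=f"{_slug(construct)}_{int(salt)}mM_oxred",
                    construct=construct,
                    salt_mM=salt,
                    redox_pair="ox/red",
                    p_event=by_salt[int(salt)],
                    w_low=_W_LOW[construct][int(salt)],
                    mu_low_pN=mu_lo,
                    sigma_low_pN=SIGMA_LOW_PN,
                    mu_high_pN=mu_hi,
                    sigma_high_pN=SIGMA_HIGH_PN,
                )
            )
    for construct, p in _P_EVENT_OXOX_10MM.items():
        mu_lo, mu_hi = _PEAKS_OXOX_WT if construct == "WT" else _PEAKS_OXRED[10]
        presets.append(
            ConditionPreset(
                label=f"{_slug(construct)}_10mM_oxox",
                construct=construct,
                salt_mM=10.0,
                redox_pair="ox/ox",
                p_event=p,
                w_low=_W_LOW_OXOX[construct],
                mu_low_pN=mu_lo,
                sigma_low_pN=SIGMA_LOW_PN,
                mu_high_pN=mu_hi,
                sigma_high_pN=SIGMA_HIGH_PN,
            )
        )
    presets.append(
        ConditionPreset(
            label="RConly_10mM_oxred",
            construct="RC-only",
            salt_mM=10.0,
            redox_pair="ox/red",
            p_event=0.30,
            w_low=0.45,
            mu_low_pN=_PEAKS_RC_ONLY[0],
            sigma_low_pN=SIGMA_LOW_PN,
            mu_high_pN=_PEAKS_RC_ONLY[1],
            sigma_high_pN=SIGMA_HIGH_PN,
        )
    )
    return presets


def get_preset(label: str) -> ConditionPreset:
    """Look up a packaged preset by its label, e.g. ``WT_10mM_oxred``."""
    for p in builtin_presets():
        if p.label == label:
            return p
    labels = ", ".join(p.label for p in builtin_presets())
    raise KeyError(f"unknown preset {label!r}; available: {labels}")


# --------------------------------------------------------------------------
# tether mechanics


def tether_force(extension_nm, params: AcquisitionParams, contour_nm: float | None = None):
    """WLC interpolation-formula force (pN) of the PEG tether at a given extension.

    F = (kBT/Lp) * [ 1/(4 (1-x)^2) - 1/4 + x ],  x = extension / contour.
    """
    Lc = params.tether_contour_nm if contour_nm is None else contour_nm
    x = np.asarray(extension_nm, dtype=float) / Lc
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("extension must satisfy 0 <= extension < contour length")
    c = kbt_pn_nm(params.temperature_K) / params.tether_persistence_nm
    f = c * (0.25 / (1.0 - x) ** 2 - 0.25 + x)
    return float(f) if np.isscalar(extension_nm) else f


def wlc_inverse_extension(force_pN: float, params: AcquisitionParams) -> float:
    """Fractional extension x at which the WLC force equals ``force_pN``."""
    if force_pN <= 0:
        return 0.0
    c = kbt_pn_nm(params.temperature_K) / params.tether_persistence_nm
    g = lambda x: c * (0.25 / (1.0 - x) ** 2 - 0.25 + x) - force_pN
    return brentq(g, 0.0, 1.0 - 1e-9, xtol=1e-12)


def _wlc_slope(force_pN: float, contour_nm: float, params: AcquisitionParams) -> float:
    """dF/ds (pN/nm) of the WLC at the given force, for the given contour."""
    x = wlc_inverse_extension(force_pN, params)
    c = kbt_pn_nm(params.temperature_K) / params.tether_persistence_nm
    return c * (0.5 / (1.0 - x) ** 3 + 1.0) / contour_nm


# --------------------------------------------------------------------------
# curve generation


def sample_rupture_forces(preset: ConditionPreset, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n rupture forces from the condition's two-component mixture."""
    comp = rng.random(n) >= preset.w_low  # False = low, True = high
    mu = np.where(comp, preset.mu_high_pN, preset.mu_low_pN)
    sd = np.where(comp, preset.sigma_high_pN, preset.sigma_low_pN)
    f = rng.normal(mu, sd)
    # forces are strictly positive; the negative tail at these mu/sd is ~1e-5
    bad = f <= 0
    while np.any(bad):
        f[bad] = rng.normal(mu[bad], sd[bad])
        bad = f <= 0
    return f


def generate_curve(
    preset: ConditionPreset,
    params: AcquisitionParams,
    seed_or_rng: int | np.random.Generator,
    curve_id: str = "c0",
) -> ForceCurve:
    """Generate one retract curve with its ground-truth record.

    The specific event is a WLC stretch whose effective contour is set so the
    force reaches the drawn rupture force exactly at the drawn separation
    offset, followed by a one-sample drop back to baseline.  Nonspecific
    adhesion is a short spike below 5 nm separation.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    n = params.samples_per_curve
    sep = np.linspace(0.0, params.modulation_amplitude_nm, n)
    force = rng.normal(0.0, params.baseline_noise_pN, n)

    truth: dict = {
        "curve_id": curve_id,
        "event": False,
        "component": "",
        "rupture_force_pN": np.nan,
        "offset_nm": np.nan,
        "loading_rate_pN_per_s": np.nan,
        "nonspecific": False,
        "nonspecific_separation_nm": np.nan,
    }

    has_event = rng.random() < preset.p_event
    is_low = rng.random() < preset.w_low
    if has_event:
        mu = preset.mu_low_pN if is_low else preset.mu_high_pN
        sd = preset.sigma_low_pN if is_low else preset.sigma_high_pN
        f_rupt = rng.normal(mu, sd)
        while f_rupt <= 0:
            f_rupt = rng.normal(mu, sd)
        off = rng.uniform(*preset.offset_range_nm)
        idx = int(round(off / (sep[1] - sep[0])))
        idx = min(max(idx, 1), n - 2)
        s_rupt = sep[idx]
        x_star = wlc_inverse_extension(f_rupt, params)
        contour_eff = s_rupt / x_star
        ramp = tether_force(sep[: idx + 1], params, contour_nm=contour_eff)
        force[: idx + 1] += ramp
        truth.update(
            event=True,
            component="low" if is_low else "high",
            rupture_force_pN=float(f_rupt),
            offset_nm=float(s_rupt),
            loading_rate_pN_per_s=float(
                _wlc_slope(f_rupt, contour_eff, params) * params.retract_velocity_nm_per_s
            ),
        )

    if rng.random() < preset.p_nonspecific:
        s_adh = rng.uniform(1.0, 4.5)
        f_adh = rng.uniform(60.0, 250.0)
        j = int(round(s_adh / (sep[1] - sep[0])))
        j = min(max(j, 1), n - 2)
        rise_start = max(0, j - int(round(2.0 / (sep[1] - sep[0]))))
        ramp = np.linspace(0.0, f_adh, j - rise_start + 1)
        force[rise_start : j + 1] += ramp
        truth.update(nonspecific=True, nonspecific_separation_nm=float(sep[j]))

    return ForceCurve(sep, force, segment="retract", curve_id=curve_id, truth=truth)


def generate_dataset(
    preset: ConditionPreset,
    params: AcquisitionParams,
    n_curves: int,
    n_complexes: int | None = None,
    seed: int = 0,
) -> CurveBundle:
    """Generate a bundle of curves for one condition.

    ``n_complexes`` is the number of receptor complexes "imaged" (defaults to
    ``n_curves``, one curve per complex), the denominator of the cumulative
    interaction probability.
    """
    n_complexes = n_curves if n_complexes is None else n_complexes
    if n_curves > 0 and not (n_curves >= n_complexes >= 1):
        raise ValueError("need n_curves >= n_complexes >= 1")
    rng = np.random.default_rng(seed)
    curves = [
        generate_curve(preset, params, rng, curve_id=f"c{i:05d}") for i in range(n_curves)
    ]
    truth = pd.DataFrame([c.truth for c in curves])
    if truth.empty:
        truth = pd.DataFrame(
            columns=[
                "curve_id",
                "event",
                "component",
                "rupture_force_pN",
                "offset_nm",
                "loading_rate_pN_per_s",
                "nonspecific",
                "nonspecific_separation_nm",
            ]
        )
    return CurveBundle(curves, truth, preset, params, seed, n_complexes)
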