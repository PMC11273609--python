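"""Probability-normalized force histograms and two-Gaussian deconvolution.

The force histogram is scaled so its total equals the cumulative interaction
probability (percent), mirroring how affinity-mapping histograms are drawn:
the area of each fitted Gaussian component is then directly the interaction
probability of that component (encounter vs productive complex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ForceHistogram",
    "MixtureFit",
    "build_histogram",
    "fit_mixture",
    "component_probabilities",
    "select_k",
]

SQRT2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class ForceHistogram:
    """Histogram of rupture forces scaled to probability-percent."""

    bin_edges_pN: np.ndarray
    heights: np.ndarray  # percent per bin; sums to cumulative_percent
    cumulative_percent: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_pN[:-1] + self.bin_edges_pN[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges_pN[1] - self.bin_edges_pN[0])


@dataclass
class MixtureFit:
    """Least-squares Gaussian mixture fit to a force histogram.

    Components are ordered by ascending mean; with k=2 the first is the
    low-force (encounter-complex) component.
    """

    k: int
    amplitudes: np.ndarray  # peak heights, percent-per-bin units
    means_pN: np.ndarray
    sds_pN: np.ndarray
    residual_norm: float
    covariance: np.ndarray | None = None
    degenerate: bool = False

    @property
    def mean_low(self) -> float:
        return float(self.means_pN[0])

    @property
    def mean_high(self) -> float:
        return float(self.means_pN[-1])


def build_histogram(forces_pN, cumulative_percent: float, bin_width_pN: float = 20.0) -> ForceHistogram:
    """Bin rupture forces and scale heights to sum to ``cumulative_percent``."""
    forces = np.asarray(forces_pN, dtype=float)
    if forces.size == 0:
        raise ValueError("forces must be nonempty")
    if bin_width_pN <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(0.0, forces.max() + 2 * bin_width_pN, bin_width_pN)
    counts, edges = np.histogram(forces, bins=edges)
    heights = counts * (cumulative_percent / forces.size)
    return ForceHistogram(edges, heights, float(cumulative_percent))


def _gauss_sum(x: np.ndarray, theta: np.ndarray, k: int) -> np.ndarray:
    y = np.zeros_like(x)
    for j in range(k):
        a, mu, sd = theta[3 * j : 3 * j + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def _initial_guesses(hist: ForceHistogram, k: int, n_restarts: int, seed: int) -> list[np.ndarray]:
    """Moment/quantile-based initialization plus jittered restarts."""
    x, h = hist.centers, hist.heights
    total = h.sum()
    w = h / total if total > 0 else np.full_like(h, 1.0 / len(h))
    cdf = np.cumsum(w)
    q = lambda p: float(np.interp(p, cdf, x))
    spread = max(q(0.84) - q(0.16), hist.bin_width)
    guesses: list[np.ndarray] = []
    if k == 1:
        base = np.array([h.max(), q(0.5), spread / 2])
    else:
        base = np.array([h.max(), q(0.25), spread / 3, h.max(), q(0.75), spread / 3])
    guesses.append(base)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        jit = base.copy()
        jit[1::3] *= rng.uniform(0.85, 1.15, k)  # means
        jit[2::3] *= rng.uniform(0.6, 1.6, k)  # sds
        jit[0::3] *= rng.uniform(0.5, 1.5, k)  # amplitudes
        guesses.append(jit)
    return guesses


def fit_mixture(hist: ForceHistogram, k: int = 2, n_restarts: int = 5, seed: int = 0) -> MixtureFit:
    """Nonlinear least-squares fit of k Gaussians to the histogram heights.

    Multistart initialization with a fixed seed; components returned ordered
    by mean.  Raises ``RuntimeError`` with diagnostics if no start converges.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    occupied = int(np.count_nonzero(hist.heights))
    if occupied < 5:
        raise ValueError(f"need >= 5 occupied bins, got {occupied}")
    x, h = hist.centers, hist.heights
    lo = np.tile([0.0, x.min() - hist.bin_width, hist.bin_width / 2], k)
    hi = np.tile([np.inf, x.max() + hist.bin_width, x.max()], k)

    best = None
    for theta0 in _initial_guesses(hist, k, n_restarts, seed):
        theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                lambda t: _gauss_sum(x, t, k) - h, theta0, bounds=(lo, hi), method="trf"
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(
            f"mixture fit failed to converge for k={k} over {n_restarts + 1} starts"
        )

    theta = best.x
    order = np.argsort(theta[1::3])
    amps = theta[0::3][order]
    means = theta[1::3][order]
    sds = theta[2::3][order]

    # covariance from the Jacobian at the optimum (Gauss-Newton approximation)
    cov = None
    try:
        J = best.jac
        dof = max(len(x) - len(theta), 1)
        s2 = 2 * best.cost / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
    except Exception:
        pass

    degenerate = False
    if k == 2:
        sep = abs(means[1] - means[0])
        amp_ratio = amps.min() / max(amps.max(), 1e-12)
        degenerate = amp_ratio < 0.1 or sep < max(sds.max(), 1e-12)

    return MixtureFit(
        k=k,
        amplitudes=amps,
        means_pN=means,
        sds_pN=sds,
        residual_norm=float(np.sqrt(2 * best.cost)),
        covariance=cov,
        degenerate=degenerate,
    )


def component_probabilities(fit: MixtureFit, hist: ForceHistogram) -> tuple[float, ...]:
    """Interaction probability (percent) of each fitted component.

    The Gaussian area A*sd*sqrt(2*pi), divided by the bin width, converts the
    fitted peak height (percent per bin) to percent of complexes.
    """
    areas = fit.amplitudes * fit.sds_pN * SQRT2PI / hist.bin_width
    return tuple(float(a) for a in areas)


def _bic(hist: ForceHistogram, fit: MixtureFit) -> float:
    n = len(hist.centers)
    rss = max(fit.residual_norm**2, 1e-300)
    return n * np.log(rss / n) + 3 * fit.k * np.log(n)


def select_k(hist: ForceHistogram, seed: int = 0) -> int:
    """Choose 1 vs 2 components by BIC on the least-squares fits; ties -> 1."""
    fit1 = fit_mixture(hist, k=1, seed=seed)
    try:
        fit2 = fit_mixture(hist, k=2, seed=seed)
    except (RuntimeError, ValueError):
        return 1
    return 2 if _bic(hist, fit2) < _bic(hist, fit1) and not fit2.degenerate else 1
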