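"""Scalar observables: speeds, entropy production, morphology, scaling fits.

Entropy production is reported in the rhoT-scaled dimensionless form: the
total rate is the stress power integral s_tot = int sigma : grad u dA,
decomposed into the viscous dissipation

    s_v = int (grad u + grad u^T) : grad u dA  >= 0

and the work done by the active units s_a = -Ca int T : grad u dA (T = pp
or Q).  The pressure contribution vanishes by incompressibility, so
s_tot = s_v + s_a up to quadrature error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .flow import FlowState, active_tensor_quad

__all__ = ["EntropyRates", "entropy_rates", "max_speed", "fit_power_law",
           "classify_morphology", "MorphologyThresholds"]


@dataclass(frozen=True)
class EntropyRates:
    s_dot_v: float
    s_dot_a: float

    @property
    def s_dot_tot(self) -> float:
        return self.s_dot_v + self.s_dot_a


def entropy_rates(state: FlowState, nematic, ca: float) -> EntropyRates:
    """Viscous and active entropy production rates by element quadrature
    (exact for the discrete polynomial degrees)."""
    spaces = state.spaces
    g = spaces.grad_p2_field(state.u)          # (nq, nt, 2, 2)
    sym = g + np.swapaxes(g, -1, -2)
    s_v = spaces.integrate(np.einsum("qeij,qeij->qe", sym, g))
    if ca != 0.0:
        T = active_tensor_quad(spaces, nematic)
        s_a = -ca * spaces.integrate(np.einsum("qeij,qeij->qe", T, g))
    else:
        s_a = 0.0
    return EntropyRates(s_dot_v=float(s_v), s_dot_a=float(s_a))


def max_speed(state: FlowState) -> float:
    """Maximum speed over the velocity nodes."""
    return float(state.speed.max())


def fit_power_law(points) -> tuple[float, float]:
    """Least-squares power-law fit y = prefactor * x^exponent.

    ``points``: sequence of (x, y) with x, y > 0 (x is typically |Ca|).
    Returns (exponent, prefactor).
    """
    pts = np.asarray(list(points), float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a power-law fit")
    if np.any(pts <= 0):
        raise ValueError("power-law fit requires positive x and y")
    slope, intercept = np.polyfit(np.log(pts[:, 0]), np.log(pts[:, 1]), 1)
    return float(slope), float(np.exp(intercept))


@dataclass(frozen=True)
class MorphologyThresholds:
    """Classifier thresholds; the shapes are classified visually in the
    literature, so fixed defaults make the state diagram reproducible."""

    film_height_ratio: float = 0.25    # center height / max height
    asymmetry: float = 0.01            # mirror asymmetry metric
    mushroom_width_excess: float = 0.05  # overhang beyond the contact width
    peak_prominence: float = 0.02      # for counting lobes, x max height


def classify_morphology(curve: geometry.InterfaceCurve,
                        thresholds: MorphologyThresholds | None = None) -> str:
    """Label the steady shape.

    Order of precedence: ``film-two-lobes`` (central height below
    ``film_height_ratio`` of the maximum over x in [0.8, 1.2], with at least
    two height maxima), then ``broken-symmetry`` (mirror asymmetry), then
    ``mushroom`` (overhang above half height wider than the contact line by
    more than ``mushroom_width_excess``), else ``simple-symmetric``.
    """
    th = thresholds or MorphologyThresholds()
    nodes = curve.nodes
    y = nodes[:, 1]
    x = nodes[:, 0]
    hmax = float(y.max())

    center = (x >= 0.8) & (x <= 1.2)
    h_center = float(y[center].min()) if center.any() else hmax
    n_peaks = _count_peaks(y, th.peak_prominence * hmax)
    if h_center < th.film_height_ratio * hmax and n_peaks >= 2:
        return "film-two-lobes"

    if geometry.mirror_asymmetry(curve) > th.asymmetry:
        return "broken-symmetry"

    upper = y > 0.5 * hmax
    if upper.any():
        width = float(x[upper].max() - x[upper].min())
        if width > 2.0 * (1.0 + th.mushroom_width_excess):
            return "mushroom"
    return "simple-symmetric"


def _count_peaks(y: np.ndarray, prominence: float) -> int:
    """Local maxima of the height profile with a minimum prominence
    (descent by at least ``prominence`` on both sides before a higher
    sample is reached)."""
    peaks = 0
    for i in range(1, y.size - 1):
        if y[i] >= y[i - 1] and y[i] >= y[i + 1] and \
                (y[i] > y[i - 1] or y[i] > y[i + 1]):
            if (y[i] - _valley(y[:i + 1][::-1], y[i])) >= prominence and \
               (y[i] - _valley(y[i:], y[i])) >= prominence:
                peaks += 1
    return peaks


def _valley(arr: np.ndarray, peak: float) -> float:
    """Lowest value reached before a sample exceeds the peak height."""
    lo = peak
    for v in arr[1:]:
        if v > peak:
            break
        lo = min(lo, v)
    return lo
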