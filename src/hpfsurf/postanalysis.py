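"""Derived quantities: CMC, scattering line shape, packing parameter.

* The critical micelle concentration is read off the free-monomer-fraction
  curve: below the CMC essentially all surfactant is monomeric, above it
  added surfactant enters aggregates, so the curve consists of two roughly
  linear regimes whose intersection estimates the CMC.
* Small-angle scattering intensity is predicted from the pair correlation
  function via I(Q) propto 1 + 4 pi rho int (g(r)-1) r^2 sin(Qr)/(Qr) dr,
  and fitted with the Ornstein-Zernike (Lorentzian) line shape
  I(Q) = I0 / (1 + Q^2 xi^2), whose correlation length xi characterizes
  exponentially decaying density correlations — the scattering signature of
  labile clusters rather than well-defined micelles.
* The surfactant packing parameter N_s = V_t / (A_c l_t) classifies the
  preferred aggregate geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .observables import RDFResult

__all__ = [
    "CMCFit",
    "OZFit",
    "PackingResult",
    "fit_cmc",
    "saxs_from_rdf",
    "fit_oz",
    "packing_parameter",
]


@dataclass
class CMCFit:
    cmc: float                       # mM
    split_index: int                 # first index of the high-conc regime
    low_slope: float
    low_intercept: float
    high_slope: float
    high_intercept: float
    residual: float                  # pooled sum of squared residuals


def _line_fit(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    ssr = float(np.sum((y - slope * x - intercept) ** 2))
    return float(slope), float(intercept), ssr


def fit_cmc(concentrations: Sequence[float],
            monomer_fractions: Sequence[float]) -> CMCFit:
    """Two-regime piecewise-linear fit; the CMC is the line intersection.

    Every ordered split with at least two points per side is tried and the
    one minimizing the pooled squared residual wins.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(monomer_fractions, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points spanning both regimes")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("monomer fractions must lie in [0, 1]")
    order = np.argsort(x)
    x, y = x[order], y[order]

    best = None
    for k in range(2, len(x) - 1):
        m1, b1, s1 = _line_fit(x[:k], y[:k])
        m2, b2, s2 = _line_fit(x[k:], y[k:])
        if best is None or s1 + s2 < best[0]:
            best = (s1 + s2, k, m1, b1, m2, b2)
    ssr, k, m1, b1, m2, b2 = best
    scale = max(abs(m1), abs(m2), 1e-30)
    if abs(m1 - m2) <= 1e-9 * scale:
        raise ValueError("no intersection: fitted regimes are parallel")
    cmc = (b2 - b1) / (m1 - m2)
    if not (x[0] < cmc < x[-1]):
        raise ValueError(
            f"intersection {cmc:.3g} mM falls outside the sampled "
            f"concentration range [{x[0]:g}, {x[-1]:g}]")
    return CMCFit(cmc=float(cmc), split_index=k, low_slope=m1, low_intercept=b1,
                  high_slope=m2, high_intercept=b2, residual=ssr)


@dataclass
class SAXSCurve:
    Q: np.ndarray                    # nm^-1
    I: np.ndarray                    # arbitrary units (I -> 1 at large Q)
    converged: bool                  # g(r_max) had relaxed to 1
    warning: Optional[str] = None


def saxs_from_rdf(rdf: RDFResult, number_density: float,
                  Q: Optional[np.ndarray] = None) -> SAXSCurve:
    """Predicted scattering intensity from a pair correlation function.

    I(Q) = 1 + 4 pi rho int_0^{r_max} (g(r) - 1) r^2 sin(Qr)/(Qr) dr by
    trapezoidal quadrature on the binned g(r).  ``number_density`` is the
    density of the scattering centers (nm^-3).  The default Q grid covers
    0.1-5 nm^-1 with 200 points.
    """
    if Q is None:
        Q = np.linspace(0.1, 5.0, 200)
    Q = np.asarray(Q, dtype=float)
    r = rdf.r
    h = rdf.g - 1.0
    tail = abs(h[-1])
    converged = tail <= 0.05
    warning = None if converged else (
        f"g(r) has not converged to 1 at r_max ({rdf.g[-1]:.3f}); "
        "the transform truncates real correlations")
    qr = np.outer(Q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr > 0, np.sin(qr) / qr, 1.0)
    integrand = sinc * (h * r ** 2)[None, :]
    excess = 4.0 * np.pi * number_density * np.trapezoid(integrand, r, axis=1)
    return SAXSCurve(Q=Q, I=1.0 + excess, converged=converged, warning=warning)


@dataclass
class OZFit:
    I0: float
    xi: float                        # nm
    residual: float


def _oz_model(Q, I0, xi):
    return I0 / (1.0 + Q ** 2 * xi ** 2)


def fit_oz(Q: Sequence[float], I: Sequence[float]) -> OZFit:
    """Nonlinear least-squares fit of the Ornstein-Zernike line shape."""
    Q = np.asarray(Q, dtype=float)
    I = np.asarray(I, dtype=float)
    if len(Q) < 3:
        raise ValueError("need at least 3 points")
    if np.any(I <= 0):
        raise ValueError("intensities must be positive")
    I0_guess = float(I.max())
    below = np.where(I <= I0_guess / 2)[0]
    xi_guess = 1.0 / Q[below[0]] if len(below) and Q[below[0]] > 0 else 0.1
    try:
        popt, _ = curve_fit(_oz_model, Q, I, p0=(I0_guess, xi_guess),
                            bounds=([0.0, 0.0], [np.inf, np.inf]),
                            maxfev=10000)
    except RuntimeError as e:
        raise ValueError(f"Ornstein-Zernike fit did not converge: {e}") from e
    residual = float(np.sum((I - _oz_model(Q, *popt)) ** 2))
    return OZFit(I0=float(popt[0]), xi=float(popt[1]), residual=residual)


@dataclass
class PackingResult:
    V_t: float                       # nm^3
    A_c: float                       # nm^2
    l_t: float                       # nm
    N_s: float
    shape: str


def packing_parameter(V_t: float, A_c: float, l_t: float) -> PackingResult:
    """Surfactant packing parameter N_s = V_t / (A_c l_t) and shape class.

    Standard thresholds: N_s < 1/3 spherical micelles, 1/3-1/2 cylindrical,
    1/2-1 bilayers, above 1 inverted structures.
    """
    if V_t <= 0 or A_c <= 0 or l_t <= 0:
        raise ValueError("V_t, A_c and l_t must all be positive")
    ns = V_t / (A_c * l_t)
    if ns < 1.0 / 3.0:
        shape = "sphere"
    elif ns < 0.5:
        shape = "cylinder"
    elif ns <= 1.0:
        shape = "bilayer"
    else:
        shape = "inverted"
    return PackingResult(V_t=V_t, A_c=A_c, l_t=l_t, N_s=ns, shape=shape)
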