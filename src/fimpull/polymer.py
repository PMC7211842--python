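"""Polymer elasticity models and least-squares fitting.

Two models cover the two kinds of pulling data:

* the worm-like chain (WLC) in the Bouchiat et al. interpolation, used per
  branch of an AFM force-extension trace.  Free parameters: persistence
  length ``P`` and contour length ``L`` (both nm).  Force diverges as the
  extension approaches ``L``.
* the extensible freely jointed chain (FJC) of Smith et al., used as the
  post-unfolding stretching baseline of steered-MD traces.  The Langevin
  backbone of Kuhn length ``b`` is multiplied by ``(1 + F/K)`` so the chain
  can stretch beyond its contour length ``L``; ``K`` is the stretch modulus
  in pN.

The WLC stretch free energy (the integral of force over extension) is
available in closed form and is the work-bookkeeping primitive of the whole
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .constants import DEFAULT_TEMPERATURE, kbt

__all__ = [
    "WLCParams",
    "FJCParams",
    "FitResult",
    "BOUCHIAT_COEFFS",
    "wlc_force",
    "wlc_stretch_energy",
    "fjc_extension",
    "fjc_force",
    "fit_wlc",
    "fit_fjc",
]

#: Correction coefficients a_2..a_7 of the Bouchiat et al. interpolation.
BOUCHIAT_COEFFS: tuple[float, ...] = (
    -0.5164228,
    -2.737418,
    16.07497,
    -38.87607,
    39.49944,
    -14.17718,
)


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters.

    Attributes
    ----------
    persistence_length : persistence length P in nm.
    contour_length : contour length L in nm.
    temperature : temperature in K.
    """

    persistence_length: float
    contour_length: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError(f"persistence_length must be > 0, got {self.persistence_length}")
        if self.contour_length <= 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


@dataclass(frozen=True)
class FJCParams:
    """Extensible freely jointed chain parameters.

    Attributes
    ----------
    kuhn_length : Kuhn segment length b in nm.
    contour_length : contour length L in nm.
    stretch_modulus : segment elastic modulus K in pN.
    temperature : temperature in K.
    """

    kuhn_length: float
    contour_length: float
    stretch_modulus: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kuhn_length <= 0:
            raise ValueError(f"kuhn_length must be > 0, got {self.kuhn_length}")
        if self.contour_length <= 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if self.stretch_modulus <= 0:
            raise ValueError(f"stretch_modulus must be > 0, got {self.stretch_modulus}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a bounded least-squares model fit.

    ``converged`` is False when the optimizer failed *or* landed on a
    parameter bound; bound-stuck fits are untrustworthy and must stay
    visible to downstream acceptance filters.
    """

    params: WLCParams | FJCParams
    rmse: float
    n_points: int
    converged: bool

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


def _wlc_bracket(z: np.ndarray) -> np.ndarray:
    """Dimensionless WLC force bracket as a function of z = x/L."""
    out = z - 0.25 + 1.0 / (4.0 * (1.0 - z) ** 2)
    zi = z * z
    for a in BOUCHIAT_COEFFS:
        out = out + a * zi
        zi = zi * z
    return out


def wlc_force(x, p: WLCParams):
    """WLC force (pN) at extension ``x`` (nm).

    F(x) = (kB T / P) [z - 1/4 + 1/(4 (1-z)^2) + sum_{i=2}^{7} a_i z^i],
    z = x / L.  Strictly increasing on [0, L); diverges as x -> L.

    Accepts a scalar or array; raises ValueError outside [0, L).
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("extension must be non-negative")
    if np.any(x_arr >= p.contour_length):
        raise ValueError(
            f"extension must be below the contour length {p.contour_length} nm"
        )
    z = x_arr / p.contour_length
    f = (kbt(p.temperature) / p.persistence_length) * _wlc_bracket(z)
    return f if np.ndim(x) else float(f)


def wlc_stretch_energy(x, p: WLCParams):
    """Stretch free energy ∫0^x F(x') dx' of the WLC, in pN·nm.

    Uses the closed-form antiderivative of the interpolation bracket
    (polynomial terms plus 1/(4(1-z)); validated against adaptive quadrature
    in the test suite).  Non-negative and non-decreasing in x.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("extension must be non-negative")
    if np.any(x_arr >= p.contour_length):
        raise ValueError(
            f"extension must be below the contour length {p.contour_length} nm"
        )
    z = x_arr / p.contour_length
    # antiderivative of the bracket in z, zero at z = 0
    anti = z * z / 2.0 - z / 4.0 + 1.0 / (4.0 * (1.0 - z)) - 0.25
    zi = z * z * z
    for i, a in enumerate(BOUCHIAT_COEFFS, start=2):
        anti = anti + a * zi / (i + 1)
        zi = zi * z
    e = (kbt(p.temperature) / p.persistence_length) * p.contour_length * anti
    return e if np.ndim(x) else float(e)


def _langevin(u: np.ndarray) -> np.ndarray:
    """coth(u) - 1/u, series-stabilized near u = 0."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < 1e-4
    us = u[small]
    out[small] = us / 3.0 - us**3 / 45.0
    ul = u[~small]
    out[~small] = 1.0 / np.tanh(ul) - 1.0 / ul
    return out


def fjc_extension(F, p: FJCParams):
    """Extension (nm) of the extensible FJC at force ``F`` (pN).

    x(F) = L [coth(F b / kB T) - kB T / (F b)] (1 + F / K); x(0) = 0 by
    continuous extension.  Strictly increasing in F, saturating at
    L (1 + F/K), so x > L is reachable.
    """
    f_arr = np.asarray(F, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("force must be non-negative")
    u = f_arr * p.kuhn_length / kbt(p.temperature)
    x = p.contour_length * _langevin(u) * (1.0 + f_arr / p.stretch_modulus)
    return x if np.ndim(F) else float(x)


def fjc_force(x, p: FJCParams, rtol: float = 1e-9):
    """Force (pN) of the extensible FJC at extension ``x`` (nm).

    Numerical inverse of :func:`fjc_extension` by monotone bracketing
    (Brent's method) to relative tolerance ``rtol`` on F.
    """
    scalar = not np.ndim(x)
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x_arr < 0):
        raise ValueError("extension must be non-negative")

    out = np.empty_like(x_arr)
    f_scale = kbt(p.temperature) / p.kuhn_length
    for i, xi in enumerate(x_arr):
        if xi == 0.0:
            out[i] = 0.0
            continue
        hi = f_scale
        for _ in range(200):
            if fjc_extension(hi, p) >= xi:
                break
            hi *= 2.0
        else:
            raise RuntimeError(
                f"fjc_force bracketing failed: extension {xi} nm not reached "
                f"below {hi} pN (params {p})"
            )
        out[i] = optimize.brentq(
            lambda f: fjc_extension(f, p) - xi, 0.0, hi, rtol=rtol, maxiter=200
        )
    return out if not scalar else float(out[0])


def _near_bound(value: float, lo: float, hi: float) -> bool:
    span = hi - lo
    return (value - lo) <= 1e-6 * span or (hi - value) <= 1e-6 * span


def _rmse(residuals: np.ndarray) -> float:
    return float(np.sqrt(np.mean(residuals**2)))


def fit_wlc(
    points,
    temperature: float = DEFAULT_TEMPERATURE,
    bounds: dict | None = None,
) -> FitResult:
    """Fit the WLC model to (extension nm, force pN) points.

    Bounded nonlinear least squares over (P, L); the contour length is
    constrained above the largest extension in the data.  ``bounds`` may
    override the default parameter box with keys ``"P"`` and ``"L"`` mapping
    to (lo, hi) tuples.

    Returns a :class:`FitResult`; ``converged`` is False on optimizer
    failure or a bound-stuck solution.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("fit_wlc needs at least 3 (extension, force) points")
    x, f = pts[:, 0], pts[:, 1]
    if np.any(x < 0):
        raise ValueError("extensions must be non-negative")
    x_max = float(np.max(x))
    if x_max <= 0:
        raise ValueError("data has no positive extension")

    box = {
        "P": (1e-3, 5.0),
        "L": (x_max * (1.0 + 1e-6), x_max * 10.0),
    }
    if bounds:
        box.update(bounds)
    lo = np.array([box["P"][0], box["L"][0]])
    hi = np.array([box["P"][1], box["L"][1]])
    p0 = np.clip(np.array([0.4, 1.05 * x_max]), lo, hi)

    kT = kbt(temperature)

    def residuals(theta):
        P, L = theta
        z = np.minimum(x / L, 1.0 - 1e-9)
        return (kT / P) * _wlc_bracket(z) - f

    try:
        sol = optimize.least_squares(
            residuals, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
    except Exception:
        params = WLCParams(p0[0], p0[1], temperature)
        return FitResult(params, _rmse(residuals(p0)), len(x), False)

    P, L = sol.x
    converged = bool(sol.success) and not (
        _near_bound(P, *box["P"]) or _near_bound(L, *box["L"])
    )
    return FitResult(
        WLCParams(float(P), float(L), temperature),
        _rmse(sol.fun),
        len(x),
        converged,
    )


def fit_fjc(
    points,
    temperature: float = DEFAULT_TEMPERATURE,
    bounds: dict | None = None,
) -> FitResult:
    """Fit the extensible FJC to (extension nm, force pN) points.

    Bounded least squares over (b, L, K) with force-space residuals, the
    statistically correct weighting when the noise sits on the force
    channel.  The model gives x(F) in closed form, so the force at each
    measured extension is obtained by inverse interpolation of a dense
    x(F) table per iteration rather than a rootfind per point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("fit_fjc needs at least 4 (extension, force) points")
    x, f = pts[:, 0], pts[:, 1]
    if np.any(x < 0):
        raise ValueError("extensions must be non-negative")
    if np.any(f < 0):
        raise ValueError("forces must be non-negative for the FJC baseline fit")
    x_max = float(np.max(x))

    box = {
        "b": (0.05, 5.0),
        "L": (0.1 * x_max, 10.0 * x_max),
        "K": (10.0, 1e6),
    }
    if bounds:
        box.update(bounds)
    lo = np.array([box["b"][0], box["L"][0], box["K"][0]])
    hi = np.array([box["b"][1], box["L"][1], box["K"][1]])
    p0 = np.clip(np.array([0.8, 1.05 * x_max, 1e4]), lo, hi)

    kT = kbt(temperature)
    f_hi = 4.0 * max(float(np.max(f)), 1.0)
    f_grid = np.linspace(0.0, f_hi, 3000)

    def residuals(theta):
        b, L, K = theta
        u = f_grid * b / kT
        x_of_f = L * _langevin(u) * (1.0 + f_grid / K)
        return np.interp(x, x_of_f, f_grid) - f

    try:
        sol = optimize.least_squares(
            residuals, p0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
    except Exception:
        params = FJCParams(p0[0], p0[1], p0[2], temperature)
        return FitResult(params, float("nan"), len(x), False)

    b, L, K = (float(v) for v in sol.x)
    params = FJCParams(b, L, K, temperature)
    converged = bool(sol.success) and not (
        _near_bound(b, *box["b"]) or _near_bound(L, *box["L"]) or _near_bound(K, *box["K"])
    )
    f_model = np.asarray(fjc_force(x, params, rtol=1e-9))
    return FitResult(params, _rmse(f_model - f), len(x), converged)
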