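"""Least-squares inversion of M(H) curves for the bimodal moment distribution.

Fits the six free parameters (beta, mu1, mu2, sigma1, sigma2, M_S) of
:class:`~mpiphantom.magnetism.MomentDistribution` to a background-corrected
magnetization curve by bounded trust-region least squares.  The mean moments
are fitted on a log10 scale (in aAm^2) for conditioning; mode identity is
fixed after the fit by ordering mu1 < mu2, which prevents label switching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy.optimize import least_squares

from .magnetism import (
    AAM2,
    MAGHEMITE,
    MagnetizationCurve,
    MaterialConstants,
    MomentDistribution,
    mh_forward,
    moment_to_diameter,
)

__all__ = ["FitResult", "subtract_background", "fit_mh", "derive_summary", "default_init"]

# internal parameter vector: (beta, log10 mu1 [aAm^2], log10 mu2, sigma1, sigma2, ms)
_LOWER = np.array([0.0, -3.0, -3.0, 0.0, 0.0, 1e-6])
_UPPER = np.array([1.0, 3.0, 3.0, 1.5, 1.5, 100.0])


@dataclass
class FitResult:
    """Fitted distribution plus diagnostics and 1-sigma uncertainties.

    ``uncertainties`` maps parameter names (beta, mu1, mu2, sigma1, sigma2,
    ms_molar) to standard errors on the natural scale (Am^2 for moments),
    obtained from the Gauss-Newton covariance at the solution.
    """

    distribution: MomentDistribution
    uncertainties: dict = field(default_factory=dict)
    residual_norm: float = np.nan
    signal_norm: float = np.nan
    converged: bool = False
    n_evaluations: int = 0
    message: str = ""

    @property
    def d_v2_nm(self) -> float:
        """Equivalent-sphere volume diameter of mode B (nm)."""
        return moment_to_diameter(self.distribution.mu2, self.distribution.ms_molar)

    @property
    def beta_mu2_aam2(self) -> float:
        """Product beta * mu2 in aAm^2 (volume-fraction-weighted mode-B moment)."""
        return self.distribution.beta * self.distribution.mu2 / AAM2


def subtract_background(
    raw: MagnetizationCurve,
    blank: MagnetizationCurve,
    iron_amount_mol: float | None = None,
) -> MagnetizationCurve:
    """Remove a blank (empty-capsule / solvent) measurement from a raw curve.

    The blank — dominated by a diamagnetic, linear-in-H term — is linearly
    interpolated onto the raw field grid and subtracted pointwise.  If
    ``iron_amount_mol`` is given the difference is normalized per mol iron,
    turning a raw moment curve into a molar magnetization curve.
    """
    lo, hi = blank.field_t[0], blank.field_t[-1]
    span = hi - lo
    if raw.field_t[0] < lo - 1e-9 * span or raw.field_t[-1] > hi + 1e-9 * span:
        raise ValueError(
            "blank field range does not cover the raw curve "
            f"(raw [{raw.field_t[0]:g}, {raw.field_t[-1]:g}] T, "
            f"blank [{lo:g}, {hi:g}] T)"
        )
    blank_on_raw = np.interp(raw.field_t, blank.field_t, blank.magnetization)
    corrected = raw.magnetization - blank_on_raw
    if iron_amount_mol is not None:
        if iron_amount_mol <= 0:
            raise ValueError("iron amount must be strictly positive")
        corrected = corrected / iron_amount_mol
    return MagnetizationCurve(raw.field_t, corrected, raw.temperature)


def default_init(
    tem_mean_diameter_nm: float = 32.0,
    ms_molar: float = 6.0,
    temperature: float = 295.0,
) -> MomentDistribution:
    """Physically motivated starting point: mode A at a 10 nm equivalent
    moment, mode B at the TEM-mean equivalent moment, beta = 0.5, sigma = 0.2."""
    from .magnetism import diameter_to_moment

    return MomentDistribution(
        beta=0.5,
        mu1=diameter_to_moment(10.0, ms_molar),
        mu2=diameter_to_moment(tem_mean_diameter_nm, ms_molar),
        sigma1=0.2,
        sigma2=0.2,
        ms_molar=ms_molar,
        temperature=temperature,
    )


def _pack(dist: MomentDistribution) -> np.ndarray:
    return np.array(
        [
            dist.beta,
            np.log10(dist.mu1 / AAM2),
            np.log10(dist.mu2 / AAM2),
            dist.sigma1,
            dist.sigma2,
            dist.ms_molar,
        ]
    )


def _unpack(theta: np.ndarray, temperature: float) -> MomentDistribution:
    beta, lg1, lg2, s1, s2, ms = theta
    return MomentDistribution(
        beta=float(np.clip(beta, 0.0, 1.0)),
        mu1=10.0**lg1 * AAM2,
        mu2=10.0**lg2 * AAM2,
        sigma1=max(float(s1), 0.0),
        sigma2=max(float(s2), 0.0),
        ms_molar=float(ms),
        temperature=temperature,
    )


def fit_mh(
    curve: MagnetizationCurve,
    init: MomentDistribution | None = None,
    weights=None,
    nodes: int = 61,
    xtol: float = 1e-12,
) -> FitResult:
    """Fit the bimodal lognormal moment model to a magnetization curve.

    Weighted least squares against :func:`~mpiphantom.magnetism.mh_forward`
    using ``scipy.optimize.least_squares`` (trust-region reflective) with the
    physical bounds beta in [0, 1], sigma in [0, 1.5], moments in [1e-3,
    1e3] aAm^2.  Deterministic given data, init and weights.  Requires at
    least 8 data points per free parameter (48 points).
    """
    n_free = 6
    if len(curve) < 2 * n_free:
        raise ValueError(
            f"need >= {2 * n_free} points to constrain {n_free} parameters, "
            f"got {len(curve)}"
        )
    if len(curve) < 8 * n_free:
        warnings.warn(
            f"only {len(curve)} points for {n_free} free parameters; "
            "8 points per parameter are recommended for a stable fit",
            stacklevel=2,
        )
    if init is None:
        init = default_init(temperature=curve.temperature)
    w = np.ones(len(curve)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != curve.field_t.shape or np.any(w < 0):
        raise ValueError("weights must be non-negative, one per data point")

    y = curve.magnetization
    b = curve.field_t
    T = curve.temperature

    def residual(theta):
        dist = _unpack(theta, T)
        model = mh_forward(dist, b, temperature=T, nodes=nodes).magnetization
        return (model - y) * w

    theta0 = np.clip(_pack(init), _LOWER, _UPPER)
    sol = least_squares(
        residual,
        theta0,
        bounds=(_LOWER, _UPPER),
        method="trf",
        xtol=xtol,
        ftol=1e-12,
        gtol=1e-12,
    )
    theta = sol.x.copy()
    # fix mode identity: mode B is the large-moment mode
    if theta[1] > theta[2]:
        theta = np.array(
            [1.0 - theta[0], theta[2], theta[1], theta[4], theta[3], theta[5]]
        )
    dist = _unpack(theta, T)

    resid = residual(theta)
    m = len(resid)
    dof = max(m - n_free, 1)
    s2 = float(resid @ resid) / dof
    try:
        jtj = sol.jac.T @ sol.jac
        cov = s2 * np.linalg.pinv(jtj)
        sig_internal = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - pinv is robust
        sig_internal = np.full(n_free, np.nan)
    ln10 = np.log(10.0)
    uncertainties = {
        "beta": sig_internal[0],
        "mu1": sig_internal[1] * ln10 * dist.mu1,
        "mu2": sig_internal[2] * ln10 * dist.mu2,
        "sigma1": sig_internal[3],
        "sigma2": sig_internal[4],
        "ms_molar": sig_internal[5],
    }
    result = FitResult(
        distribution=dist,
        uncertainties=uncertainties,
        residual_norm=float(np.linalg.norm(resid)),
        signal_norm=float(np.linalg.norm(y * w)),
        converged=bool(sol.success),
        n_evaluations=int(sol.nfev),
        message=sol.message,
    )
    if not sol.success:
        result.message = f"fit did not converge: {sol.message}"
    return result


def derive_summary(
    fit: FitResult,
    tem_mean_diameter_nm: float | None = None,
    constants: MaterialConstants = MAGHEMITE,
) -> dict:
    """Summary parameters derived from a fitted distribution.

    Returns d_v2 (nm), beta*mu2 (aAm^2), the mode-B volume-fraction percent,
    M_S on both molar and mass scales, and — when a TEM mean diameter is
    supplied — the percent by which d_v2 falls below it.
    """
    dist = fit.distribution
    d_v2 = moment_to_diameter(dist.mu2, dist.ms_molar, constants)
    summary = {
        "d_v2_nm": d_v2,
        "beta_mu2_aam2": fit.beta_mu2_aam2,
        "mode_b_volume_percent": 100.0 * dist.beta,
        "ms_molar_am2_per_mol": dist.ms_molar,
        "ms_mass_am2_per_kg": dist.ms_molar / constants.fe_molar_mass,
        "sigma2": dist.sigma2,
        "mu2_aam2": dist.mu2 / AAM2,
    }
    if tem_mean_diameter_nm is not None:
        summary["tem_mean_diameter_nm"] = tem_mean_diameter_nm
        summary["percent_smaller_than_tem"] = 100.0 * (
            1.0 - d_v2 / tem_mean_diameter_nm
        )
    return summary
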