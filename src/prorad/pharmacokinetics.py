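"""Extended Tofts pharmacokinetic modelling of DCE-MRI concentration curves.

The dynamic contrast-enhanced (DCE) signal is treated as tracer concentration
in tissue, C_t(t).  The extended Tofts model relates it to the arterial plasma
concentration C_p(t) through three physiological quantities:

    C_t(t) = v_p * C_p(t) + Ktrans * int_0^t C_p(tau) exp(-kep (t - tau)) dtau

where Ktrans (min^-1) is the volume transfer constant between plasma and the
extravascular extracellular space (EES), kep (min^-1) the rate constant from
the EES back to plasma, v_e = Ktrans / kep the EES volume fraction, and v_p
the plasma volume fraction.

The arterial input function (AIF) is the Parker fixed population average:
a sum of two Gaussians plus an exponential decay modulated by a sigmoid,
converted from whole-blood to plasma concentration by 1 / (1 - Hct).

Because no signal-to-concentration calibration is performed, relative
enhancement is taken as proportional to concentration; fitted Ktrans values
are therefore on a relative scale unless calibrated input is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .errors import ConfigurationError, RegionStatsError

__all__ = [
    "PARKER_POPULATION",
    "DEFAULT_HEMATOCRIT",
    "ConcentrationCurve",
    "PKParameters",
    "parker_aif",
    "tofts_forward",
    "fit_tofts",
]

#: Population-average AIF constants (biexponential-free Parker form).
#: Units: A1, A2 in mmol*min; T1, T2, sigma1, sigma2, tau in min;
#: alpha in mmol; beta, s in min^-1.  Overridable per call.
PARKER_POPULATION: Mapping[str, float] = {
    "A1": 0.809,
    "A2": 0.330,
    "T1": 0.17046,
    "T2": 0.365,
    "sigma1": 0.0563,
    "sigma2": 0.132,
    "alpha": 1.050,
    "beta": 0.1685,
    "s": 38.078,
    "tau": 0.483,
}

#: Default hematocrit for the blood-to-plasma conversion C_p = C_b / (1 - Hct).
DEFAULT_HEMATOCRIT = 0.42

#: Internal quadrature step for the convolution integral, in seconds.
DEFAULT_GRID_DT_S = 1.0


@dataclass(frozen=True)
class ConcentrationCurve:
    """A sampled concentration-vs-time curve.

    t is in minutes with t = 0 at contrast injection; C is tracer
    concentration in mM or any fixed proportional unit.
    """

    t: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        C = np.asarray(self.C, dtype=float)
        if t.ndim != 1 or C.ndim != 1 or len(t) != len(C):
            raise ConfigurationError("t and C must be 1-D arrays of equal length")
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise ConfigurationError("time points must be strictly increasing")
        if len(t) and t[0] < 0:
            raise ConfigurationError("negative time points are not allowed")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "C", C)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class PKParameters:
    """Fitted or true extended-Tofts parameters for one region.

    ve is maintained as Ktrans / kep (the model identity); vp is carried
    internally but only Ktrans, kep and ve are exported as features.
    """

    Ktrans: float  # min^-1
    kep: float     # min^-1
    ve: float      # EES volume fraction
    vp: float = 0.0
    fit_rss: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if self.Ktrans < 0 or self.kep < 0 or self.ve < 0 or self.vp < 0:
            raise ConfigurationError("pharmacokinetic parameters must be >= 0")
        if self.Ktrans > 0 and self.kep <= 0:
            raise ConfigurationError("kep must be positive when Ktrans > 0")
        if self.ve > 1 + 1e-9 or self.vp >= 1:
            raise ConfigurationError("ve must be <= 1 and vp < 1")
        if self.kep > 0 and abs(self.ve * self.kep - self.Ktrans) > 1e-6 * max(1.0, self.Ktrans):
            raise ConfigurationError("ve * kep must equal Ktrans")

    @classmethod
    def from_rates(cls, Ktrans: float, kep: float, vp: float = 0.0,
                   **kwargs) -> "PKParameters":
        ve = Ktrans / kep if kep > 0 else 0.0
        return cls(Ktrans=Ktrans, kep=kep, ve=ve, vp=vp, **kwargs)


def parker_aif(t, hct: float = DEFAULT_HEMATOCRIT,
               constants: Mapping[str, float] | None = None) -> ConcentrationCurve:
    """Evaluate the Parker population-average AIF at times ``t`` (minutes).

    Whole-blood concentration is the sum of two Gaussian bolus terms and an
    exponentially decaying recirculation term gated by a sigmoid; the plasma
    curve is C_b / (1 - Hct).

    Raises
    ------
    ConfigurationError
        If any time point is negative or Hct is outside [0, 1).
    """
    c = dict(PARKER_POPULATION)
    if constants:
        c.update(constants)
    if not (0 <= hct < 1):
        raise ConfigurationError(f"hematocrit must be in [0, 1), got {hct}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ConfigurationError("negative time passed to parker_aif")

    cb = np.zeros_like(t)
    for a, mu, sig in ((c["A1"], c["T1"], c["sigma1"]),
                       (c["A2"], c["T2"], c["sigma2"])):
        cb += a / (sig * np.sqrt(2 * np.pi)) * np.exp(-((t - mu) ** 2) / (2 * sig ** 2))
    cb += c["alpha"] * np.exp(-c["beta"] * t) / (1 + np.exp(-c["s"] * (t - c["tau"])))
    return ConcentrationCurve(t=t, C=cb / (1.0 - hct))


def _fine_grid(t_max: float, grid_dt_s: float) -> np.ndarray:
    dt_min = grid_dt_s / 60.0
    n = int(np.ceil(t_max / dt_min)) + 1
    return np.linspace(0.0, t_max, max(n, 2))


def _exp_convolve(cp: np.ndarray, t: np.ndarray, kep: float) -> np.ndarray:
    """int_0^t cp(tau) exp(-kep (t - tau)) dtau on a shared grid (trapezoid).

    Rewritten as exp(-kep t) * cumtrapz(cp exp(kep tau)); safe in float64 for
    kep * t_max well below ~700.
    """
    if kep == 0.0:
        return cumulative_trapezoid(cp, t, initial=0.0)
    w = cp * np.exp(kep * (t - t[-1]))
    integ = cumulative_trapezoid(w, t, initial=0.0)
    return np.exp(-kep * (t - t[-1])) * integ


def tofts_forward(params: PKParameters, aif: ConcentrationCurve,
                  t_out=None, grid_dt_s: float = DEFAULT_GRID_DT_S) -> ConcentrationCurve:
    """Simulate the tissue curve from extended-Tofts parameters and an AIF.

    The convolution is evaluated by the trapezoidal rule on an internal grid
    with ``grid_dt_s`` second spacing, then sampled at ``t_out`` (defaults to
    the AIF time axis).
    """
    if params.kep < 0:
        raise ConfigurationError("kep must be >= 0")
    t_out = np.asarray(aif.t if t_out is None else t_out, dtype=float)
    if t_out.max() > aif.t.max() + 1e-9:
        raise ConfigurationError("AIF does not cover the requested output times")
    tf = _fine_grid(float(t_out.max()), grid_dt_s)
    cp = np.interp(tf, aif.t, aif.C)
    ct = params.vp * cp + params.Ktrans * _exp_convolve(cp, tf, params.kep)
    return ConcentrationCurve(t=t_out, C=np.interp(t_out, tf, ct))


#: Deterministic multi-start grid over (ve, kep, vp).
DEFAULT_FIT_STARTS: Sequence[tuple[float, float, float]] = tuple(
    (ve0, kep0, 0.01)
    for ve0 in (0.1, 0.3, 0.6)
    for kep0 in (0.3, 0.8, 2.0)
)

_FIT_LOWER = np.array([0.0, 1e-6, 0.0])
_FIT_UPPER = np.array([1.0, 20.0, 0.99])


def fit_tofts(curve: ConcentrationCurve, aif: ConcentrationCurve,
              grid_dt_s: float = DEFAULT_GRID_DT_S,
              starts: Sequence[tuple[float, float, float]] = DEFAULT_FIT_STARTS,
              ) -> PKParameters:
    """Fit (Ktrans, kep, vp) to a measured tissue curve by bounded nonlinear
    least squares with a fixed grid of starting points.

    The fit is parametrized over (ve, kep, vp) with ve in [0, 1], which
    enforces the ve = Ktrans / kep identity and physical bounds by
    construction.  ``converged`` is False when no start converged; the
    best-RSS parameters are still returned.
    """
    if len(curve) < 4:
        raise RegionStatsError("need at least 4 samples to fit the Tofts model")
    tf = _fine_grid(float(curve.t.max()), grid_dt_s)
    cp = np.interp(tf, aif.t, aif.C)
    c_obs = curve.C

    def residuals(theta):
        ve, kep, vp = theta
        ct = vp * cp + ve * kep * _exp_convolve(cp, tf, kep)
        return np.interp(curve.t, tf, ct) - c_obs

    best = None
    any_ok = False
    for x0 in starts:
        try:
            res = least_squares(residuals, x0=np.asarray(x0), bounds=(_FIT_LOWER, _FIT_UPPER),
                                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:  # pragma: no cover - defensive
            continue
        any_ok = any_ok or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RegionStatsError("Tofts fit failed from every starting point")
    ve, kep, vp = best.x
    return PKParameters(Ktrans=ve * kep, kep=kep, ve=ve, vp=vp,
                        fit_rss=float(2 * best.cost), converged=bool(any_ok))
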