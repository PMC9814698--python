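"""Two-state FRET thermodynamic model of peptide hairpin melting.

A donor/quencher pair reports the peptide end-to-end distance through the
Foerster transfer efficiency E(r) = R0^6 / (R0^6 + r^6).  The peptide is
modelled as a two-state unfolded/hairpin (U-H) equilibrium with
temperature-independent dH and dS, so the hairpin fraction at absolute
temperature T is f_H = K / (1 + K) with K = exp(-(dH - T dS) / (R T)).
Observed fluorescence is the population-weighted unquenched fraction
scaled by a single instrument factor:

    I(T) = scale * [ f_H (1 - E(r_H)) + (1 - f_H)(1 - E(r_U)) ].

Hairpin formation brings the labelled termini closer (r_H < r_U), so with
dH < 0 and dS < 0 the intensity rises monotonically with temperature as
the hairpin melts.  The default Foerster radius, 33 A, is that of the
EDANS/Dabcyl pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

GAS_CONSTANT = 8.314e-3  # kJ mol^-1 K^-1

__all__ = [
    "GAS_CONSTANT",
    "TwoStateParams",
    "MeltCurve",
    "TwoStateFit",
    "fret_efficiency",
    "hairpin_fraction",
    "predicted_intensity",
    "normalize_endpoint",
    "fit_two_state",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Thermodynamic and photophysical parameters of the U-H melt model.

    dH in kJ/mol and dS in kJ/(mol K) refer to hairpin formation; R0, r_U
    and r_H are in angstroms with r_H < r_U.
    """

    dH: float
    dS: float
    R0: float = 33.0
    r_U: float = 27.0
    r_H: float = 12.0
    scale: float = 1.0

    def __post_init__(self):
        if self.R0 <= 0 or self.r_U <= 0 or self.r_H <= 0:
            raise ValueError("distances must be positive")
        if self.r_H >= self.r_U:
            raise ValueError("hairpin distance r_H must be shorter than r_U")


@dataclass
class MeltCurve:
    """Fluorescence intensity versus temperature (degC, as recorded)."""

    temperature: np.ndarray
    intensity: np.ndarray
    condition_label: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.temperature.shape != self.intensity.shape:
            raise ValueError("temperature/intensity length mismatch")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be strictly increasing")


def fret_efficiency(r, R0: float = 33.0):
    """Foerster transfer efficiency at donor-acceptor distance r."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or R0 <= 0:
        raise ValueError("distances must be positive")
    ratio6 = (r / R0) ** 6
    out = 1.0 / (1.0 + ratio6)
    return float(out) if np.ndim(out) == 0 else out


def hairpin_fraction(T_kelvin, dH: float, dS: float):
    """Equilibrium hairpin fraction at absolute temperature T."""
    T = np.asarray(T_kelvin, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be positive")
    dG = dH - T * dS
    # logistic form of K/(1+K) avoids overflow for large |dG|
    out = 1.0 / (1.0 + np.exp(dG / (GAS_CONSTANT * T)))
    return float(out) if np.ndim(out) == 0 else out


def predicted_intensity(temperature_celsius, params: TwoStateParams):
    """Model fluorescence intensity at the given temperatures (degC)."""
    T = np.asarray(temperature_celsius, dtype=float) + 273.15
    f_h = hairpin_fraction(T, params.dH, params.dS)
    bright_h = 1.0 - fret_efficiency(params.r_H, params.R0)
    bright_u = 1.0 - fret_efficiency(params.r_U, params.R0)
    out = params.scale * (f_h * bright_h + (1.0 - f_h) * bright_u)
    return float(out) if np.ndim(out) == 0 else out


def normalize_endpoint(
    curve_a: MeltCurve, curve_b: MeltCurve, endpoint_celsius: float | None = None
) -> tuple[MeltCurve, MeltCurve]:
    """Scale ``curve_b`` so both curves coincide at the endpoint temperature.

    The endpoint defaults to the highest shared temperature (the melt
    protocol's 95 degC point, where conformational differences vanish);
    ``curve_a`` is returned unchanged.
    """
    if endpoint_celsius is None:
        endpoint_celsius = min(curve_a.temperature[-1], curve_b.temperature[-1])

    def endpoint_value(curve: MeltCurve) -> float:
        match = np.isclose(curve.temperature, endpoint_celsius)
        if not match.any():
            raise ValueError(
                f"{curve.condition_label or 'curve'} lacks the "
                f"{endpoint_celsius} degC endpoint"
            )
        return float(curve.intensity[match][0])

    factor = endpoint_value(curve_a) / endpoint_value(curve_b)
    scaled = MeltCurve(
        temperature=curve_b.temperature.copy(),
        intensity=curve_b.intensity * factor,
        condition_label=curve_b.condition_label,
    )
    return curve_a, scaled


@dataclass
class TwoStateFit:
    """Result of a least-squares two-state melt fit."""

    params: TwoStateParams
    converged: bool
    identifiable: bool
    residual_rms: float
    ci_dH: tuple[float, float] | None = None
    ci_dS: tuple[float, float] | None = None
    ci_scale: tuple[float, float] | None = None
    message: str = ""


def _fit_once(temps, intensities, fixed: TwoStateParams, x0):
    def residuals(x):
        dH, dS, scale = x
        p = replace(fixed, dH=dH, dS=dS, scale=scale)
        return predicted_intensity(temps, p) - intensities

    return least_squares(residuals, x0, method="lm", max_nfev=2000)


def fit_two_state(
    curve: MeltCurve,
    fixed: TwoStateParams | None = None,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> TwoStateFit:
    """Estimate (dH, dS, scale) from a melt curve with R0, r_U, r_H fixed.

    Multi-started Levenberg-Marquardt least squares; optional residual
    bootstrap gives percentile confidence intervals.  A flat model
    (r_H = r_U cannot occur by construction, but a curve with no
    temperature dependence) leaves dH/dS unidentifiable and is flagged
    rather than raised.
    """
    fixed = fixed or TwoStateParams(dH=-20.0, dS=-0.06)
    temps = curve.temperature
    intensities = curve.intensity
    if temps.size < 5:
        raise ValueError("need at least 5 temperature points to fit")

    span = float(np.ptp(intensities))
    level = float(np.mean(np.abs(intensities))) or 1.0
    if span / level < 1e-10:
        return TwoStateFit(
            params=replace(fixed, scale=float(np.mean(intensities))),
            converged=False,
            identifiable=False,
            residual_rms=0.0,
            message="flat curve: dH and dS are unidentifiable",
        )

    scale0 = float(np.max(intensities))
    starts = [
        (-20.0, -0.06, scale0),
        (-50.0, -0.15, scale0),
        (-5.0, -0.02, scale0),
        (fixed.dH, fixed.dS, scale0),
    ]
    best = None
    for x0 in starts:
        try:
            res = _fit_once(temps, intensities, fixed, x0)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return TwoStateFit(
            params=fixed, converged=False, identifiable=True,
            residual_rms=float("nan"), message="optimizer failed from all starts",
        )

    dH, dS, scale = best.x
    fitted = replace(fixed, dH=float(dH), dS=float(dS), scale=float(scale))
    rms = float(np.sqrt(np.mean(best.fun**2)))
    result = TwoStateFit(
        params=fitted,
        converged=bool(best.success),
        identifiable=True,
        residual_rms=rms,
        message=best.message,
    )

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        model = predicted_intensity(temps, fitted)
        # leverage correction: residuals of a p-parameter fit underestimate
        # the noise scale by sqrt((n - p) / n)
        n_params = 3
        resid = (intensities - model) * np.sqrt(
            temps.size / max(temps.size - n_params, 1)
        )
        samples = []
        for _ in range(n_bootstrap):
            boot = model + rng.choice(resid, size=resid.size, replace=True)
            try:
                res = _fit_once(temps, boot, fixed, (dH, dS, scale))
            except Exception:
                continue
            samples.append(res.x)
        if len(samples) >= max(10, n_bootstrap // 2):
            arr = np.asarray(samples)
            lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
            result.ci_dH = (float(lo[0]), float(hi[0]))
            result.ci_dS = (float(lo[1]), float(hi[1]))
            result.ci_scale = (float(lo[2]), float(hi[2]))
    return result
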