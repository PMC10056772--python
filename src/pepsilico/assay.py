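"""Radical-scavenging assay arithmetic and IC50 estimation.

Scavenging ratios from plate-reader absorbances:

* DPPH:        R = 1 - (As - Ac) / Ab   (sample, sample-colour control, blank)
* colorimetric kits (hydroxyl, superoxide): R = (Acontrol - Asample) / Acontrol
* ABTS capacity vs a standard:              R = (A0 - A1) / A0

The last two are the same algebraic map; all three are invariant under a
common rescaling of the absorbances. Values outside [0, 1] are returned as
computed, with a warning — negative scavenging is a meaningful blank
artifact and should be visible, not clipped.

IC50 is estimated either by a four-parameter logistic (4PL) fit

    R(c) = bottom + (top - bottom) / (1 + (IC50 / c)^slope)

with the bottom fixed at 0 and the top free (the default, mimicking common
dose-response software), or by log-linear interpolation at R = 0.5 for
sparse data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


def _warn_out_of_range(r: float, name: str) -> float:
    if not (0.0 <= r <= 1.0):
        warnings.warn(f"{name} scavenging ratio {r:.4g} outside [0, 1]")
    return r


def dpph_scavenging(a_sample: float, a_control: float, a_blank: float) -> float:
    """DPPH scavenging ratio R = 1 - (As - Ac) / Ab."""
    if a_blank <= 0:
        raise ValueError("blank absorbance must be positive")
    return _warn_out_of_range(1.0 - (a_sample - a_control) / a_blank, "DPPH")


def ratio_scavenging(a_control: float, a_sample: float) -> float:
    """Kit scavenging ratio R = (Acontrol - Asample) / Acontrol."""
    if a_control <= 0:
        raise ValueError("control absorbance must be positive")
    return _warn_out_of_range((a_control - a_sample) / a_control, "ratio")


def abts_capacity(a_standard: float, a_sample: float) -> float:
    """ABTS capacity R = (A0 - A1) / A0 against the standard A0."""
    if a_standard <= 0:
        raise ValueError("standard absorbance must be positive")
    return _warn_out_of_range((a_standard - a_sample) / a_standard, "ABTS")


def four_param_logistic(
    c: np.ndarray, bottom: float, top: float, ic50: float, slope: float
) -> np.ndarray:
    """4PL dose-response curve; c and IC50 share units (e.g. mg/mL)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / c) ** slope)


@dataclass
class Ic50Fit:
    ic50: float
    bottom: float
    top: float
    slope: float
    mode: str
    residual_rms: float | None = None


def fit_ic50(
    concentrations,
    responses,
    mode: str = "4pl",
    fix_bottom: float | None = 0.0,
) -> Ic50Fit:
    """Estimate IC50 from a dose-response series.

    4PL mode (default): least-squares fit with the bottom fixed at
    ``fix_bottom`` (pass None to free it) and top/IC50/slope free; needs
    at least 4 points. Interpolation mode: log-linear interpolation of the
    response at R = 0.5; the series must bracket 0.5.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise ValueError("concentration and response series differ in length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be strictly positive")

    if mode == "interpolate":
        order = np.argsort(c)
        c, r = c[order], r[order]
        above = np.nonzero(r >= 0.5)[0]
        below = np.nonzero(r <= 0.5)[0]
        if above.size == 0 or below.size == 0:
            raise ValueError("responses do not bracket 0.5; cannot interpolate")
        i = above[0] if r[0] < 0.5 else below[0]
        if r[i] == 0.5:
            return Ic50Fit(float(c[i]), 0.0, 1.0, float("nan"), mode)
        j, k = i - 1, i
        frac = (0.5 - r[j]) / (r[k] - r[j])
        log_ic50 = np.log(c[j]) + frac * (np.log(c[k]) - np.log(c[j]))
        return Ic50Fit(float(np.exp(log_ic50)), 0.0, 1.0, float("nan"), mode)

    if mode != "4pl":
        raise ValueError(f"unknown IC50 mode {mode!r}")
    if c.size < 4:
        raise ValueError("4PL fit needs at least 4 points")

    top0 = float(np.clip(r.max(), 0.1, 2.0))
    ic0 = float(np.exp(np.mean(np.log(c))))
    if fix_bottom is None:
        def model(x, bottom, top, ic50, slope):
            return four_param_logistic(x, bottom, top, ic50, slope)
        p0 = [0.0, top0, ic0, 1.0]
        bounds = ([-1.0, 0.0, c.min() / 1e3, 0.05], [1.0, 2.5, c.max() * 1e3, 20.0])
    else:
        b = float(fix_bottom)
        def model(x, top, ic50, slope):
            return four_param_logistic(x, b, top, ic50, slope)
        p0 = [top0, ic0, 1.0]
        bounds = ([0.0, c.min() / 1e3, 0.05], [2.5, c.max() * 1e3, 20.0])
    try:
        popt, _ = curve_fit(model, c, r, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"4PL fit did not converge (n={c.size}, response range "
            f"[{r.min():.3g}, {r.max():.3g}]): {exc}"
        ) from exc
    resid = r - model(c, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if fix_bottom is None:
        bottom, top, ic50, slope = popt
    else:
        bottom = float(fix_bottom)
        top, ic50, slope = popt
    return Ic50Fit(float(ic50), float(bottom), float(top), float(slope), mode, rms)
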