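"""AFM force-curve mechanics.

Extension (approach) force curves are processed in four steps: baseline /
contact-point detection, indentation correction for cantilever deflection
(δ = (z − z_c) − F/k), a linearised Hertz fit of F^{2/3} against δ over the
5–20 % indentation window, and a height filter that drops curves measured
on regions thinner than 150 nm (where substrate effects dominate).

The fitted modulus is reported as the *apparent* Young's modulus
(``E_apparent_Pa``): with sub-micron samples and a small-radius tip the
Hertz assumptions of infinite thickness and low strain do not hold, so the
value tracks relative changes in mechanical properties rather than an
absolute stiffness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ForceCurve",
    "HertzFit",
    "HeightFilterResult",
    "NoContactError",
    "FitFailedError",
    "find_contact_point",
    "compute_indentation",
    "fit_hertz_linearized",
    "fit_hertz_nonlinear",
    "apply_height_filter",
    "fit_curve",
    "summarize_condition",
    "read_curve_tsv",
    "analyze_curve_dir",
]

HEIGHT_THRESHOLD_M = 150e-9


class NoContactError(RuntimeError):
    """No contact point could be located on the curve."""


class FitFailedError(RuntimeError):
    """The Hertz fit failed (window too small or nonpositive slope)."""


@dataclass
class ForceCurve:
    """Extension-segment force record: piezo position vs force, plus probe
    metadata (spring constant k, tip radius R, Poisson ratio ν)."""

    z_m: np.ndarray
    force_N: np.ndarray
    k: float
    R: float
    nu: float = 0.5
    sampling_rate_hz: float = 250.0
    site_height_m: float | None = None
    cell_id: str = ""
    condition: str = ""
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.z_m = np.asarray(self.z_m, float)
        self.force_N = np.asarray(self.force_N, float)
        if self.z_m.shape != self.force_N.shape or self.z_m.ndim != 1:
            raise ValueError("z and force must be equal-length 1D arrays")
        if len(self.z_m) < 50:
            raise ValueError("curve too short (< 50 samples)")
        if self.k <= 0 or self.R <= 0:
            raise ValueError("k and R must be positive")


@dataclass
class BaselineFit:
    intercept: float
    slope: float
    noise_sd: float
    z_contact_m: float | None = None   # sub-sample refined contact position

    def at(self, z: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * z


@dataclass
class HertzFit:
    contact_index: int
    contact_z_m: float
    delta_max_m: float
    fit_window: tuple[int, int]
    E_app_Pa: float
    r_squared: float
    slope: float
    intercept: float


@dataclass
class HeightFilterResult:
    height_m: float
    passes: bool


def _smooth(y: np.ndarray, w: int = 5) -> np.ndarray:
    if w <= 1:
        return y
    kernel = np.ones(w) / w
    return np.convolve(y, kernel, mode="same")


def find_contact_point(curve: ForceCurve, noise_factor: float = 3.0,
                       min_run: int = 5) -> tuple[int, BaselineFit]:
    """Locate the contact point on an extension curve.

    A line is fitted to the leading (pre-contact) segment; the first index
    where the smoothed force exceeds the baseline by ``noise_factor`` times
    the baseline noise SD, and stays above for at least ``min_run``
    samples, marks the threshold crossing.  The crossing is then refined by
    extrapolating a local F^{2/3}-vs-z fit back to zero force, which
    removes the bias of thresholding on a slowly rising power law.
    """
    z, f = curve.z_m, curve.force_N
    n = len(z)
    lead = max(20, n // 4)
    if n < lead + 10:
        raise NoContactError("curve too short for baseline estimation")
    coef = np.polyfit(z[:lead], f[:lead], 1)
    baseline = BaselineFit(intercept=coef[1], slope=coef[0],
                           noise_sd=float(np.std(f[:lead] - np.polyval(coef, z[:lead]))))
    resid = _smooth(f - baseline.at(z), 5)
    thresh = max(noise_factor * baseline.noise_sd, 1e-15)
    above = resid > thresh
    idx = None
    for i in range(lead // 2, n - min_run + 1):
        if above[i] and above[i:i + min_run].all():
            idx = i
            break
    if idx is None:
        raise NoContactError("no sustained force rise above baseline")

    # refinement: with x = z - F/k (tip-sample distance), the Hertz law gives
    # F^(2/3) = a * (x - z_contact) exactly, so the x-intercept of a linear
    # fit over the whole post-contact segment recovers the contact position
    # at sub-sample precision
    fc = f - baseline.at(z)
    baseline.z_contact_m = float(z[idx])
    fcmax = fc[idx:].max()
    # only high-force samples enter the refinement fit: the F^(2/3)
    # transform is noise-stable there, and smoothing-leaked pre-contact
    # samples are excluded
    sel = np.zeros(n, bool)
    sel[idx:] = fc[idx:] >= max(0.1 * fcmax, thresh)
    x = (z - fc / curve.k)[sel]
    y = fc[sel] ** (2.0 / 3.0)
    if len(y) >= 4 and np.ptp(y) > 0:
        a, b = np.polyfit(x, y, 1)
        if a > 0:
            zc = -b / a
            if z[0] <= zc <= z[min(idx + 5, n - 1)]:
                baseline.z_contact_m = float(zc)
                idx = int(np.clip(np.searchsorted(z, zc), 1, n - 1))
    return idx, baseline


def compute_indentation(curve: ForceCurve, contact_index: int,
                        baseline: BaselineFit | None = None) -> np.ndarray:
    """Indentation δ_i = (z_i − z_contact) − F_i/k on post-contact samples.

    Returns an array aligned with the post-contact portion of the curve
    (``curve.z_m[contact_index:]``); negative values are floored at 0.  If
    the baseline carries a sub-sample refined contact position it is used
    as the indentation origin instead of the sample grid point.
    """
    z = curve.z_m[contact_index:]
    f = curve.force_N[contact_index:]
    zc = curve.z_m[contact_index]
    if baseline is not None:
        f = f - baseline.at(z)
        if baseline.z_contact_m is not None:
            zc = baseline.z_contact_m
    delta = (z - zc) - f / curve.k
    if np.all(delta <= 0):
        raise FitFailedError("no positive indentation past contact")
    return np.clip(delta, 0.0, None)


def _window_mask(delta: np.ndarray, lo: float, hi: float) -> np.ndarray:
    dmax = delta.max()
    return (delta >= lo * dmax) & (delta <= hi * dmax)


def fit_hertz_linearized(curve: ForceCurve, delta: np.ndarray,
                         contact_index: int,
                         baseline: BaselineFit | None = None,
                         window_lo: float = 0.05, window_hi: float = 0.20,
                         min_samples: int = 10) -> HertzFit:
    """Linearised Hertz fit over the [window_lo, window_hi] indentation window.

    OLS of F^{2/3} on δ gives slope a; E_app = (3/4) a^{3/2} (1−ν²) / √R.
    """
    z = curve.z_m[contact_index:]
    f = curve.force_N[contact_index:]
    if baseline is not None:
        f = f - baseline.at(z)
    mask = _window_mask(delta, window_lo, window_hi)
    if mask.sum() < min_samples:
        raise FitFailedError(
            f"only {int(mask.sum())} samples in the {window_lo:.0%}-{window_hi:.0%} window")
    d = delta[mask]
    y = np.where(f[mask] > 0, f[mask], 0.0) ** (2.0 / 3.0)
    a, b = np.polyfit(d, y, 1)
    if a <= 0:
        raise FitFailedError("nonpositive slope in linearised fit")
    yhat = a * d + b
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    E = 0.75 * a ** 1.5 * (1.0 - curve.nu ** 2) / np.sqrt(curve.R)
    idx = np.flatnonzero(mask)
    return HertzFit(
        contact_index=contact_index,
        contact_z_m=float(curve.z_m[contact_index]),
        delta_max_m=float(delta.max()),
        fit_window=(contact_index + int(idx[0]), contact_index + int(idx[-1]) + 1),
        E_app_Pa=float(E),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        slope=float(a),
        intercept=float(b),
    )


def fit_hertz_nonlinear(curve: ForceCurve, delta: np.ndarray,
                        contact_index: int,
                        baseline: BaselineFit | None = None,
                        window_lo: float = 0.05, window_hi: float = 0.20,
                        min_samples: int = 10) -> float:
    """Nonlinear least squares of F = (4/3) E/(1−ν²) √R δ^{3/2} on the same
    window; used as an independent cross-check of the linearised fit."""
    z = curve.z_m[contact_index:]
    f = curve.force_N[contact_index:]
    if baseline is not None:
        f = f - baseline.at(z)
    mask = _window_mask(delta, window_lo, window_hi)
    if mask.sum() < min_samples:
        raise FitFailedError("window too small for nonlinear fit")
    d, y = delta[mask], f[mask]
    pref = (4.0 / 3.0) / (1.0 - curve.nu ** 2) * np.sqrt(curve.R)
    y_scale = float(np.max(np.abs(y)))
    if y_scale <= 0:
        raise FitFailedError("no positive forces in window")
    E0 = y_scale / (pref * float(np.max(d)) ** 1.5)
    # residuals normalised to the window force scale; parameter in units of
    # the crude initial estimate, so the solver sees an O(1) problem
    res = least_squares(lambda p: (pref * p[0] * E0 * d ** 1.5 - y) / y_scale,
                        x0=[1.0], bounds=([0.0], [np.inf]), xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    E = float(res.x[0] * E0)
    if not res.success or E <= 0:
        raise FitFailedError("nonlinear fit did not converge")
    return E


def apply_height_filter(site_height_m: float,
                        threshold_m: float = HEIGHT_THRESHOLD_M) -> HeightFilterResult:
    """Keep only curves measured where the sample is thicker than 150 nm
    (strict inequality)."""
    if site_height_m < 0:
        raise ValueError("height must be nonnegative")
    # relative guard so a height equal to the threshold up to float
    # round-off is excluded
    passes = site_height_m > threshold_m * (1.0 + 1e-9)
    return HeightFilterResult(height_m=float(site_height_m), passes=bool(passes))


def fit_curve(curve: ForceCurve, window_lo: float = 0.05,
              window_hi: float = 0.20) -> HertzFit:
    """Full single-curve pipeline: contact point, indentation, linearised fit."""
    idx, baseline = find_contact_point(curve)
    delta = compute_indentation(curve, idx, baseline)
    return fit_hertz_linearized(curve, delta, idx, baseline,
                                window_lo=window_lo, window_hi=window_hi)


def summarize_condition(fits: pd.DataFrame, min_cells: int = 5,
                        min_curves_per_cell: int = 10) -> pd.DataFrame:
    """Long-format per-condition summary of apparent moduli.

    Flags conditions with fewer than ``min_cells`` cells or any cell with
    fewer than ``min_curves_per_cell`` curves (the study's sampling
    guideline).
    """
    if fits.empty:
        raise ValueError("no fits to summarize")
    out = []
    for cond, g in fits.groupby("condition"):
        per_cell = g.groupby("cell_id").size()
        out.append({
            "condition": cond,
            "n_cells": int(per_cell.size),
            "n_curves": int(len(g)),
            "median_E_apparent_Pa": float(g["E_apparent_Pa"].median()),
            "mean_E_apparent_Pa": float(g["E_apparent_Pa"].mean()),
            "sem_E_apparent_Pa": float(g["E_apparent_Pa"].sem()),
            "flag_low_sampling": bool(per_cell.size < min_cells
                                      or (per_cell < min_curves_per_cell).any()),
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# I/O


def read_curve_tsv(tsv_path: str | Path) -> ForceCurve:
    """Read a curve from TSV (columns z_m, force_N) plus its sidecar JSON
    (k, R, nu, sampling_rate, optional site_height_m / cell_id / condition)."""
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t")
    meta = json.loads(tsv_path.with_suffix(".json").read_text())
    return ForceCurve(
        z_m=df["z_m"].to_numpy(), force_N=df["force_N"].to_numpy(),
        k=meta["k"], R=meta["R"], nu=meta.get("nu", 0.5),
        sampling_rate_hz=meta.get("sampling_rate", 250.0),
        site_height_m=meta.get("site_height_m"),
        cell_id=meta.get("cell_id", ""), condition=meta.get("condition", ""),
        curve_id=tsv_path.stem,
    )


def analyze_curve_dir(curve_dir: str | Path, nu: float | None = None,
                      window_lo: float = 0.05, window_hi: float = 0.20) -> pd.DataFrame:
    """Fit every ``*.tsv`` curve under ``curve_dir``; one row per curve."""
    rows = []
    for f in sorted(Path(curve_dir).glob("**/*.tsv")):
        curve = read_curve_tsv(f)
        if nu is not None:
            curve.nu = nu
        height_pass = True
        if curve.site_height_m is not None:
            height_pass = apply_height_filter(curve.site_height_m).passes
        try:
            fit = fit_curve(curve, window_lo, window_hi)
        except (NoContactError, FitFailedError) as exc:
            rows.append({"curve_id": curve.curve_id, "cell_id": curve.cell_id,
                         "condition": curve.condition, "error": str(exc),
                         "height_pass": height_pass})
            continue
        rows.append({
            "curve_id": curve.curve_id, "cell_id": curve.cell_id,
            "condition": curve.condition, "contact_z_m": fit.contact_z_m,
            "delta_max_m": fit.delta_max_m, "E_apparent_Pa": fit.E_app_Pa,
            "r2": fit.r_squared, "height_pass": height_pass, "error": "",
        })
    if not rows:
        raise FileNotFoundError(f"no .tsv curves under {curve_dir}")
    return pd.DataFrame(rows)
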