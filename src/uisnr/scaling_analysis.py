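"""Power-law scaling of uiSNR versus static field strength B0.

The uiSNR does not follow a single power law across 0.55-14 T: the slope
of log uiSNR vs log B0 itself grows with B0 as the RF fields move from
the near-field to the far-field regime. The analysis therefore fits
``S(B0) = a B0^alpha`` piecewise in a low-field regime (default
0.55-3 T, near-linear alpha ~ 1) and a high-field regime (default
5-14 T, near-quadratic alpha ~ 2), per voxel, with Levenberg-Marquardt
on the linear-scale model initialized from the log-log least-squares
line. Between adjacent field strengths the *effective* exponent

    alpha_eff = log(S_high / S_low) / log(B0_high / B0_low)

summarizes the local slope without any fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigError
from .phantom import VoxelModel
from .uisnr_core import ConvergenceMask

#: The simulated B0 grid (T) and its default regime split.
DEFAULT_B0_GRID = (0.55, 1.5, 3.0, 5.0, 7.0, 10.5, 11.7, 14.0)
DEFAULT_LOW_REGIME = (0.55, 1.5, 3.0)
DEFAULT_HIGH_REGIME = (5.0, 7.0, 10.5, 11.7, 14.0)


@dataclass(frozen=True)
class FitSettings:
    """Levenberg-Marquardt stopping rules for the power-law fit."""

    tolerance: float = 1e-10
    max_iterations: int = 500


@dataclass
class ScalingFit:
    """Per-voxel power-law fit over one B0 regime.

    ``alpha`` (exponent) and ``amplitude`` are NaN where the fit did not
    converge (e.g. non-positive SNR input); ``residual`` is the sum of
    squared linear-scale residuals.
    """

    alpha: np.ndarray
    amplitude: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    regime: tuple[float, ...]


@dataclass
class TissueStats:
    """Per-tissue summary of the scaling exponent within a mask."""

    table: pd.DataFrame = field(repr=False)

    def row(self, tissue: str) -> pd.Series:
        return self.table.set_index("tissue").loc[tissue]


def _fit_one(b0: np.ndarray, s: np.ndarray,
             settings: FitSettings) -> tuple[float, float, float, bool]:
    logs = np.log(s)
    logb = np.log(b0)
    slope, intercept = np.polyfit(logb, logs, 1)
    p0 = np.array([np.exp(intercept), slope])

    def resid(p):
        return p[0] * b0 ** p[1] - s

    try:
        res = least_squares(resid, p0, method="lm",
                            xtol=settings.tolerance,
                            ftol=settings.tolerance,
                            gtol=settings.tolerance,
                            max_nfev=settings.max_iterations
                            * (len(p0) + 1))
    except Exception:
        return np.nan, np.nan, np.nan, False
    a, alpha = res.x
    return float(alpha), float(a), float(2.0 * res.cost), bool(res.success)


def fit_power_law(snr_values: np.ndarray, b0_list: Sequence[float],
                  settings: FitSettings | None = None) -> ScalingFit:
    """Per-voxel LM fit of ``S = a B0^alpha``.

    ``snr_values`` has shape ``(n_fields, ...)`` with the leading axis
    matching ``b0_list``. Voxels with any non-positive or non-finite
    SNR are flagged not-converged and left NaN.
    """
    settings = settings or FitSettings()
    b0 = np.asarray(b0_list, dtype=float)
    snr = np.asarray(snr_values, dtype=float)
    if b0.ndim != 1 or len(b0) < 2:
        raise ConfigError("need at least 2 field strengths")
    if snr.shape[0] != len(b0):
        raise ValueError("leading axis of snr_values must match b0_list")
    vox_shape = snr.shape[1:]
    flat = snr.reshape(len(b0), -1)
    n_vox = flat.shape[1]
    alpha = np.full(n_vox, np.nan)
    amp = np.full(n_vox, np.nan)
    resid = np.full(n_vox, np.nan)
    conv = np.zeros(n_vox, dtype=bool)
    usable = np.all(np.isfinite(flat) & (flat > 0), axis=0)
    for j in np.nonzero(usable)[0]:
        alpha[j], amp[j], resid[j], conv[j] = _fit_one(b0, flat[:, j],
                                                       settings)
    return ScalingFit(alpha=alpha.reshape(vox_shape),
                      amplitude=amp.reshape(vox_shape),
                      residual=resid.reshape(vox_shape),
                      converged=conv.reshape(vox_shape),
                      regime=tuple(b0))


def piecewise_fit(snr_by_b0: Mapping[float, np.ndarray],
                  low_regime: Sequence[float] = DEFAULT_LOW_REGIME,
                  high_regime: Sequence[float] = DEFAULT_HIGH_REGIME,
                  settings: FitSettings | None = None
                  ) -> tuple[ScalingFit, ScalingFit]:
    """Independent power-law fits in the low- and high-field regimes."""
    low = tuple(float(b) for b in low_regime)
    high = tuple(float(b) for b in high_regime)
    if len(low) < 2 or len(high) < 2:
        raise ConfigError("each regime needs at least 2 field strengths")
    if set(low) & set(high):
        raise ConfigError("regimes must be disjoint")
    missing = [b for b in low + high if b not in snr_by_b0]
    if missing:
        raise ConfigError(f"no SNR maps for B0 = {missing}")
    fits = []
    for regime in (low, high):
        stack = np.stack([np.asarray(snr_by_b0[b], dtype=float)
                          for b in regime])
        fits.append(fit_power_law(stack, regime, settings))
    return fits[0], fits[1]


def effective_exponent(snr_low, snr_high, b0_low: float,
                       b0_high: float):
    """log(S_high/S_low) / log(B0_high/B0_low); elementwise on arrays."""
    if b0_high <= b0_low or b0_low <= 0:
        raise ValueError("require 0 < b0_low < b0_high")
    snr_low = np.asarray(snr_low, dtype=float)
    snr_high = np.asarray(snr_high, dtype=float)
    if np.any(snr_low <= 0) or np.any(snr_high <= 0):
        raise ValueError("SNR values must be positive")
    out = np.log(snr_high / snr_low) / np.log(b0_high / b0_low)
    return out if out.ndim else float(out)


def tissue_statistics(fit: ScalingFit, model: VoxelModel,
                      mask: ConvergenceMask | np.ndarray | None = None,
                      unions: Mapping[str, Sequence[int]] | None = None
                      ) -> TissueStats:
    """Mean/std of the fitted exponent per tissue within the mask.

    Statistics use only converged voxels inside the (convergence) mask;
    the standard deviation is the population form (divide by n). Label
    unions (e.g. whole body) are recomputed over the pooled voxels, not
    averaged over per-tissue means. Tissues with no eligible voxel are
    reported with count 0 and NaN statistics.
    """
    if fit.alpha.shape != model.shape:
        raise ValueError("fit and model grids are not aligned")
    if mask is None:
        mask_arr = np.ones(model.shape, dtype=bool)
    elif isinstance(mask, ConvergenceMask):
        mask_arr = mask.mask
    else:
        mask_arr = np.asarray(mask, dtype=bool)
    eligible = mask_arr & fit.converged & np.isfinite(fit.alpha)

    labels_present = [int(v) for v in np.unique(model.labels) if v != 0]
    groups: list[tuple[str, np.ndarray]] = []
    for lab in labels_present:
        name = model.tissue_table[lab].name
        groups.append((name, model.labels == lab))
    all_unions = {"whole_body": labels_present}
    if unions:
        all_unions.update({k: list(v) for k, v in unions.items()})
    for name, labs in all_unions.items():
        groups.append((name, np.isin(model.labels, labs)))

    rows = []
    for name, sel in groups:
        vals = fit.alpha[sel & eligible]
        n = vals.size
        rows.append({
            "tissue": name,
            "mean_alpha": float(vals.mean()) if n else np.nan,
            "std_alpha": float(vals.std()) if n else np.nan,  # population
            "n_voxels": n,
        })
    return TissueStats(table=pd.DataFrame(rows))


def xnuclei_field(frequency: float, gamma_over_2pi: float) -> float:
    """B0 (T) at which a nucleus with ``gamma_over_2pi`` resonates.

    Converts a frequency window observed for one nucleus (e.g. the
    proton linear-to-superlinear transition between 127.7 and 212.9 MHz)
    into the corresponding field range for another nucleus.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if gamma_over_2pi == 0:
        raise ValueError("gyromagnetic ratio must be nonzero")
    return frequency / abs(gamma_over_2pi)


def xnuclei_field_ranges(frequencies: Sequence[float],
                         gammas: Mapping[str, float]) -> pd.DataFrame:
    """Per-nucleus B0 values for a list of frequencies (Hz)."""
    rows = []
    for name, g in gammas.items():
        rows.append({"nucleus": name,
                     **{f"B0_at_{f / 1e6:.6g}_MHz_T": xnuclei_field(f, g)
                        for f in frequencies}})
    return pd.DataFrame(rows)
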