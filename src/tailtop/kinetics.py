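"""Synthesis and decay half-life estimation from SLAM labeling courses.

The labeled fraction of a transcript's pool is inferred from its T→C
conversion rate, normalized to the saturation conversion measured at time 0
of the catabolic (chase) course — i.e. after the long 4sU pre-label.  On
the normalized scale the chase follows ``A·exp(−k t)`` (amplitude free) and
the pulse ``1 − exp(−k t)``, both fitted by nonlinear least squares in
minutes; the half-life is ``ln 2 / k``.

Fits are screened the way the field screens them: only fits with R² > 0.6
are interpreted, and half-lives outside (0, 5000) minutes are flagged as
outliers.  Flat data (zero total sum of squares) gets R² defined as 0 and
is filtered out rather than raising.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FitStatus",
    "KineticFit",
    "normalize_conversions",
    "fit_decay",
    "fit_synthesis",
    "fit_transcripts",
    "filter_fits",
]

LN2 = math.log(2.0)
R2_THRESHOLD = 0.6
HALF_LIFE_BOUNDS_MIN = (0.0, 5000.0)


class FitStatus(enum.Enum):
    OK = "ok"
    LOW_R2 = "low_r2"
    OUTLIER = "outlier"
    UNNORMALIZABLE = "unnormalizable"
    INSUFFICIENT_DATA = "insufficient_data"


@dataclass
class KineticFit:
    """One transcript's exponential fit (rate in 1/min, half-life in min)."""

    transcript_id: str
    mode: str  # "synthesis" or "decay"
    k_per_min: float
    half_life_min: float
    r_squared: float
    status: FitStatus
    n_points: int = 0
    amplitude: float = float("nan")
    message: str = ""


def normalize_conversions(records: pd.DataFrame, background: float = 0.0) -> pd.DataFrame:
    """Normalize conversion rates to each transcript's saturation conversion.

    The saturation anchor is the replicate-mean conversion at time 0 of the
    catabolic course; the normalized labeled fraction is
    ``(conversion − background) / (saturation − background)``.  Values may
    exceed 1 (noise) and are flagged, not clipped.  Transcripts whose
    saturation does not exceed the background are marked ``unnormalizable``
    and must be excluded from fitting.
    """
    required = {"transcript_id", "design", "time_h", "replicate", "conversion_rate"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns {sorted(missing)}")
    anchor = records[(records["design"] == "catabolic") & (records["time_h"] == 0.0)]
    sat = anchor.groupby("transcript_id")["conversion_rate"].mean().rename("saturation")
    out = records.merge(sat, on="transcript_id", how="left")
    out["unnormalizable"] = ~(out["saturation"] > background)
    denom = out["saturation"] - background
    with np.errstate(divide="ignore", invalid="ignore"):
        out["normalized_fraction"] = np.where(
            out["unnormalizable"], np.nan, (out["conversion_rate"] - background) / denom
        )
    out["exceeds_one"] = out["normalized_fraction"] > 1.0
    return out


def _finalize(transcript_id, mode, k, amplitude, r2, n_points, message=""):
    half_life = LN2 / k if k > 0 else math.inf
    status = _status_for(r2, half_life)
    return KineticFit(
        transcript_id=transcript_id,
        mode=mode,
        k_per_min=k,
        half_life_min=half_life,
        r_squared=r2,
        status=status,
        n_points=n_points,
        amplitude=amplitude,
        message=message,
    )


def _status_for(r2: float, half_life: float) -> FitStatus:
    lo, hi = HALF_LIFE_BOUNDS_MIN
    if not r2 > R2_THRESHOLD:
        return FitStatus.LOW_R2
    if not (lo < half_life < hi):
        return FitStatus.OUTLIER
    return FitStatus.OK


def _r_squared(y, y_hat) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0  # flat data: define R^2 = 0 so the filter removes it
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def _prepare(times_h, fractions, transcript_id, mode):
    t = np.asarray(times_h, dtype=float) * 60.0  # fit in minutes
    y = np.asarray(fractions, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(np.unique(t)) < 3:
        return t, y, KineticFit(
            transcript_id=transcript_id,
            mode=mode,
            k_per_min=math.nan,
            half_life_min=math.nan,
            r_squared=math.nan,
            status=FitStatus.INSUFFICIENT_DATA,
            n_points=int(len(t)),
            message="fewer than 3 distinct time points",
        )
    return t, y, None


def fit_decay(times_h, fractions, transcript_id: str = "", k0: float = LN2 / 180.0) -> KineticFit:
    """Fit ``A·exp(−k t)`` to a chase course (times in hours, k in 1/min)."""
    t, y, early = _prepare(times_h, fractions, transcript_id, "decay")
    if early is not None:
        return early
    a0 = float(np.clip(y[t == t.min()].mean(), 1e-6, 10.0))
    try:
        popt, _ = curve_fit(
            lambda tt, a, k: a * np.exp(-k * tt),
            t,
            y,
            p0=(a0, k0),
            bounds=((0.0, 1e-9), (10.0, 1.0)),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return KineticFit(
            transcript_id=transcript_id,
            mode="decay",
            k_per_min=math.nan,
            half_life_min=math.nan,
            r_squared=math.nan,
            status=FitStatus.INSUFFICIENT_DATA,
            n_points=len(t),
            message=f"optimizer failed: {exc}",
        )
    a, k = float(popt[0]), float(popt[1])
    r2 = _r_squared(y, a * np.exp(-k * t))
    return _finalize(transcript_id, "decay", k, a, r2, len(t))


def fit_synthesis(times_h, fractions, transcript_id: str = "", k0: float = LN2 / 180.0) -> KineticFit:
    """Fit ``1 − exp(−k t)`` to a saturation-normalized pulse course."""
    t, y, early = _prepare(times_h, fractions, transcript_id, "synthesis")
    if early is not None:
        return early
    try:
        popt, _ = curve_fit(
            lambda tt, k: 1.0 - np.exp(-k * tt),
            t,
            y,
            p0=(k0,),
            bounds=((1e-9,), (1.0,)),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return KineticFit(
            transcript_id=transcript_id,
            mode="synthesis",
            k_per_min=math.nan,
            half_life_min=math.nan,
            r_squared=math.nan,
            status=FitStatus.INSUFFICIENT_DATA,
            n_points=len(t),
            message=f"optimizer failed: {exc}",
        )
    k = float(popt[0])
    r2 = _r_squared(y, 1.0 - np.exp(-k * t))
    return _finalize(transcript_id, "synthesis", k, 1.0, r2, len(t))


def fit_transcripts(
    normalized: pd.DataFrame, mode: str, pool_replicates: bool = True
) -> pd.DataFrame:
    """Fit every transcript of a normalized course table.

    ``mode`` is ``"decay"`` (catabolic records) or ``"synthesis"``
    (anabolic).  By default all replicate points are pooled into a single
    fit; with ``pool_replicates=False`` each replicate is fitted separately
    and rows gain a ``replicate`` column.
    """
    if mode not in ("decay", "synthesis"):
        raise ValueError("mode must be 'decay' or 'synthesis'")
    design = "catabolic" if mode == "decay" else "anabolic"
    fitter = fit_decay if mode == "decay" else fit_synthesis
    sub = normalized[normalized["design"] == design]
    rows = []
    group_cols = ["transcript_id"] if pool_replicates else ["transcript_id", "replicate"]
    for key, grp in sub.groupby(group_cols, sort=True):
        tid = key[0] if isinstance(key, tuple) else key
        if bool(grp["unnormalizable"].iloc[0]):
            fit = KineticFit(
                transcript_id=tid,
                mode=mode,
                k_per_min=math.nan,
                half_life_min=math.nan,
                r_squared=math.nan,
                status=FitStatus.UNNORMALIZABLE,
                n_points=0,
                message="saturation <= background",
            )
        else:
            fit = fitter(grp["time_h"].to_numpy(), grp["normalized_fraction"].to_numpy(), tid)
        row = {
            "transcript_id": fit.transcript_id,
            "mode": fit.mode,
            "k_per_min": fit.k_per_min,
            "half_life_min": fit.half_life_min,
            "r_squared": fit.r_squared,
            "status": fit.status.value,
            "n_points": fit.n_points,
            "message": fit.message,
        }
        if not pool_replicates:
            row["replicate"] = key[1]
        rows.append(row)
    return pd.DataFrame(rows)


def filter_fits(
    fits: pd.DataFrame,
    r2_threshold: float = R2_THRESHOLD,
    half_life_bounds_min: tuple[float, float] = HALF_LIFE_BOUNDS_MIN,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Re-apply the interpretation filters and summarise status counts.

    Status ``ok`` requires R² above the threshold *and* a half-life inside
    the open interval ``half_life_bounds_min``.  Lowering the R² threshold
    can only move fits from ``low_r2`` toward ``ok``/``outlier``, never the
    reverse.  Upstream ``unnormalizable`` / ``insufficient_data`` statuses
    are preserved.
    """
    out = fits.copy()
    lo, hi = half_life_bounds_min
    fitted = ~out["status"].isin(
        [FitStatus.UNNORMALIZABLE.value, FitStatus.INSUFFICIENT_DATA.value]
    )
    low = fitted & ~(out["r_squared"] > r2_threshold)
    outlier = fitted & ~low & ~((out["half_life_min"] > lo) & (out["half_life_min"] < hi))
    ok = fitted & ~low & ~outlier
    out.loc[low, "status"] = FitStatus.LOW_R2.value
    out.loc[outlier, "status"] = FitStatus.OUTLIER.value
    out.loc[ok, "status"] = FitStatus.OK.value
    counts = out["status"].value_counts().to_dict()
    return out, counts
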