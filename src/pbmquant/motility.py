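"""Single-cell motility statistics from time-lapse trajectories.

For a track of N uniformly sampled positions r_1..r_N (spacing δt), the
per-lag statistics use every overlapping pair of points i apart:

    MSD(i) = 1/(N−i) · Σ_{j=1..N−i} ‖r_{j+i} − r_j‖²      (μm²)
    MAD(i) = 1/(N−i) · Σ_{j=1..N−i} ‖r_{j+i} − r_j‖        (μm)

Ordinary least squares of MSD against lag time over a short-lag window
gives the diffusion coefficient D = slope/4 (2-D Einstein relation);
the same regression on MAD gives the mean velocity V = slope. R² of each
fit diagnoses how diffusive (MSD) or directionally consistent (MAD) the
motion is. Fits use a free intercept, which absorbs static localisation
offsets; a through-origin fit would change D and is deliberately not used.

The model-fitting surface follows the statsmodels idiom:

>>> res = MotilityModel(tracks).fit()
>>> res.per_track        # doctest: +SKIP
>>> print(res.summary()) # doctest: +SKIP
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FitError, InsufficientDataError, ValidationError
from .io import TrajectoryTable, UNIFORM_DT_TOL, logger


@dataclass(frozen=True)
class LagStatistics:
    """Per-lag MSD/MAD curves of one track.

    Arrays are indexed by lag i = 1..N−1; ``n_pairs[i-1] = N − i`` is the
    number of overlapping displacement pairs averaged at that lag.
    """

    track_id: object
    n_points: int
    delta_t: float
    lag: np.ndarray        # lag index i
    lag_time: np.ndarray   # i·δt, minutes
    msd: np.ndarray        # μm²
    mad: np.ndarray        # μm
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": self.track_id,
                "lag": self.lag,
                "lag_time_min": self.lag_time,
                "msd_um2": self.msd,
                "mad_um": self.mad,
                "n_pairs": self.n_pairs,
            }
        )


@dataclass(frozen=True)
class FitPolicy:
    """Which lags enter the MSD/MAD regressions.

    By default the window is lags 1..floor((N−1)·max_lag_frac) — short
    lags only, because long lags average few pairs and are noisy — with a
    floor of ``min_lags`` so a regression is always over ≥3 points.
    """

    max_lag_frac: float = 0.25
    min_lags: int = 3
    min_lag: int = 1
    max_lag: int | None = None

    def window(self, n_lags_available: int) -> tuple[int, int]:
        """(first, last) lag index, inclusive."""
        if self.max_lag is not None:
            last = min(self.max_lag, n_lags_available)
        else:
            last = int(math.floor(n_lags_available * self.max_lag_frac))
        last = max(last, self.min_lag + self.min_lags - 1)
        last = min(last, n_lags_available)
        if last - self.min_lag + 1 < self.min_lags:
            raise FitError(
                f"fit range [{self.min_lag}, {last}] has fewer than "
                f"{self.min_lags} lags"
            )
        return self.min_lag, last


@dataclass(frozen=True)
class MotilityEstimate:
    """Regression-derived motility parameters of one track.

    ``r2_*`` is NaN (with the matching ``r2_*_defined`` False) when the
    response is constant over the fit window — a stationary cell has no
    meaningful R², not a perfect one.
    """

    track_id: object
    D: float               # μm²/min, slope_msd / 4
    V: float               # μm/min,  slope_mad
    slope_msd: float
    intercept_msd: float
    r2_msd: float
    slope_mad: float
    intercept_mad: float
    r2_mad: float
    fit_lag_min: int
    fit_lag_max: int
    n_lags_fit: int

    @property
    def r2_msd_defined(self) -> bool:
        return not math.isnan(self.r2_msd)

    @property
    def r2_mad_defined(self) -> bool:
        return not math.isnan(self.r2_mad)


# ---------------------------------------------------------------------------


def _track_arrays(track: pd.DataFrame) -> tuple[np.ndarray, float]:
    xy = track[["x", "y"]].to_numpy(dtype=float)
    t = track["t"].to_numpy(dtype=float)
    if len(xy) < 2:
        raise InsufficientDataError("track has fewer than 2 points")
    dt = np.diff(t)
    if np.ptp(dt) > UNIFORM_DT_TOL or (dt <= 0).any():
        raise ValidationError("track is not uniformly sampled")
    return xy, float(dt[0])


def lag_statistics(track: pd.DataFrame, track_id: object | None = None) -> LagStatistics:
    """MSD/MAD at every lag 1..N−1 of one uniformly sampled track.

    ``track`` is one track's rows of a :class:`~pbmquant.io.TrajectoryTable`
    (columns t, x, y; sorted by frame).
    """
    xy, delta_t = _track_arrays(track)
    n = len(xy)
    if track_id is None:
        track_id = track["track_id"].iloc[0] if "track_id" in track else ""
    lags = np.arange(1, n)
    msd = np.empty(n - 1)
    mad = np.empty(n - 1)
    for i in lags:
        d = xy[i:] - xy[:-i]
        sq = np.einsum("ij,ij->i", d, d)
        msd[i - 1] = sq.mean()
        mad[i - 1] = np.sqrt(sq).mean()
    return LagStatistics(
        track_id=track_id,
        n_points=n,
        delta_t=delta_t,
        lag=lags,
        lag_time=lags * delta_t,
        msd=msd,
        mad=mad,
        n_pairs=(n - lags),
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Free-intercept least squares; returns (slope, intercept, r2).

    r2 = 1 − SSres/SStot; NaN when the response is constant (SStot = 0).
    """
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = ((y - ym) ** 2).sum()
    if ss_tot == 0.0:
        return slope, intercept, float("nan")
    ss_res = ((y - (slope * x + intercept)) ** 2).sum()
    return slope, intercept, 1.0 - ss_res / ss_tot


def fit_motility(
    stats: LagStatistics, fit_policy: FitPolicy | None = None
) -> MotilityEstimate:
    """OLS of MSD and MAD against lag time; D = slope_msd/4, V = slope_mad."""
    policy = fit_policy or FitPolicy()
    first, last = policy.window(len(stats.lag))
    sel = (stats.lag >= first) & (stats.lag <= last)
    x = stats.lag_time[sel]
    s_msd, i_msd, r2_msd = _ols(x, stats.msd[sel])
    s_mad, i_mad, r2_mad = _ols(x, stats.mad[sel])
    return MotilityEstimate(
        track_id=stats.track_id,
        D=s_msd / 4.0,
        V=s_mad,
        slope_msd=s_msd,
        intercept_msd=i_msd,
        r2_msd=r2_msd,
        slope_mad=s_mad,
        intercept_mad=i_mad,
        r2_mad=r2_mad,
        fit_lag_min=first,
        fit_lag_max=last,
        n_lags_fit=int(sel.sum()),
    )


# ---------------------------------------------------------------------------
# Model / Results


class MotilityModel:
    """Per-track motility regression over one or more conditions.

    Parameters
    ----------
    data
        A single :class:`TrajectoryTable`, or a mapping
        ``{condition: TrajectoryTable}`` for a multi-condition study.
    fit_policy
        Lag window for the regressions (default: short-lag quarter).
    """

    def __init__(
        self,
        data: TrajectoryTable | Mapping[str, TrajectoryTable],
        fit_policy: FitPolicy | None = None,
    ) -> None:
        if isinstance(data, TrajectoryTable):
            data = {"all": data}
        if not data:
            raise ValidationError("no conditions supplied")
        for cond, table in data.items():
            if not isinstance(table, TrajectoryTable):
                raise ValidationError(f"condition {cond!r} is not a TrajectoryTable")
        self.data = dict(data)
        self.fit_policy = fit_policy or FitPolicy()

    def fit(self) -> "MotilityResults":
        rows = []
        curves: list[LagStatistics] = []
        n_skipped = 0
        for cond, table in self.data.items():
            fitted_any = False
            for tid, g in table.iter_tracks():
                stats = lag_statistics(g, track_id=tid)
                curves.append(stats)
                try:
                    est = fit_motility(stats, self.fit_policy)
                except FitError:
                    n_skipped += 1
                    continue
                fitted_any = True
                rows.append(
                    {
                        "condition": cond,
                        "track_id": tid,
                        "n_points": stats.n_points,
                        "D_um2_per_min": est.D,
                        "V_um_per_min": est.V,
                        "r2_msd": est.r2_msd,
                        "r2_mad": est.r2_mad,
                        "slope_msd": est.slope_msd,
                        "intercept_msd": est.intercept_msd,
                        "slope_mad": est.slope_mad,
                        "intercept_mad": est.intercept_mad,
                        "fit_lag_min": est.fit_lag_min,
                        "fit_lag_max": est.fit_lag_max,
                    }
                )
            if not fitted_any:
                raise ValidationError(
                    f"condition {cond!r} has no track long enough to fit"
                )
        if n_skipped:
            logger.warning("%d tracks too short for the fit window; excluded",
                           n_skipped)
        return MotilityResults(
            model=self,
            per_track=pd.DataFrame(rows),
            lag_curves=curves,
            n_tracks_skipped=n_skipped,
        )


@dataclass
class MotilityResults:
    """Fitted per-track motility estimates plus cohort aggregates."""

    model: MotilityModel
    per_track: pd.DataFrame
    lag_curves: list[LagStatistics]
    n_tracks_skipped: int = 0

    _AGG_COLS = ("D_um2_per_min", "V_um_per_min", "r2_msd", "r2_mad")

    @property
    def by_condition(self) -> pd.DataFrame:
        """Group mean, SEM (NaN for n = 1) and n per condition."""
        out = []
        for cond, g in self.per_track.groupby("condition", sort=False):
            row: dict = {"condition": cond, "n_tracks": len(g)}
            for c in self._AGG_COLS:
                vals = g[c].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                row[f"{c}_mean"] = vals.mean() if len(vals) else float("nan")
                row[f"{c}_sem"] = (
                    vals.std(ddof=1) / math.sqrt(len(vals))
                    if len(vals) > 1
                    else float("nan")
                )
            out.append(row)
        return pd.DataFrame(out)

    def summary(self) -> str:
        """Human-readable cohort table (means ± SEM)."""
        lines = ["Motility regression summary", "=" * 64]
        lines.append(
            f"{'condition':<12}{'n':>5}{'D [um^2/min]':>18}{'V [um/min]':>16}"
            f"{'R2(MSD)':>8}{'R2(MAD)':>8}"
        )
        for _, r in self.by_condition.iterrows():
            d = f"{r['D_um2_per_min_mean']:.4g} ± {r['D_um2_per_min_sem']:.2g}"
            v = f"{r['V_um_per_min_mean']:.4g} ± {r['V_um_per_min_sem']:.2g}"
            lines.append(
                f"{str(r['condition']):<12}{int(r['n_tracks']):>5}{d:>18}{v:>16}"
                f"{r['r2_msd_mean']:>8.3f}{r['r2_mad_mean']:>8.3f}"
            )
        if self.n_tracks_skipped:
            lines.append(f"({self.n_tracks_skipped} tracks too short; excluded)")
        return "\n".join(lines)

    def lag_table(self) -> pd.DataFrame:
        """All per-track MSD/MAD curves as one tidy frame."""
        return pd.concat([c.to_frame() for c in self.lag_curves], ignore_index=True)


def cohort_summary(
    tables: Mapping[str, TrajectoryTable] | TrajectoryTable,
    fit_policy: FitPolicy | None = None,
) -> MotilityResults:
    """Convenience wrapper: ``MotilityModel(tables, fit_policy).fit()``."""
    return MotilityModel(tables, fit_policy).fit()


# ---------------------------------------------------------------------------
# rose-plot data


def trajectory_rose_plot_data(table: TrajectoryTable) -> pd.DataFrame:
    """Origin-normalised tracks with per-step speed, for rose/spider plots.

    Each track is translated so its first point is (0, 0); every row keeps
    the speed of the step *ending* at that point (NaN for the first point).
    """
    out = []
    for tid, g in table.iter_tracks():
        xy = g[["x", "y"]].to_numpy(dtype=float)
        t = g["t"].to_numpy(dtype=float)
        rel = xy - xy[0]
        step_len = np.hypot(*np.diff(rel, axis=0).T)
        speed = np.concatenate(([np.nan], step_len / np.diff(t)))
        out.append(
            pd.DataFrame(
                {
                    "track_id": tid,
                    "frame": g["frame"].to_numpy(),
                    "t": t,
                    "x": rel[:, 0],
                    "y": rel[:, 1],
                    "step_speed_um_per_min": speed,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def plot_rose(table: TrajectoryTable, ax=None, cmap: str = "viridis"):
    """Draw origin-normalised tracks coloured by instantaneous speed."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    data = trajectory_rose_plot_data(table)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    speeds = data["step_speed_um_per_min"].dropna()
    vmax = speeds.max() if len(speeds) else 1.0
    for _, g in data.groupby("track_id", sort=False):
        pts = g[["x", "y"]].to_numpy()
        segs = np.stack([pts[:-1], pts[1:]], axis=1)
        lc = LineCollection(segs, cmap=cmap, array=g["step_speed_um_per_min"].to_numpy()[1:],
                            clim=(0, vmax), linewidths=1)
        ax.add_collection(lc)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    return ax
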