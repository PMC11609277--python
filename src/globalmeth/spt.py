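"""Single-particle tracking: LoG detection, LAP linking, MSD fitting.

Spots are detected per frame as local maxima of the scale-normalized
Laplacian-of-Gaussian response with sub-pixel quadratic refinement.
Frame-to-frame correspondence is a linear assignment problem (LAP) with a
birth/termination cost: a detection links to at most one detection in the
next frame or terminates; there is no gap closing and no merging/splitting.
Each track's time-averaged MSD is fitted with

    MSD(t) = 4 D t**alpha + 2 sigma**2

where D is the diffusion coefficient (µm²/s), alpha the anomalous scaling
exponent (1 = Brownian) and sigma the static localization error (µm).
Mobility summaries keep tracks with at least ``min_track_frames`` consecutive
frames and fit R² at or above ``r2_min``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import OptimizeWarning, curve_fit, linear_sum_assignment
from skimage.feature import peak_local_max

from .exceptions import ConfigurationError

_BIG = 1e12  # forbidden-assignment cost


@dataclass
class Trajectory:
    """One linked track: strictly consecutive frames with (x, y) in pixels."""

    track_id: int
    frames: np.ndarray
    xy: np.ndarray  # (n, 2) px

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.frames) != len(self.xy):
            raise ConfigurationError("frames and coordinates length mismatch")
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) == 1):
            raise ConfigurationError("track frames must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrajectorySet:
    """A bag of tracks plus acquisition metadata (and, if synthetic, truth)."""

    tracks: list[Trajectory]
    frame_interval: float | None = None  # s
    pixel_size: float | None = None  # µm/px
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame(
                {"track_id": t.track_id, "frame": t.frames, "x": t.xy[:, 0], "y": t.xy[:, 1]}
            )
            for t in self.tracks
        ]
        if not rows:
            return pd.DataFrame(columns=["track_id", "frame", "x", "y"])
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TrajectorySet":
        tracks = []
        for tid, sub in df.groupby("track_id", sort=True):
            sub = sub.sort_values("frame")
            tracks.append(
                Trajectory(int(tid), sub["frame"].to_numpy(), sub[["x", "y"]].to_numpy())
            )
        return cls(tracks=tracks, **kwargs)


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track: lag times (s) and MSD (µm²)."""

    lag_times: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray


@dataclass
class MSDFit:
    """Fitted MSD model parameters and goodness of fit."""

    D: float  # µm²/s
    alpha: float
    sigma: float  # µm
    r_squared: float
    converged: bool = True


@dataclass
class MobilitySummary:
    """Per-track fitted parameters after length and fit-quality filtering."""

    D: np.ndarray
    alpha: np.ndarray
    r_squared: np.ndarray
    track_lengths: np.ndarray
    n_tracks_total: int
    n_retained: int
    min_track_frames: int
    r2_min: float

    @property
    def median_D(self) -> float:
        return float(np.median(self.D))

    @property
    def median_alpha(self) -> float:
        return float(np.median(self.alpha))


# ---------------------------------------------------------------------------
# detection


def detect_spots(frame: np.ndarray, scale: float, threshold: float) -> pd.DataFrame:
    """LoG blob detection on one grayscale frame.

    The scale-normalized response ``-scale**2 * LoG(frame)`` is peak-picked
    above ``threshold`` with a minimum separation of ``2*scale`` pixels
    (highest response wins); peaks are refined to sub-pixel by a 3-point
    quadratic fit along each axis.  Returns columns x, y, intensity, response.
    """
    if scale <= 0:
        raise ConfigurationError("scale must be positive")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ConfigurationError("detect_spots expects a 2-D grayscale frame")
    response = -(scale ** 2) * ndi.gaussian_laplace(frame, sigma=scale)
    min_dist = max(1, int(round(2 * scale)))
    peaks = peak_local_max(
        response, min_distance=min_dist, threshold_abs=threshold, exclude_border=1
    )
    rows = []
    for r, c in peaks:
        dy = _quadratic_offset(response[r - 1, c], response[r, c], response[r + 1, c])
        dx = _quadratic_offset(response[r, c - 1], response[r, c], response[r, c + 1])
        rows.append((c + dx, r + dy, frame[r, c], response[r, c]))
    return pd.DataFrame(rows, columns=["x", "y", "intensity", "response"])


def _quadratic_offset(left: float, centre: float, right: float) -> float:
    denom = left - 2 * centre + right
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))


def detect_stack(stack: np.ndarray, scale: float, threshold: float) -> list[pd.DataFrame]:
    """Run :func:`detect_spots` on every frame of a (t, y, x) stack."""
    return [detect_spots(fr, scale, threshold) for fr in stack]


# ---------------------------------------------------------------------------
# linking


def _lap_frame_links(a: np.ndarray, b: np.ndarray, max_disp: float) -> list[tuple[int, int]]:
    """Optimal links between two frames' detections under the LAP model.

    Builds the augmented square matrix [[C, T], [B, 0]] with link cost C =
    squared displacement (forbidden beyond max_disp), diagonal termination
    and birth costs max_disp**2, and a zero lower-right filler; solves it
    with the Jonker–Volgenant algorithm.
    """
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        return []
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    cost_alt = max_disp ** 2
    link = np.where(d2 <= cost_alt, d2, _BIG)
    top_right = np.full((n1, n1), _BIG)
    np.fill_diagonal(top_right, cost_alt)
    bottom_left = np.full((n2, n2), _BIG)
    np.fill_diagonal(bottom_left, cost_alt)
    bottom_right = np.zeros((n2, n1))
    cost = np.block([[link, top_right], [bottom_left, bottom_right]])
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n1 and j < n2 and link[i, j] < _BIG
    ]


def link_trajectories(detections: list[pd.DataFrame], max_disp: float) -> TrajectorySet:
    """Link per-frame detections into trajectories; no gap closing.

    A detection may link to at most one detection in the subsequent frame or
    terminate; an unlinked detection starts a new track.  Tracks shorter than
    two frames are discarded.
    """
    if max_disp <= 0:
        raise ConfigurationError("max_disp must be positive")
    coords = [
        d[["x", "y"]].to_numpy(dtype=float) if len(d) else np.empty((0, 2))
        for d in detections
    ]
    frames_of: list[list[int]] = []
    points_of: list[list[np.ndarray]] = []

    def new_track(frame: int, p: np.ndarray) -> int:
        frames_of.append([frame])
        points_of.append([p])
        return len(frames_of) - 1

    active = [new_track(0, p) for p in (coords[0] if coords else [])]
    for f in range(len(coords) - 1):
        nxt = coords[f + 1]
        links = _lap_frame_links(coords[f], nxt, max_disp)
        linked_from = {j: i for i, j in links}
        new_active: list[int] = []
        for j, p in enumerate(nxt):
            if j in linked_from:
                tid = active[linked_from[j]]
                frames_of[tid].append(f + 1)
                points_of[tid].append(p)
            else:
                tid = new_track(f + 1, p)
            new_active.append(tid)
        active = new_active
    tracks = [
        Trajectory(track_id=k, frames=np.array(fr), xy=np.array(pts))
        for k, (fr, pts) in enumerate(zip(frames_of, points_of))
        if len(fr) >= 2
    ]
    return TrajectorySet(tracks=tracks)


# ---------------------------------------------------------------------------
# MSD analysis


def compute_msd(
    track: Trajectory,
    frame_interval: float,
    pixel_size: float,
    max_lag_fraction: float = 0.25,
) -> MSDCurve:
    """Time-averaged MSD of one track, in µm² vs seconds.

    Lags run from 1 up to ``max_lag_fraction`` of the track length (at least
    one lag); the classic cap controls the variance of the long-lag points.
    """
    if frame_interval <= 0 or pixel_size <= 0:
        raise ConfigurationError("frame_interval and pixel_size must be positive")
    n = len(track)
    if n < 2:
        raise ConfigurationError("MSD needs a track of length >= 2")
    max_lag = max(1, int(np.floor(n * max_lag_fraction)))
    xy = track.xy * pixel_size
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    n_pairs = np.empty(max_lag, dtype=np.int64)
    for k in lags:
        disp = xy[k:] - xy[:-k]
        msd[k - 1] = np.mean((disp ** 2).sum(axis=1))
        n_pairs[k - 1] = len(disp)
    return MSDCurve(lag_times=lags * frame_interval, msd=msd, n_pairs=n_pairs)


def _msd_model(t: np.ndarray, d: float, alpha: float, sigma: float) -> np.ndarray:
    return 4.0 * d * np.power(t, alpha) + 2.0 * sigma ** 2


def fit_msd(curve: MSDCurve, weight_by_pairs: bool = False) -> MSDFit:
    """Nonlinear least squares of ``MSD = 4 D t**alpha + 2 sigma**2``.

    Bounds: D >= 0, alpha in (0, 2], sigma >= 0.  Initial values come from a
    log-log regression over the first lags.  ``weight_by_pairs`` weights each
    lag by the square root of its displacement-pair count.
    """
    t, y = curve.lag_times, curve.msd
    if len(t) < 3:
        raise ConfigurationError("MSD fit needs >= 3 lag points for 3 parameters")
    # zero-lag extrapolation attributes the static offset to 2·sigma² up front;
    # without it a flat curve is degenerate (alpha→0 folds the constant into D)
    sigma0_sq = max(float(y[0] - (y[1] - y[0])), 0.0) / 2.0
    y_corr = y - 2.0 * sigma0_sq
    pos = y_corr > 0
    if pos.sum() >= 2:
        k = min(5, int(pos.sum()))
        lt, ly = np.log(t[pos][:k]), np.log(y_corr[pos][:k])
        slope, intercept = np.polyfit(lt, ly, 1)
        alpha0 = float(np.clip(slope, 0.1, 1.9))
        d0 = max(np.exp(intercept) / 4.0, 1e-9)
    else:
        alpha0, d0 = 1.0, 1e-9
    p0 = (d0, alpha0, np.sqrt(sigma0_sq))
    sigma_w = 1.0 / np.sqrt(curve.n_pairs) if weight_by_pairs else None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
            _msd_model,
            t,
            y,
            p0=p0,
            sigma=sigma_w,
            bounds=([0.0, 1e-6, 0.0], [np.inf, 2.0, np.inf]),
            maxfev=10_000,
        )
        converged = True
    except RuntimeError:
        popt, converged = np.array(p0), False
    resid = y - _msd_model(t, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return MSDFit(
        D=float(popt[0]),
        alpha=float(popt[1]),
        sigma=float(popt[2]),
        r_squared=r2,
        converged=converged,
    )


def summarize_mobility(
    tracks: TrajectorySet,
    frame_interval: float,
    pixel_size: float,
    min_track_frames: int = 5,
    r2_min: float = 0.8,
    max_lag_fraction: float = 0.25,
) -> MobilitySummary:
    """Per-track MSD fits filtered by length and fit quality.

    Diffusion coefficients come from tracks with at least ``min_track_frames``
    consecutive frames and fits with R² >= ``r2_min`` (the quality floor;
    set ``r2_min=0`` to disable).
    """
    ds, alphas, r2s, lengths = [], [], [], []
    for tr in tracks.tracks:
        if len(tr) < min_track_frames:
            continue
        curve = compute_msd(tr, frame_interval, pixel_size, max_lag_fraction)
        if len(curve.lag_times) < 3:
            continue
        fit = fit_msd(curve)
        if not fit.converged or fit.r_squared < r2_min:
            continue
        ds.append(fit.D)
        alphas.append(fit.alpha)
        r2s.append(fit.r_squared)
        lengths.append(len(tr))
    if not ds:
        raise ConfigurationError("no tracks retained after length and R² filtering")
    return MobilitySummary(
        D=np.array(ds),
        alpha=np.array(alphas),
        r_squared=np.array(r2s),
        track_lengths=np.array(lengths),
        n_tracks_total=len(tracks),
        n_retained=len(ds),
        min_track_frames=min_track_frames,
        r2_min=r2_min,
    )


def compare_mobility(
    a: MobilitySummary,
    b: MobilitySummary,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> dict:
    """Difference of median D (a − b) with a bootstrap percentile interval."""
    rng = np.random.default_rng(seed)
    diff = a.median_D - b.median_D
    boots = np.empty(n_boot)
    for i in range(n_boot):
        da = rng.choice(a.D, size=len(a.D), replace=True)
        db = rng.choice(b.D, size=len(b.D), replace=True)
        boots[i] = np.median(da) - np.median(db)
    lo, hi = np.quantile(boots, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return {
        "median_D_a": a.median_D,
        "median_D_b": b.median_D,
        "diff_median_D": float(diff),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": n_boot,
    }


# ---------------------------------------------------------------------------
# I/O


def write_tracks_csv(tracks: TrajectorySet, path) -> None:
    tracks.to_dataframe().to_csv(path, index=False)


def read_tracks_csv(path, **kwargs) -> TrajectorySet:
    return TrajectorySet.from_dataframe(pd.read_csv(path), **kwargs)
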