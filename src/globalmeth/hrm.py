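"""High-resolution-melt (HRM) methylation quantification.

After bisulfite conversion, methylated template retains its CpGs and the PCR
amplicon melts at a higher temperature than the converted, unmethylated one.
A sample's normalized melt curve is therefore (approximately) a convex
combination of the fully methylated and fully unmethylated standard curves,
and its percent methylation is recovered by least squares against those two
end members.  The 25% and 50% standards are not used in the fit and serve as
held-out accuracy checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

REQUIRED_FRACTIONS = (0.0, 0.25, 0.5, 1.0)


@dataclass
class MeltCurve:
    """One amplicon melt curve: fluorescence vs temperature (°C, ascending)."""

    sample: str
    temperature: np.ndarray
    fluorescence: np.ndarray
    target: str = "LINE-1"

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ConfigurationError("temperature and fluorescence lengths differ")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ConfigurationError("non-finite fluorescence values")
        if not np.all(np.diff(self.temperature) > 0):
            raise ConfigurationError("temperature grid must be strictly increasing")


@dataclass
class StandardSet:
    """Melt curves of the methylation standards, keyed by true fraction."""

    curves: dict[float, MeltCurve]
    required: tuple[float, ...] = REQUIRED_FRACTIONS

    def __post_init__(self) -> None:
        missing = [f for f in self.required if f not in self.curves]
        if missing:
            raise ConfigurationError(f"missing standards: {missing}")
        grids = [c.temperature for c in self.curves.values()]
        if any(g.shape != grids[0].shape or not np.allclose(g, grids[0]) for g in grids):
            raise ConfigurationError("standards must share one temperature grid")

    def __getitem__(self, fraction: float) -> MeltCurve:
        return self.curves[fraction]


@dataclass
class MethylationEstimate:
    """Estimated methylated fraction with fit residual and windows used."""

    sample: str
    fraction: float
    residual_norm: float
    pre_window: tuple[float, float] = field(default=(np.nan, np.nan))
    post_window: tuple[float, float] = field(default=(np.nan, np.nan))


def _fit_baseline(curve: MeltCurve, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    mask = (curve.temperature >= lo) & (curve.temperature <= hi)
    if mask.sum() < 2:
        raise ConfigurationError(f"degenerate baseline window {window}: < 2 grid points")
    coeff = np.polyfit(curve.temperature[mask], curve.fluorescence[mask], 1)
    return np.polyval(coeff, curve.temperature)


def normalize_melt(
    curve: MeltCurve,
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
) -> MeltCurve:
    """Two-baseline melt normalization onto the [0, 1] fluorescence scale.

    Straight lines are fitted to the pre-melt and post-melt windows and the
    curve is rescaled as (F − post)/(pre − post), so it runs from ~1 before
    the transition to ~0 after it.  The transform is invariant to affine
    changes of the raw signal.

    Default windows span the first and last ``max(2 °C, 15% of the grid)``:
    a fitted baseline is extrapolated across the whole grid, so its slope
    error grows linearly with distance from the window — windows much
    narrower than the extrapolation distance let fluorescence noise distort
    the normalized curve shape.
    """
    t = curve.temperature
    width = max(2.0, 0.15 * (t[-1] - t[0]))
    if pre_window is None:
        pre_window = (t[0], t[0] + width)
    if post_window is None:
        post_window = (t[-1] - width, t[-1])
    if pre_window[1] > post_window[0]:
        raise ConfigurationError("pre-melt window must end before the post-melt window")
    pre = _fit_baseline(curve, pre_window)
    post = _fit_baseline(curve, post_window)
    denom = pre - post
    if np.any(np.abs(denom) < 1e-12):
        raise ConfigurationError("pre- and post-melt baselines coincide")
    return MeltCurve(
        sample=curve.sample,
        temperature=t.copy(),
        fluorescence=(curve.fluorescence - post) / denom,
        target=curve.target,
    )


def estimate_methylation(
    sample: MeltCurve,
    standards: StandardSet,
) -> MethylationEstimate:
    """Least-squares methylated fraction of a normalized curve.

    Solves ``f = argmin_f || sample − (f·S100 + (1−f)·S0) ||²`` in closed form
    and clips to [0, 1].  All curves must be normalized on a shared grid.
    """
    s0 = standards[0.0]
    s100 = standards[1.0]
    if sample.temperature.shape != s0.temperature.shape or not np.allclose(
        sample.temperature, s0.temperature
    ):
        raise ConfigurationError("sample and standards are on different temperature grids")
    basis = s100.fluorescence - s0.fluorescence
    denom = float(basis @ basis)
    if denom < 1e-12:
        raise ConfigurationError(
            "0% and 100% standards are identical: no melt separation, fraction unidentifiable"
        )
    y = sample.fluorescence - s0.fluorescence
    f = float(np.clip((y @ basis) / denom, 0.0, 1.0))
    resid = y - f * basis
    return MethylationEstimate(
        sample=sample.sample,
        fraction=f,
        residual_norm=float(np.linalg.norm(resid)),
    )


def derivative_curve(curve: MeltCurve) -> pd.DataFrame:
    """−dF/dT melt-peak representation (for plotting; not used in fitting)."""
    d = -np.gradient(curve.fluorescence, curve.temperature)
    return pd.DataFrame({"temperature": curve.temperature, "neg_dFdT": d})


def write_melt_csv(curves: list[MeltCurve], path) -> None:
    """Long-format CSV: sample, temperature, fluorescence."""
    frames = [
        pd.DataFrame(
            {"sample": c.sample, "temperature": c.temperature, "fluorescence": c.fluorescence}
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_melt_csv(path) -> list[MeltCurve]:
    df = pd.read_csv(path)
    curves = []
    for sample, sub in df.groupby("sample", sort=False):
        sub = sub.sort_values("temperature")
        curves.append(
            MeltCurve(
                sample=str(sample),
                temperature=sub["temperature"].to_numpy(),
                fluorescence=sub["fluorescence"].to_numpy(),
            )
        )
    return curves
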