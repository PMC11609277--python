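"""Synthetic-data generators for every pipeline input.

Each generator emulates the statistical structure of one experiment so the
downstream analyses are testable without any external data:

* :func:`make_methylome` — a three-arm (mock / inactive / active effector)
  CpG-array beta matrix with a tunable global hypermethylation shift in the
  active arm, per-probe chromatin-state annotations, and detection p-values.
* :func:`make_screen_counts` — null (or spiked) negative-binomial pooled-
  screen counts with region-targeting, non-targeting and AAVS1 guide classes.
* :func:`make_trajectories` — 2-D Brownian or subdiffusive particle tracks
  (fractional Gaussian noise) with localization error.
* :func:`render_frames` — a grayscale movie of Gaussian spots with Poisson
  noise, closing the loop with the tracking pipeline.
* :func:`make_melt_curves` — two-state sigmoid HRM curves mixing methylated
  and unmethylated species, including the 0/25/50/100% standards.

All generators are bit-reproducible under their config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, toeplitz

from .config import MeltConfig, MethylomeConfig, ScreenConfig, TrackingConfig
from .enrichment import Segmentation
from .exceptions import ConfigurationError
from .hrm import MeltCurve, StandardSet
from .methylome import BetaMatrix
from .screen import ScreenTable
from .spt import Trajectory, TrajectorySet

_CHROM_LENGTH = 50_000_000  # nominal synthetic chromosome length, bp


# ---------------------------------------------------------------------------
# methylome


def make_methylome(
    config: MethylomeConfig,
) -> tuple[BetaMatrix, pd.Series, pd.DataFrame]:
    """Generate a beta matrix, probe→state annotation map, and detection p-values.

    Per-CpG baseline mean betas are drawn from the (bimodal) baseline Beta
    distribution; per-sample betas are Beta-distributed around the arm-level
    mean at fixed precision.  In the active arm, each CpG is hypermethylated
    (mean raised by ``global_shift``, clipped below 1) with its state's shift
    probability.  Detection p-values exceed 0.01 with the configured fail
    rate.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cpg
    probe_ids = pd.Index([f"cg{i:08d}" for i in range(n)], name="probe")

    # concatenated uniform placement: strictly increasing positions per chromosome
    chrom_idx = np.sort(rng.integers(0, config.n_chrom, size=n))
    chroms = np.array([f"chr{c + 1}" for c in chrom_idx])
    pos = np.empty(n, dtype=np.int64)
    for c in range(config.n_chrom):
        mask = chrom_idx == c
        steps = rng.integers(1, 2 * _CHROM_LENGTH // max(n, 1) + 2, size=mask.sum())
        pos[mask] = 100 + np.cumsum(steps)
    manifest = pd.DataFrame({"chrom": chroms, "pos": pos}, index=probe_ids)

    states = np.array(config.states)
    state_codes = rng.choice(len(states), size=n, p=np.asarray(config.state_weights))
    annot = pd.Series(states[state_codes], index=probe_ids, name="state")

    a0, b0 = config.baseline_beta_params
    mu = np.clip(rng.beta(a0, b0, size=n), 1e-3, 1 - 1e-3)

    p_shift = config.shift_prob_per_state()[state_codes]
    shifted = (rng.random(n) < p_shift) & (config.global_shift > 0)
    mu_active = np.clip(mu + np.where(shifted, config.global_shift, 0.0), 1e-3, 1 - 1e-3)

    kappa = config.precision
    cols, names, meta = [], [], []
    for arm in config.arms:
        arm_mu = mu_active if arm == "active" else mu
        for rep in range(1, config.n_replicates + 1):
            cols.append(np.clip(rng.beta(arm_mu * kappa, (1 - arm_mu) * kappa), 0.0, 1.0))
            names.append(f"{arm}_rep{rep}")
            meta.append((arm, "sgAAVS1" if arm != "mock" else "none", rep))
    betas = pd.DataFrame(
        np.column_stack(cols), index=probe_ids, columns=pd.Index(names, name="sample")
    )
    samples = pd.DataFrame(meta, index=betas.columns, columns=["arm", "sgrna", "replicate"])

    shape = betas.shape
    fail = rng.random(shape) < config.detection_fail_rate
    detp = np.where(
        fail,
        rng.uniform(0.01, 1.0, size=shape),
        rng.uniform(0.0, 0.01, size=shape),
    )
    detp_table = pd.DataFrame(detp, index=probe_ids, columns=betas.columns)

    bm = BetaMatrix(betas=betas, manifest=manifest, samples=samples)
    return bm, annot, detp_table


def segmentation_from_annotation(manifest: pd.DataFrame, annot: pd.Series) -> Segmentation:
    """Build a BED-compatible genome partition consistent with a probe→state map.

    Consecutive probes on a chromosome sharing a state are merged into one
    interval; boundaries fall midway between neighbouring probes of different
    states, so intersecting the returned segmentation with the manifest
    reproduces ``annot`` exactly.
    """
    rows = []
    for chrom, sub in manifest.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        positions = sub["pos"].to_numpy(dtype=np.int64)
        st = annot.loc[sub.index].to_numpy()
        block_start = 0
        for i in range(1, len(positions) + 1):
            if i == len(positions) or st[i] != st[block_start]:
                left = 0 if block_start == 0 else (
                    (positions[block_start - 1] + positions[block_start]) // 2
                )
                right = positions[-1] + 100 if i == len(positions) else (
                    (positions[i - 1] + positions[i]) // 2
                )
                rows.append((chrom, int(left), int(right), st[block_start]))
                block_start = i
    return Segmentation(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))


# ---------------------------------------------------------------------------
# pooled screen


def make_screen_counts(config: ScreenConfig) -> ScreenTable:
    """Negative-binomial guide counts for a two-arm pooled screen.

    Each guide's expected depth is ``mean_depth * 2**baseline`` with a
    per-guide log2 baseline (SD ``guide_log2_sd``) shared across arms and
    replicates — the library-representation spread.  Guides of
    ``effect_regions`` have their active-arm mean multiplied by
    ``2**effect``.  Counts are NB with dispersion ``nb_dispersion``
    (variance = m + m²/r).
    """
    rng = np.random.default_rng(config.seed)
    guide_ids, classes, regions = [], [], []
    for r in range(config.n_regions):
        region = f"region_{r + 1:04d}"
        for g in range(config.guides_per_region):
            guide_ids.append(f"{region}_sg{g + 1}")
            classes.append("region-targeting")
            regions.append(region)
    for g in range(config.n_nontargeting):
        guide_ids.append(f"nontargeting_sg{g + 1}")
        classes.append("non-targeting")
        regions.append("")
    for g in range(config.n_aavs1):
        guide_ids.append(f"AAVS1_sg{g + 1}")
        classes.append("AAVS1")
        regions.append("")
    guides = pd.DataFrame(
        {"class": classes, "region": regions}, index=pd.Index(guide_ids, name="guide")
    )
    n_guides = len(guides)

    baseline = rng.normal(0.0, config.guide_log2_sd, size=n_guides)
    effect = np.zeros(n_guides)
    for region, log2_effect in config.effect_regions.items():
        mask = (guides["region"] == region).to_numpy()
        if not mask.any():
            raise ConfigurationError(f"effect region {region!r} not in the library")
        effect[mask] = log2_effect

    r_disp = config.nb_dispersion
    cols, names, meta = [], [], []
    for arm in ("active", "inactive"):
        arm_mean = config.mean_depth * 2.0 ** (baseline + (effect if arm == "active" else 0.0))
        for rep in range(1, config.n_replicates + 1):
            p = r_disp / (r_disp + arm_mean)
            cols.append(rng.negative_binomial(r_disp, p))
            names.append(f"{arm}_rep{rep}")
            meta.append((arm, rep))
    counts = pd.DataFrame(
        np.column_stack(cols), index=guides.index, columns=pd.Index(names, name="sample")
    )
    samples = pd.DataFrame(meta, index=counts.columns, columns=["arm", "replicate"])
    return ScreenTable(counts=counts, guides=guides, samples=samples)


# ---------------------------------------------------------------------------
# particle trajectories and movies


def _fgn_increments(
    rng: np.random.Generator,
    n_steps: int,
    n_series: int,
    alpha: float,
    step_var: float,
) -> np.ndarray:
    """Fractional-Gaussian-noise increments with Var(x(k)) = step_var * k**alpha.

    Uses the exact autocovariance of fGn with Hurst index H = alpha/2 and a
    Cholesky factor of its Toeplitz covariance; for alpha = 1 this reduces to
    i.i.d. Gaussian steps.
    """
    if n_steps == 0:
        return np.empty((n_series, 0))
    z = rng.standard_normal((n_series, n_steps))
    if abs(alpha - 1.0) < 1e-12:
        return z * np.sqrt(step_var)
    k = np.arange(n_steps, dtype=float)
    h2 = alpha  # 2H
    gamma = 0.5 * step_var * (np.abs(k + 1) ** h2 - 2 * np.abs(k) ** h2 + np.abs(k - 1) ** h2)
    lower = cholesky(toeplitz(gamma), lower=True)
    return z @ lower.T


def make_trajectories(config: TrackingConfig) -> TrajectorySet:
    """Simulate 2-D (sub)diffusive tracks in pixel units with localization noise.

    Per axis the increment process is fractional Gaussian noise scaled so the
    2-D ensemble MSD is ``4 D t**alpha`` (µm²); isotropic Gaussian noise of
    SD ``localization_sigma`` is then added to every observed position.
    True parameters are stored in ``meta``.
    """
    rng = np.random.default_rng(config.seed)
    n_p, n_f = config.n_particles, config.n_frames
    # per-axis increment variance over one frame: MSD_x(dt) = 2 D dt**alpha
    step_var = 2.0 * config.diffusion_coefficient * config.frame_interval ** config.alpha
    field_um = config.field_size * config.pixel_size
    margin = 0.15 * field_um
    start = rng.uniform(margin, field_um - margin, size=(n_p, 2))
    inc_x = _fgn_increments(rng, n_f - 1, n_p, config.alpha, step_var)
    inc_y = _fgn_increments(rng, n_f - 1, n_p, config.alpha, step_var)
    x = np.concatenate([start[:, :1], start[:, :1] + np.cumsum(inc_x, axis=1)], axis=1)
    y = np.concatenate([start[:, 1:], start[:, 1:] + np.cumsum(inc_y, axis=1)], axis=1)
    if config.localization_sigma > 0:
        x = x + rng.normal(0.0, config.localization_sigma, size=x.shape)
        y = y + rng.normal(0.0, config.localization_sigma, size=y.shape)
    tracks = [
        Trajectory(
            track_id=i,
            frames=np.arange(n_f),
            xy=np.column_stack([x[i], y[i]]) / config.pixel_size,  # px
        )
        for i in range(n_p)
    ]
    return TrajectorySet(
        tracks=tracks,
        frame_interval=config.frame_interval,
        pixel_size=config.pixel_size,
        meta={
            "true_D": config.diffusion_coefficient,
            "true_alpha": config.alpha,
            "true_sigma": config.localization_sigma,
        },
    )


def render_frames(
    tracks: TrajectorySet,
    config: TrackingConfig,
    seed: int | None = None,
) -> np.ndarray:
    """Render tracks into a (t, y, x) grayscale movie with Poisson noise.

    Each particle becomes a Gaussian spot of width ``psf_sigma`` px and peak
    amplitude ``photons`` on a uniform ``background``; the whole frame is
    Poisson sampled.  Particles outside the field are clipped with a warning.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    size = config.field_size
    n_frames = max((int(t.frames.max()) + 1 for t in tracks.tracks), default=config.n_frames)
    expected = np.full((n_frames, size, size), float(config.background))
    yy, xx = np.mgrid[0:size, 0:size]
    clipped = 0
    for tr in tracks.tracks:
        for frame, (px, py) in zip(tr.frames, tr.xy):
            if not (0 <= px < size and 0 <= py < size):
                clipped += 1
                continue
            expected[frame] += config.photons * np.exp(
                -((xx - px) ** 2 + (yy - py) ** 2) / (2 * config.psf_sigma ** 2)
            )
    if clipped:
        warnings.warn(f"{clipped} particle positions fell outside the field and were clipped")
    return rng.poisson(expected).astype(np.float64)


# ---------------------------------------------------------------------------
# melt curves


@dataclass
class MeltCurveSet:
    """Standards plus simulated unknowns with their true methylated fractions."""

    standards: StandardSet
    samples: list[MeltCurve]
    true_fractions: list[float]


def _two_state_curve(temp: np.ndarray, f: float, cfg: MeltConfig) -> np.ndarray:
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))  # noqa: E731
    return f * sig((cfg.tm_methylated - temp) / cfg.slope) + (1 - f) * sig(
        (cfg.tm_unmethylated - temp) / cfg.slope
    )


def make_melt_curves(config: MeltConfig) -> MeltCurveSet:
    """Two-state sigmoid melt curves for the standards and unknown mixtures.

    Each curve is ``f·sig((Tm_meth − T)/slope) + (1−f)·sig((Tm_unmeth −
    T)/slope)`` plus Gaussian noise; the four calibration standards
    f ∈ {0, 0.25, 0.5, 1} are always included (noise-free standards when
    ``noise_sd`` applies only to unknowns is *not* assumed — standards get
    the same noise).
    """
    rng = np.random.default_rng(config.seed)
    temp = config.temp_grid

    def curve(name: str, f: float) -> MeltCurve:
        y = _two_state_curve(temp, f, config)
        if config.noise_sd > 0:
            y = y + rng.normal(0.0, config.noise_sd, size=temp.shape)
        return MeltCurve(sample=name, temperature=temp.copy(), fluorescence=y)

    standards = StandardSet(
        {f: curve(f"std_{int(round(f * 100))}pct", f) for f in (0.0, 0.25, 0.5, 1.0)}
    )
    samples, truths = [], []
    for i, f in enumerate(config.mixture_fractions):
        samples.append(curve(f"mix_{i + 1}_{int(round(f * 100))}pct", float(f)))
        truths.append(float(f))
    return MeltCurveSet(standards=standards, samples=samples, true_fractions=truths)
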