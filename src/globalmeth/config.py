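"""Configuration dataclasses for the synthetic-data generators.

Each config is a plain dataclass validated on construction.  Defaults encode
the study design the generators emulate: a three-arm (mock / catalytically
inactive / active DNMT3A) methylome experiment read out on a CpG array, a
pooled CRISPR screen with 10 guides per target region plus non-targeting and
AAVS1 safe-harbor controls, live-cell single-particle imaging at a 30 ms
frame interval, and high-resolution-melt (HRM) curves mixing fully methylated
and unmethylated amplicon species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

#: Labels mirroring a 10-state chromHMM segmentation; the names are cosmetic.
DEFAULT_STATES: tuple[str, ...] = (
    "TssA",
    "TssFlnk",
    "Tx",
    "TxWk",
    "EnhG",
    "Enh",
    "ZNF_Rpts",
    "Het",
    "ReprPC",
    "Quies",
)

ARMS: tuple[str, ...] = ("mock", "inactive", "active")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class MethylomeConfig:
    """Two-arm (plus mock) beta-value matrix generator settings.

    Baseline per-CpG methylation means are drawn from a bimodal Beta
    distribution (``baseline_beta_params``); per-sample betas are then drawn
    from a Beta distribution with that mean at fixed ``precision``.  In the
    active arm each CpG is hypermethylated with probability
    ``shift_probability * state_shift_multipliers[state]`` by adding
    ``global_shift`` to its mean (clipped at 1).
    """

    n_cpg: int = 20_000
    n_chrom: int = 5
    states: tuple[str, ...] = DEFAULT_STATES
    state_weights: tuple[float, ...] | None = None  # None = uniform
    arms: tuple[str, ...] = ARMS
    n_replicates: int = 3
    baseline_beta_params: tuple[float, float] = (0.85, 0.85)
    precision: float = 120.0
    global_shift: float = 0.3
    shift_probability: float = 0.3
    state_shift_multipliers: dict[str, float] = field(default_factory=dict)
    detection_fail_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cpg > 0, "n_cpg must be positive")
        _require(self.n_chrom > 0, "n_chrom must be positive")
        _require(self.n_replicates > 0, "n_replicates must be positive")
        _require(len(self.states) > 0, "need at least one chromatin state")
        _require(len(set(self.states)) == len(self.states), "duplicate state labels")
        if self.state_weights is None:
            self.state_weights = tuple(1.0 / len(self.states) for _ in self.states)
        _require(len(self.state_weights) == len(self.states), "state_weights length mismatch")
        _require(all(w >= 0 for w in self.state_weights), "state_weights must be non-negative")
        _require(abs(sum(self.state_weights) - 1.0) < 1e-9, "state_weights must sum to 1")
        a, b = self.baseline_beta_params
        _require(a > 0 and b > 0, "baseline Beta shapes must be positive")
        _require(self.precision > 0, "precision must be positive")
        _require(self.global_shift >= 0, "global_shift must be >= 0")
        _require(0 <= self.shift_probability <= 1, "shift_probability must be in [0,1]")
        _require(0 <= self.detection_fail_rate <= 1, "detection_fail_rate must be in [0,1]")
        unknown = set(self.state_shift_multipliers) - set(self.states)
        _require(not unknown, f"multipliers for unknown states: {sorted(unknown)}")

    def shift_prob_per_state(self) -> np.ndarray:
        """Per-state hypermethylation probability, clipped to [0, 1]."""
        mult = np.array([self.state_shift_multipliers.get(s, 1.0) for s in self.states])
        return np.clip(self.shift_probability * mult, 0.0, 1.0)


@dataclass
class ScreenConfig:
    """Pooled-screen count generator settings.

    Counts per guide and sample are negative binomial around
    ``mean_depth * 2**baseline_i`` where the per-guide ``baseline_i`` (log2
    library-representation offset, SD ``guide_log2_sd``) is shared across
    arms — the source of the tight guide-abundance diagonal seen in a null
    screen.  ``effect_regions`` maps region id → log2 proliferation effect
    applied to the active arm only.
    """

    n_regions: int = 1009
    guides_per_region: int = 10
    n_nontargeting: int = 737
    n_aavs1: int = 262
    mean_depth: float = 500.0
    nb_dispersion: float = 20.0
    guide_log2_sd: float = 1.2
    effect_regions: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_regions >= 0, "n_regions must be >= 0")
        _require(self.guides_per_region >= 1, "guides_per_region must be >= 1")
        _require(self.n_nontargeting >= 0 and self.n_aavs1 >= 0, "control counts must be >= 0")
        _require(self.mean_depth > 0, "mean_depth must be positive")
        _require(self.nb_dispersion > 0, "nb_dispersion must be positive")
        _require(self.guide_log2_sd >= 0, "guide_log2_sd must be >= 0")
        _require(self.n_replicates >= 1, "n_replicates must be >= 1")


@dataclass
class TrackingConfig:
    """Single-particle trajectory and movie generator settings.

    Displacements follow fractional Gaussian noise with anomalous exponent
    ``alpha`` (1 = Brownian) scaled so the 2-D ensemble MSD is
    ``4 D t**alpha``; isotropic Gaussian localization noise of SD
    ``localization_sigma`` (µm) is added to each observed position.
    """

    n_particles: int = 50
    n_frames: int = 50
    frame_interval: float = 0.03  # s
    diffusion_coefficient: float = 0.5  # µm²/s
    alpha: float = 1.0
    localization_sigma: float = 0.02  # µm
    pixel_size: float = 0.107  # µm/px
    field_size: int = 64  # px
    psf_sigma: float = 1.3  # px
    photons: float = 300.0  # peak spot amplitude, counts
    background: float = 100.0  # counts/px
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_particles >= 0, "n_particles must be >= 0")
        _require(self.n_frames >= 1, "n_frames must be >= 1")
        _require(self.frame_interval > 0, "frame_interval must be positive")
        _require(self.diffusion_coefficient >= 0, "D must be >= 0")
        _require(0 < self.alpha <= 2, "alpha must be in (0, 2]")
        _require(self.localization_sigma >= 0, "localization_sigma must be >= 0")
        _require(self.pixel_size > 0, "pixel_size must be positive")
        _require(self.field_size > 0, "field_size must be positive")
        _require(self.psf_sigma > 0, "psf_sigma must be positive")
        _require(self.photons >= 0 and self.background >= 0, "intensities must be >= 0")


@dataclass
class MeltConfig:
    """HRM melt-curve generator settings.

    Each curve is a convex combination of two logistic melt transitions: the
    methylated species melting at ``tm_methylated`` and the unmethylated one
    at ``tm_unmethylated`` (methylated DNA melts higher), plus i.i.d. Gaussian
    fluorescence noise.  ``mixture_fractions`` are the true percent-methylation
    levels of the simulated unknowns; the four calibration standards
    {0, 25, 50, 100}% are always generated.
    """

    temp_grid: np.ndarray = None  # type: ignore[assignment]
    tm_methylated: float = 82.0
    tm_unmethylated: float = 76.0
    slope: float = 1.0  # °C transition width
    noise_sd: float = 0.01
    mixture_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temp_grid is None:
            # 60–95 °C at 0.1 °C steps, the instrument ramp used for HRM
            self.temp_grid = np.arange(60.0, 95.0 + 1e-9, 0.1)
        self.temp_grid = np.asarray(self.temp_grid, dtype=float)
        _require(self.temp_grid.ndim == 1 and self.temp_grid.size >= 3, "temp_grid too small")
        _require(bool(np.all(np.diff(self.temp_grid) > 0)), "temp_grid must be strictly increasing")
        _require(self.tm_methylated > self.tm_unmethylated,
                 "methylated DNA must melt at a higher temperature")
        _require(self.slope > 0, "slope must be positive")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(all(0 <= f <= 1 for f in self.mixture_fractions),
                 "mixture fractions must be in [0,1]")
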