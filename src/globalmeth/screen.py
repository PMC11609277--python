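"""Pooled-screen scoring: normalization, guide LFCs, region gene scores.

A proliferation screen compares sgRNA abundance after 21 days of culture
between cells carrying the active effector and the catalytically inactive
control.  Counts are normalized to log2 reads-per-million (+1 pseudocount),
per-guide log-fold-changes (active − inactive, replicate-averaged) are
computed, each target region's gene score is the mean LFC of its guides, and
a robust z-score against pseudo-regions built from the non-targeting control
guides flags regions departing from the null.  Arm-correlation diagnostics
(Pearson r of abundances or gene scores between arms) summarize whether the
two arms behave identically, the hallmark of a no-hit screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, ConfigurationError, PairingError

GUIDE_CLASSES = ("region-targeting", "non-targeting", "AAVS1")


@dataclass
class ScreenTable:
    """Raw guide counts plus guide and sample metadata.

    ``counts``: guides × samples integer matrix.
    ``guides``: indexed by guide id with ``class`` (region-targeting /
    non-targeting / AAVS1) and ``region`` (empty for controls).
    ``samples``: indexed by sample id with ``arm`` (active / inactive) and
    integer ``replicate``.
    """

    counts: pd.DataFrame
    guides: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.guides.index):
            raise AlignmentError("count matrix and guide table ids differ")
        if not self.counts.columns.equals(self.samples.index):
            raise AlignmentError("count matrix columns and sample sheet differ")
        if (self.counts.to_numpy() < 0).any():
            raise ConfigurationError("counts must be non-negative")
        targeting = self.guides["class"] == "region-targeting"
        if (self.guides.loc[targeting, "region"].fillna("") == "").any():
            raise ConfigurationError("region-targeting guides need a region id")


@dataclass
class GuideScoreTable:
    """Normalized per-sample abundances and per-guide LFCs."""

    abundance: pd.DataFrame  # guides × samples, log2 RPM + pseudocount
    guides: pd.DataFrame
    samples: pd.DataFrame
    lfc: pd.Series | None = None  # filled by guide_lfc


def normalize_counts(table: ScreenTable, pseudocount: float = 1.0) -> GuideScoreTable:
    """log2(1e6 * count / sample_total + pseudocount) per guide and sample."""
    totals = table.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ConfigurationError(f"zero-total samples: {bad}")
    rpm = 1e6 * table.counts / totals
    abundance = np.log2(rpm + pseudocount)
    return GuideScoreTable(abundance=abundance, guides=table.guides, samples=table.samples)


def _paired_arms(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """(active, inactive) sample-id pairs matched by replicate index."""
    act = samples[samples["arm"] == "active"].sort_values("replicate")
    ina = samples[samples["arm"] == "inactive"].sort_values("replicate")
    if act.empty or ina.empty:
        raise PairingError("both 'active' and 'inactive' arms are required")
    if len(act) != len(ina):
        raise PairingError(f"unpaired replicates: {len(act)} active vs {len(ina)} inactive")
    return list(zip(act.index, ina.index))


def guide_lfc(scores: GuideScoreTable) -> pd.Series:
    """Per-guide LFC: mean over replicate pairs of (active − inactive) abundance."""
    pairs = _paired_arms(scores.samples)
    diffs = [scores.abundance[a] - scores.abundance[i] for a, i in pairs]
    lfc = pd.concat(diffs, axis=1).mean(axis=1)
    lfc.name = "lfc"
    scores.lfc = lfc
    return lfc


def gene_score(
    lfc: pd.Series,
    table: ScreenTable,
    pseudo_region_size: int = 10,
) -> pd.DataFrame:
    """Region gene scores (mean guide LFC) with robust z against controls.

    The null centre is the median score of pseudo-regions built, in order,
    from blocks of ``pseudo_region_size`` non-targeting guides.  The null
    spread of a region with n guides is the scaled MAD (1.4826 × median
    absolute deviation) of the non-targeting *guide* LFCs divided by √n:
    the guide-level MAD pools all controls, so the spread estimate is far
    more stable than a MAD over the pseudo-region scores themselves, and it
    adapts to regions with unequal guide counts.
    """
    guides = table.guides
    targeting = guides[guides["class"] == "region-targeting"]
    merged = pd.DataFrame({"lfc": lfc.loc[targeting.index], "region": targeting["region"]})
    grouped = merged.groupby("region")["lfc"]
    scores = grouped.mean()
    n_guides = grouped.size()
    empty_regions = n_guides[n_guides == 0]
    if not empty_regions.empty:  # pragma: no cover - groupby drops empty groups
        warnings.warn(f"excluded {len(empty_regions)} regions with no guides")
    nt = guides.index[guides["class"] == "non-targeting"]
    if len(nt) >= pseudo_region_size:
        nt_lfc = lfc.loc[nt].to_numpy()
        n_pseudo = len(nt_lfc) // pseudo_region_size
        pseudo = nt_lfc[: n_pseudo * pseudo_region_size].reshape(n_pseudo, -1).mean(axis=1)
        center = float(np.median(pseudo))
        guide_spread = 1.4826 * float(np.median(np.abs(nt_lfc - np.median(nt_lfc))))
    else:
        warnings.warn("too few non-targeting guides for a null distribution; z set to NaN")
        center, guide_spread = np.nan, np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        if guide_spread and np.isfinite(guide_spread):
            robust_z = (scores - center) / (guide_spread / np.sqrt(n_guides))
        else:
            robust_z = pd.Series(np.nan, index=scores.index)
    return pd.DataFrame({"score": scores, "n_guides": n_guides, "robust_z": robust_z})


def arm_correlation(
    scores: GuideScoreTable | pd.DataFrame,
    level: str = "guide",
) -> tuple[float, float]:
    """Pearson r (and two-tailed p) between active- and inactive-arm values.

    ``level='guide'`` correlates replicate-averaged normalized abundances per
    guide from a :class:`GuideScoreTable`.  ``level='region'`` accepts a
    DataFrame with ``score_active`` and ``score_inactive`` columns.
    """
    if level == "guide":
        if not isinstance(scores, GuideScoreTable):
            raise ConfigurationError("guide-level correlation needs a GuideScoreTable")
        samples = scores.samples
        act = samples.index[samples["arm"] == "active"]
        ina = samples.index[samples["arm"] == "inactive"]
        x = scores.abundance[act].mean(axis=1).to_numpy()
        y = scores.abundance[ina].mean(axis=1).to_numpy()
    elif level == "region":
        x = np.asarray(scores["score_active"], dtype=float)
        y = np.asarray(scores["score_inactive"], dtype=float)
    else:
        raise ConfigurationError(f"unknown level {level!r}")
    if len(x) < 3:
        raise ConfigurationError("Pearson correlation needs >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConfigurationError("zero variance: Pearson r undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def write_screen_tsv(table: ScreenTable, counts_path, samples_path) -> None:
    """Write guide counts (+ class/region columns) and the sample sheet as TSV."""
    out = pd.concat([table.guides[["class", "region"]], table.counts], axis=1)
    out.to_csv(counts_path, sep="\t", index_label="guide")
    table.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_screen_tsv(counts_path, samples_path) -> ScreenTable:
    df = pd.read_csv(counts_path, sep="\t", index_col="guide")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    guides = df[["class", "region"]].copy()
    guides["region"] = guides["region"].fillna("")
    counts = df.drop(columns=["class", "region"]).astype(np.int64)
    counts.columns.name = "sample"
    return ScreenTable(counts=counts, guides=guides, samples=samples)
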