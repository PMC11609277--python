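"""Resampling enrichment of hypermethylated CpGs across chromatin states.

Given a per-CpG fold-change table and a chromHMM-style genome partition, the
test counts how many strongly hypermethylated sites (fold-change >= 2 by
default) fall in each chromatin state, builds a resampled null by repeatedly
drawing random probe sets from the full array, and reports a Z-score per
state: Z > 0 means the state carries more hypermethylated sites than random
placement would produce.

Two null constructions are offered (``null_mode``):

``membership``
    Draw as many random probes as there are hypermethylated sites and count
    how many land in each state (state membership of a random set of the
    observed size).
``fc-recount``
    For each state, draw as many random probes as the state contains and
    count how many of the drawn probes are themselves hypermethylated
    (re-count of significant sites within annotation-sized random draws).

Under a genome-wide partition the two are calibrated against the same
hypergeometric law; both are kept because published descriptions of this
style of test are worded either way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError, ParseError

UNASSIGNED = "unassigned"


@dataclass
class Segmentation:
    """Non-overlapping labelled genomic intervals (0-based, half-open).

    ``intervals`` columns: ``chrom``, ``start``, ``end``, ``state``.
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intervals
        need = {"chrom", "start", "end", "state"}
        if not need.issubset(df.columns):
            raise ConfigurationError(f"segmentation needs columns {sorted(need)}")
        if (df["start"] >= df["end"]).any():
            raise ConfigurationError("segmentation has intervals with start >= end")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
        overlap = df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1]
        if np.any(same & overlap):
            raise ConfigurationError("segmentation intervals overlap within a chromosome")
        self.intervals = df

    @property
    def states(self) -> list[str]:
        return sorted(self.intervals["state"].unique())


@dataclass
class EnrichmentResult:
    """Observed counts, resampled null moments and Z-scores per state.

    ``table`` columns: ``observed``, ``null_mean``, ``null_sd``, ``z``
    (NaN where the null is degenerate).  Parameters used are kept for
    provenance.
    """

    table: pd.DataFrame
    n_resamples: int
    threshold: float
    seed: int | None = None
    n_selected: int | None = None
    null_mode: str = "membership"


def read_segmentation_bed(path) -> Segmentation:
    """Read a 4+-column BED (chrom, start, end, state) into a Segmentation."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"expected >= 4 BED columns, got {len(parts)}", line=i)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinates: {parts[1]!r}/{parts[2]!r}", line=i) from exc
            rows.append((parts[0], start, end, parts[3]))
    return Segmentation(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]))


def write_segmentation_bed(seg: Segmentation, path) -> None:
    seg.intervals[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def intersect_annotations(probes: pd.DataFrame, seg: Segmentation) -> pd.Series:
    """Assign each probe to the chromatin state of the interval containing it.

    ``probes`` is a manifest indexed by probe id with ``chrom`` and 1-based
    ``pos``; a probe at position p lies in interval [start, end) iff
    start <= p - 1 < end.  Probes covered by no interval map to
    ``"unassigned"``.
    """
    if not {"chrom", "pos"}.issubset(probes.columns):
        raise AlignmentError("probe manifest needs 'chrom' and 'pos' columns")
    result = pd.Series(UNASSIGNED, index=probes.index, name="state", dtype=object)
    for chrom, ivals in seg.intervals.groupby("chrom", sort=False):
        mask = probes["chrom"] == chrom
        if not mask.any():
            continue
        coord = probes.loc[mask, "pos"].to_numpy(dtype=np.int64) - 1  # 0-based
        starts = ivals["start"].to_numpy(dtype=np.int64)
        ends = ivals["end"].to_numpy(dtype=np.int64)
        states = ivals["state"].to_numpy()
        idx = np.searchsorted(starts, coord, side="right") - 1
        inside = (idx >= 0) & (coord < ends[np.clip(idx, 0, len(ends) - 1)])
        assigned = np.where(inside, states[np.clip(idx, 0, len(states) - 1)], UNASSIGNED)
        result.loc[mask] = assigned
    return result


def observed_counts(
    fc,
    annot: pd.Series,
    threshold: float = 2.0,
    states: list[str] | None = None,
) -> tuple[pd.Series, int]:
    """Per-state count of hypermethylated probes (FC >= threshold, inclusive).

    Returns the per-state counts (unassigned probes excluded from the listing
    but included in the total) and the total number of FC >= threshold probes.
    """
    fc_series = fc.fc if hasattr(fc, "fc") else pd.Series(fc)
    common = fc_series.index.intersection(annot.index)
    if common.empty:
        raise AlignmentError("fold-change table and annotation map share no probes")
    fc_series = fc_series.loc[common]
    ann = annot.loc[common]
    hot = fc_series >= threshold
    total = int(hot.sum())
    if states is None:
        states = sorted(s for s in ann.unique() if s != UNASSIGNED)
    counts = ann[hot].value_counts()
    out = pd.Series([int(counts.get(s, 0)) for s in states], index=states, name="observed")
    return out, total


def resample_null(
    annot: pd.Series,
    n_select: int,
    n_resamples: int = 100,
    seed: int | None = None,
    states: list[str] | None = None,
) -> pd.DataFrame:
    """Null per-state counts from uniform draws of ``n_select`` probes.

    Each resample draws ``n_select`` probe ids without replacement from the
    full probe universe (unassigned probes included — they are on the array)
    and records how many drawn probes belong to each state.  Marginally each
    state's count is hypergeometric with mean ``n_select * state_fraction``.
    """
    n_universe = len(annot)
    if n_select > n_universe:
        raise ConfigurationError(f"n_select={n_select} exceeds universe size {n_universe}")
    if n_resamples < 1:
        raise ConfigurationError("n_resamples must be >= 1")
    if states is None:
        states = sorted(s for s in annot.unique() if s != UNASSIGNED)
    codes = pd.Categorical(annot.to_numpy(), categories=states).codes  # -1 = not listed
    rng = np.random.default_rng(seed)
    null = np.zeros((n_resamples, len(states)), dtype=np.int64)
    for r in range(n_resamples):
        draw = rng.choice(n_universe, size=n_select, replace=False)
        drawn_codes = codes[draw]
        null[r] = np.bincount(drawn_codes[drawn_codes >= 0], minlength=len(states))
    return pd.DataFrame(null, columns=states)


def z_scores(observed: pd.Series, null: pd.DataFrame) -> pd.DataFrame:
    """Mean-centre and scale the null; Z per state, NaN where null SD is zero."""
    if set(observed.index) != set(null.columns):
        raise AlignmentError("observed and null state sets differ")
    null = null[observed.index]
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - mean) / sd
    z[sd == 0] = np.nan
    return pd.DataFrame(
        {"observed": observed, "null_mean": mean, "null_sd": sd, "z": z}
    )


def run_enrichment(
    fc,
    annot: pd.Series,
    threshold: float = 2.0,
    n_resamples: int = 100,
    seed: int | None = None,
    null_mode: str = "membership",
) -> EnrichmentResult:
    """Full enrichment test: observed counts -> resampled null -> Z-scores."""
    if null_mode not in ("membership", "fc-recount"):
        raise ConfigurationError(f"unknown null_mode {null_mode!r}")
    states = sorted(s for s in annot.unique() if s != UNASSIGNED)
    obs, total = observed_counts(fc, annot, threshold=threshold, states=states)
    if null_mode == "membership":
        null = resample_null(annot, n_select=total, n_resamples=n_resamples,
                             seed=seed, states=states)
    else:
        null = _fc_recount_null(fc, annot, threshold, n_resamples, seed, states)
    table = z_scores(obs, null)
    return EnrichmentResult(
        table=table,
        n_resamples=n_resamples,
        threshold=threshold,
        seed=seed,
        n_selected=total,
        null_mode=null_mode,
    )


def _fc_recount_null(fc, annot, threshold, n_resamples, seed, states) -> pd.DataFrame:
    """Annotation-sized random draws, re-counting FC >= threshold within each."""
    fc_series = fc.fc if hasattr(fc, "fc") else pd.Series(fc)
    common = fc_series.index.intersection(annot.index)
    hot = (fc_series.loc[common] >= threshold).to_numpy()
    ann = annot.loc[common]
    n_universe = len(common)
    rng = np.random.default_rng(seed)
    sizes = {s: int((ann == s).sum()) for s in states}
    null = np.zeros((n_resamples, len(states)), dtype=np.int64)
    for j, s in enumerate(states):
        m = sizes[s]
        for r in range(n_resamples):
            draw = rng.choice(n_universe, size=m, replace=False)
            null[r, j] = int(hot[draw].sum())
    return pd.DataFrame(null, columns=states)
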