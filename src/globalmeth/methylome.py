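"""Two-arm methylome analysis: QC, normalization, per-CpG fold-change, MDS.

The workflow mirrors a standard array methylation comparison between cells
carrying an active de-novo methyltransferase effector and the catalytically
inactive control: drop probes that fail detection in any sample, quantile
normalize betas across samples, compute the replicate-averaged per-CpG
fold-change of active over inactive betas, and summarize samples by classical
multidimensional scaling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import AlignmentError, ConfigurationError, PairingError

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ("arm", "sgrna", "replicate")


@dataclass
class BetaMatrix:
    """CpG-probe × sample matrix of methylation beta values in [0, 1].

    Attributes
    ----------
    betas : DataFrame, probes × samples
    manifest : DataFrame indexed by probe id with ``chrom`` and 1-based ``pos``
    samples : DataFrame indexed by sample id with ``arm`` (mock / inactive /
        active), ``sgrna`` label and integer ``replicate``
    """

    betas: pd.DataFrame
    manifest: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.betas.index.has_duplicates:
            raise AlignmentError("duplicate probe ids in beta matrix")
        if not self.betas.index.equals(self.manifest.index):
            raise AlignmentError("beta matrix and manifest probe ids differ")
        if not self.betas.columns.equals(self.samples.index):
            raise AlignmentError("beta matrix columns and sample sheet ids differ")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise AlignmentError(f"sample sheet lacks columns: {missing}")
        vals = self.betas.to_numpy()
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ConfigurationError("beta values outside [0, 1]")

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def arm_samples(self, arm: str) -> pd.DataFrame:
        """Sample-sheet rows for one arm, sorted by replicate index."""
        sub = self.samples[self.samples["arm"] == arm]
        return sub.sort_values("replicate")


@dataclass
class FoldChangeTable:
    """Per-CpG replicate-averaged methylation fold-change with coordinates.

    ``table`` columns: ``chrom``, ``pos`` (1-based), ``fc`` (mean over
    replicate pairs), plus one ``fc_rep<i>`` column per replicate pair.
    """

    table: pd.DataFrame
    numerator_arm: str = "active"
    denominator_arm: str = "inactive"
    floor: float = 0.01

    def __post_init__(self) -> None:
        if (self.table["fc"] <= 0).any():
            raise ConfigurationError("fold-changes must be positive")

    @property
    def fc(self) -> pd.Series:
        return self.table["fc"]


@dataclass
class MDSCoordinates:
    """Classical-MDS sample embedding and the Gram-matrix eigenvalues."""

    coordinates: pd.DataFrame  # samples × k
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def filter_detection(
    betas: BetaMatrix,
    detp: pd.DataFrame,
    threshold: float = 0.01,
) -> BetaMatrix:
    """Drop every probe whose detection p-value exceeds ``threshold`` in ANY sample.

    The comparison is strict (p > threshold fails; p == threshold is kept),
    matching the convention that a probe is low quality when both channels
    are at background with p-value > 0.01.
    """
    if not detp.index.equals(betas.betas.index) or not detp.columns.equals(betas.betas.columns):
        raise AlignmentError("detection-p table is not aligned to the beta matrix")
    bad = (detp.to_numpy() > threshold).any(axis=1)
    n_dropped = int(bad.sum())
    logger.info("detection filter dropped %d/%d probes (p > %g)", n_dropped, len(bad), threshold)
    keep = ~bad
    return BetaMatrix(
        betas=betas.betas.loc[keep],
        manifest=betas.manifest.loc[keep],
        samples=betas.samples,
    )


def quantile_normalize(betas: BetaMatrix) -> BetaMatrix:
    """Across-sample quantile normalization of the beta matrix.

    Every column is mapped onto the common reference distribution formed by
    the row-wise mean of the sorted columns; ties within a column receive the
    average of the reference values at their rank positions.  With a single
    sample the matrix is returned unchanged with a warning.
    """
    x = betas.betas.to_numpy(dtype=float)
    n, m = x.shape
    if m < 2:
        warnings.warn("quantile normalization needs >= 2 samples; passing through")
        return betas
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        # average ranks handle ties: interpolate the reference at rank-1 positions
        ranks = rankdata(x[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, np.arange(n), reference)
    return BetaMatrix(
        betas=pd.DataFrame(out, index=betas.betas.index, columns=betas.betas.columns),
        manifest=betas.manifest,
        samples=betas.samples,
    )


def fold_change(
    betas: BetaMatrix,
    numerator_arm: str = "active",
    denominator_arm: str = "inactive",
    floor: float = 0.01,
) -> FoldChangeTable:
    """Replicate-averaged per-CpG beta fold-change between two arms.

    Replicates are paired by replicate index; for each pair,
    ``FC_r = max(beta_num, floor) / max(beta_den, floor)`` and the reported FC
    is the arithmetic mean of the per-replicate ratios.  The floor guards
    against division by near-zero betas at unmethylated sites.
    """
    num = betas.arm_samples(numerator_arm)
    den = betas.arm_samples(denominator_arm)
    if num.empty or den.empty:
        raise PairingError(
            f"both arms required: {numerator_arm!r} has {len(num)} samples, "
            f"{denominator_arm!r} has {len(den)}"
        )
    if len(num) != len(den):
        raise PairingError(
            f"unpaired replicate counts: {len(num)} vs {len(den)} "
            f"({numerator_arm} vs {denominator_arm})"
        )
    out = betas.manifest[["chrom", "pos"]].copy()
    reps = []
    for (rep_n, row_n), (rep_d, row_d) in zip(num.iterrows(), den.iterrows()):
        a = np.maximum(betas.betas[rep_n].to_numpy(dtype=float), floor)
        b = np.maximum(betas.betas[rep_d].to_numpy(dtype=float), floor)
        col = f"fc_rep{int(row_n['replicate'])}"
        out[col] = a / b
        reps.append(col)
    out["fc"] = out[reps].mean(axis=1)
    return FoldChangeTable(
        table=out,
        numerator_arm=numerator_arm,
        denominator_arm=denominator_arm,
        floor=floor,
    )


def mean_global_fold_change(fc: FoldChangeTable) -> float:
    """Arithmetic mean fold-change across all retained CpG sites.

    This is the genome-wide summary plotted per sgRNA: a value near 1 means
    no net methylation change, while globally deposited methylation pushes it
    well above 1.
    """
    if fc.table.empty:
        raise ConfigurationError("empty fold-change table")
    return float(fc.fc.mean())


def classical_mds(betas: BetaMatrix, k: int = 2) -> MDSCoordinates:
    """Classical (Torgerson) MDS of samples on Euclidean beta-vector distances.

    The squared-distance matrix is double centred, the top-``k`` eigenvectors
    are scaled by the square root of their eigenvalues, and each axis is
    sign-fixed so its first nonzero loading is positive.
    """
    x = betas.betas.to_numpy(dtype=float).T  # samples × probes
    n = x.shape[0]
    if n < 3:
        raise ConfigurationError("classical MDS needs >= 3 samples")
    if k >= n:
        raise ConfigurationError(f"k={k} must be < n_samples={n}")
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ sq @ j
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))
    for axis in range(k):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    return MDSCoordinates(
        coordinates=pd.DataFrame(
            coords, index=betas.betas.columns, columns=[f"dim{i + 1}" for i in range(k)]
        ),
        eigenvalues=eigval,
    )


def manhattan_export(fc: FoldChangeTable, path) -> None:
    """Write per-CpG log2 fold-changes as a sorted, 0-based half-open bedGraph.

    A probe at 1-based position ``p`` becomes the interval ``[p-1, p)``.  The
    file opens and explores cleanly in IGV.
    """
    tbl = fc.table
    header = (
        f'track type=bedGraph name="log2FC {fc.numerator_arm}/{fc.denominator_arm}"\n'
    )
    with open(path, "w") as fh:
        fh.write(header)
        if tbl.empty:
            return
        known = ~tbl["chrom"].isna()
        if not known.all():
            warnings.warn("probes with unknown chromosome were dropped from bedGraph")
            tbl = tbl[known]
        out = tbl[["chrom", "pos"]].copy()
        out["start"] = out["pos"].astype(int) - 1
        out["end"] = out["pos"].astype(int)
        out["value"] = np.log2(tbl["fc"].to_numpy())
        out = out.sort_values(
            ["chrom", "start"],
            key=lambda s: s.map(_natural_key) if s.name == "chrom" else s,
        )
        for chrom, start, end, value in out[["chrom", "start", "end", "value"]].itertuples(
            index=False
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6f}\n")


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph written by :func:`manhattan_export` (chrom/start/end/value)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def _natural_key(chrom: str):
    """Sort chr2 before chr10; non-numeric suffixes (X, Y, M) after numbers."""
    tag = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(tag), "") if tag.isdigit() else (1, 0, tag)
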