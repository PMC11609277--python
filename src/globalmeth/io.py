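"""Readers and writers for the tabular and image interchange formats.

Beta matrices travel as a probes × samples TSV with a probe manifest folded
in (chrom, pos columns) plus a sidecar sample sheet; detection p-values as an
aligned TSV; image stacks as multi-page grayscale TIFF.  Format-specific I/O
for BED segmentations, bedGraph exports, screen tables, melt curves and
track CSVs lives next to the code that owns those types.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .methylome import BetaMatrix


def write_beta_tsv(bm: BetaMatrix, betas_path, samples_path, detp=None, detp_path=None) -> None:
    out = pd.concat([bm.manifest[["chrom", "pos"]], bm.betas], axis=1)
    out.to_csv(betas_path, sep="\t", index_label="probe")
    bm.samples.to_csv(samples_path, sep="\t", index_label="sample")
    if detp is not None and detp_path is not None:
        detp.to_csv(detp_path, sep="\t", index_label="probe")


def read_beta_tsv(betas_path, samples_path) -> BetaMatrix:
    df = pd.read_csv(betas_path, sep="\t", index_col="probe")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    manifest = df[["chrom", "pos"]].copy()
    betas = df.drop(columns=["chrom", "pos"]).astype(float)
    betas.columns.name = "sample"
    return BetaMatrix(betas=betas, manifest=manifest, samples=samples)


def read_detp_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe").astype(float)


def write_stack_tiff(stack: np.ndarray, path) -> None:
    """Write a (t, y, x) float stack as multi-page grayscale TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack_tiff(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None, ...]
    return stack.astype(np.float64)
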