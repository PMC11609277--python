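# globalmeth

Analysis toolkit for experiments probing **globally deposited DNA
methylation** — the situation where a CRISPR methyltransferase effector
(dCas9–DNMT3A recruited through a SAM-style sgRNA scaffold) methylates the
genome broadly instead of only its sgRNA target. The package is written for
computational biologists who need to score that phenotype from its standard
readouts:

* **Methylome fold-change** (`globalmeth.methylome`): CpG-array beta values
  for active vs catalytically inactive effector arms — detection-p filtering
  (drop a probe when p > 0.01 in any sample), across-sample quantile
  normalization, the per-CpG replicate-averaged fold-change
  FC = mean_r [ max(β_active, 0.01) / max(β_inactive, 0.01) ], genome-wide
  mean FC, classical (Torgerson) MDS of samples, and bedGraph export for IGV.
* **Chromatin-state enrichment** (`globalmeth.enrichment`): counts of
  hypermethylated CpGs (FC ≥ 2) per chromHMM state, a resampled null
  (100 random draws of equal size from the probe universe), and
  Z = (obs − null mean)/null sd per state.
* **Pooled-screen scoring** (`globalmeth.screen`): log2 RPM+1 normalization,
  per-guide LFC (active − inactive), region gene scores (mean guide LFC),
  robust z against non-targeting controls, and Pearson arm-correlation
  diagnostics.
* **HRM quantification** (`globalmeth.hrm`): melt-curve baseline
  normalization and closed-form least-squares percent methylation against
  0%/100% standards, with 25%/50% standards held out as accuracy checks.
* **Single-particle tracking** (`globalmeth.spt`): LoG spot detection,
  LAP frame-to-frame linking (no gap closing, no merge/split), time-averaged
  MSD, and fits of MSD(t) = 4·D·t^α + 2·σ² with track-length (≥5 frames) and
  fit-quality (R² ≥ 0.8) filters.
* **Synthetic data** (`globalmeth.synthetic_data`): generators that emulate
  each input's statistical structure (two-arm Beta-distributed methylomes,
  negative-binomial screen counts, fractional-Brownian tracks and rendered
  movies, two-state sigmoid melt curves), used throughout the test suite.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a synthetic two-arm methylome with a promoter-biased
hypermethylation shift, run the fold-change pipeline and the enrichment
test:

```python
from globalmeth import MethylomeConfig
from globalmeth import synthetic_data as synth, methylome as meth, enrichment as enr

cfg = MethylomeConfig(n_cpg=20_000, global_shift=0.3,
                      state_shift_multipliers={"TssA": 2.0}, seed=0)
betas, annot, detp = synth.make_methylome(cfg)
betas = meth.quantile_normalize(meth.filter_detection(betas, detp))
fc = meth.fold_change(betas)            # active / inactive, replicate-averaged
print(f"mean global FC: {meth.mean_global_fold_change(fc):.3f}")
res = enr.run_enrichment(fc, annot.loc[betas.betas.index], seed=1)
print(res.table[["observed", "null_mean", "z"]].round(2))
```

Output:

```
mean global FC: 1.320
          observed  null_mean     z
Enh            129     129.97 -0.10
EnhG           110     135.71 -2.46
Het            118     134.11 -1.59
Quies          114     129.85 -1.63
ReprPC         111     131.88 -2.34
TssA           233     132.91  9.09
TssFlnk        105     132.78 -2.51
Tx             120     128.83 -0.79
TxWk           137     129.18  0.75
ZNF_Rpts       143     134.78  0.77
```

The promoter state (TssA), whose hypermethylation probability was doubled,
stands out at Z ≈ 9 while every other state sits inside the resampled null —
the signature of methylation enriched in a specific chromatin context.
(Across-sample quantile normalization removes part of an arm-wide marginal
shift; run `fold_change` on unnormalized betas to measure the global
increase itself — the generator calibration `global_shift=0.2805,
shift_probability=1.0` yields a genome-wide mean FC of ≈ 3.)

The same stages are exposed on the command line:

```bash
globalmeth simulate --kind methylome --seed 0 --out sim/
globalmeth methylome --betas sim/betas.tsv --samples sim/samples.tsv \
    --detp sim/detection_p.tsv --out out/
globalmeth enrich --fc out/fold_change.tsv --segmentation sim/segmentation.bed \
    --seed 1 --out out/enrichment.tsv
```

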