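# zingerscan

Detection and characterization of **zinger motifs** — transcription-factor
binding motifs (CTCF-like, ETS-like, JUN-like and THAP11) that turn up,
enriched and centred on the peak maximum, in ChIP-seq datasets where that
factor was *not* the immunoprecipitation target. Zinger motif peaks can make
up a large share of a dataset and confound motif-based interpretation, so
quantifying them matters to anyone analysing TF ChIP-seq peak collections.

The package implements the full analysis as a reusable, tested pipeline,
plus a synthetic-data generator that reproduces the statistical structure of
a multi-dataset ChIP-seq corpus so every stage can be validated against
planted ground truth at desk scale.

## What it computes

Given peak sets (BED6/narrowPeak/broadPeak), sequences (FASTA) and binding
profiles (JASPAR raw PFM text):

1. **Motif scanning** (`zingerscan.motifs`). PFMs are converted to log-odds
   PWMs with the √N pseudocount convention,
   `w_bj = log2((c_bj + p_b√N) / (N + √N) / p_b)`, and windows are scored on
   the 0–100 relative scale `100·(s − s_min)/(s_max − s_min)`. Retained hits
   on the two strands may overlap by at most ⌊L/5⌋ bp (greedy by descending
   score), so a 7 bp motif can overlap a neighbour by at most 1 bp.
2. **Over-representation scoring** (`zingerscan.enrichment`). Per dataset
   and profile, a one-tailed Fisher exact test on motif-containing sequence
   counts against a GC-matched background gives the **Fisher-log score**
   (−ln p; 6.91 ⇔ p = 0.001), and a two-sample Kolmogorov–Smirnov test on
   motif distances to the region centre gives the **KS centrality score**.
   Infinite scores are capped (Fisher: max finite + 100, or 500; KS: 100),
   scores are averaged per ChIPped TF, binarized against row-wise
   mean + 2·SD (Fisher) and mean + 1·SD (KS) thresholds, and enriched-dataset
   counts are corrected for motif families that share a consensus
   (count − (family members − 1)).
3. **TFBS landscapes and enrichment zones** (`zingerscan.landscape`). The
   top-scoring motif per 1001 bp region is plotted against its signed
   distance to the peakMax; heuristic boundaries are set where the 5 bp
   binned density exceeds the distal (175–500 bp) baseline, and the motif
   score threshold where proximal per-bp frequency is ≥20% above the flanks
   (defaults ±90 bp and score 82). Background-corrected composition
   subtracts an equal-width distal control zone count:
   `corrected = max(0, n_zone − n_distal) / n_peaks`.
4. **Zinger peak analyses** (`zingerscan.zinger`). Pairwise zinger
   co-occurrence (2×2 Fisher, signed 1−p heatmap encoding), agreement of
   zinger motif peaks with ChIP-seq for the zinger TF itself (peakMax within
   100 bp), and one-tailed rank-sum comparisons of peak scores.
5. **Neighborhoods** (`zingerscan.neighborhoods`). Classified peakMax
   positions pooled across datasets are single-linkage merged at 50 bp;
   recurrence is counted as unique TFs and cell lines; ChIPped-TF
   neighborhoods within 300 bp of other classes are removed; proximity to
   cohesin/PRC tracks (≤500 bp) is compared with one-tailed Fisher tests.
6. **Null calibration** (`zingerscan.nullcal`). Each profile's PFM is
   column-shuffled 100 times (2 edge columns fixed; 3 for matrices ≥18
   columns wide), pushed through the same enrichment analysis with the
   original thresholds, and a zero-adjusted logarithmic distribution (ZALG)
   is fitted to the enriched-dataset counts:
   `P(0) = p₀`, `P(y) = (1 − p₀)·μʸ/(−y·ln(1 − μ))` for y ≥ 1.
   The tail probability P(Y ≥ observed) calibrates how surprising the real
   profile's enrichment frequency is.

## Worked example

```python
import zingerscan as zs

cfg = zs.simulate.default_corpus_config(seed=7, n_tfs=3, n_cell_lines=2, n_peaks=5000)
bundle = zs.run_pipeline(corpus_cfg=cfg)

comp = bundle["composition"]
print(comp[["dataset_id", "corrected_chipped", "corrected_zinger"]].round(3).to_string(index=False))
```

```
dataset_id  corrected_chipped  corrected_zinger
  TF00_CL0              0.559             0.129
  TF00_CL1              0.553             0.114
  TF01_CL0              0.575             0.119
  TF01_CL1              0.545             0.122
  TF02_CL0              0.512             0.144
  TF02_CL1              0.512             0.113
```

The corpus plants ChIPped-TF sites in 55% of peaks and zinger sites in 12%
(3% per zinger class) within ±90 bp of the peakMax; the background-corrected
composition recovers both. Continuing,

```python
print(bundle["recurrence"][["n_neighborhoods", "n_multi_tf"]])
prox = bundle["proximity"]
row = prox[(prox.track == "cohesin") & (prox.set_a == "zinger") & (prox.set_b == "chipped")].iloc[0]
print(f"cohesin proximity: zinger {row.frac_a:.2f} vs chipped {row.frac_b:.2f} "
      f"(one-tailed Fisher p = {row.p_one_tailed:.2e})")
```

```
              n_neighborhoods  n_multi_tf
zinger                 3341.0       318.0
chipped               15389.0        89.0
unidentified           6661.0        39.0

cohesin proximity: zinger 0.37 vs chipped 0.14 (one-tailed Fisher p = 1.31e-184)
```

Zinger peaks recur across datasets (318 neighborhoods ChIPped by ≥2 unique
TFs, versus 89 for ChIPped-TF peaks despite 4.6× more neighborhoods) and
their neighborhoods sit significantly closer to the simulated
cohesin-bound regions.

A command-line interface mirrors the library
(`zingerscan simulate | scan | zones | enrich | classify … | run-all`); see
`zingerscan --help`.

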