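# thymorep

Simulation and statistical analysis of thymocyte T-cell-receptor (TCR)
repertoires. The package pairs a seeded V(D)J rearrangement simulator —
which reproduces life-stage-dependent repertoire structure (shorter
non-template insertions, proximal 3'V/5'J segment bias, heavier
clone-size tails, and weaker positive selection in foetal-stage
repertoires) — with the analysis battery used to characterise such
repertoires:

- **`thymorep.catalog`** — ordered germline V/J segment catalogs with
  junction-proximal sequences, CDR1/CDR2 annotations and per-V selection
  weights (`build_catalog`, TSV round trip).
- **`thymorep.simulate`** — the rearrangement simulator: proximal-biased
  segment draws with progressive α-locus rearrangement rounds, geometric
  trimming/insertion junction assembly with ground truth, discrete
  power-law clone sizes, lineage-weighted selection, and documented
  `foetal` / `adult` / `adult_hc` presets.
- **`thymorep.io`** — AIRR Rearrangement TSV input/output, duplicate-row
  merging, validation, and sample manifests.
- **`thymorep.abundance`** — clone-size spectra, discrete power-law
  maximum-likelihood fits (Hurwitz-zeta normalised, optional Clauset-style
  `xmin` scan), and top-1% clonality statistics.
- **`thymorep.diversity`** — rarefaction (hypergeometric subsampling) and
  rarefied Shannon entropy, Gini index, and pairwise CDR3 Jaccard
  similarity.
- **`thymorep.usage`** — proportional V/J and V×J usage tables in
  chromosomal order, group-mean heatmaps with average-linkage column
  clustering, Benjamini–Hochberg FDR, and the differential V×J tiling
  procedure (detection thresholds, Student's t, BH 5%).
- **`thymorep.cdr`** — junction productivity classification, greedy
  germline decomposition into V match / insert / J match, insert-length
  and CDR3-length statistics, and CDR1×CDR2 recoding of V usage.
- **`thymorep.pca`** — log10(+0.01 pseudocount for zeros) → per-feature
  z-score → SVD PCA with variance fractions and per-feature contributions.
- **`thymorep.pipeline`** — cohort-level orchestration emitting tidy TSV
  result tables, plus the Levene-gated Student/Welch scalar group test.

## CLI

```sh
# simulate a repertoire (AIRR TSV) with junction ground truth
thymorep simulate --preset foetal --cell-type DP --chain TRB \
    --n 50000 --seed 7 --out sample.tsv --truth sample.truth.tsv

# clone-size statistics
thymorep stats --in sample.tsv --out stats.json --spectrum spectrum.tsv

# rarefied diversity over a manifest (path/sample_id/life_stage/cell_type/chain TSV)
thymorep diversity --manifest samples.tsv --stat shannon \
    --depth 50000 --repeats 1000 --seed 7 --out div.tsv

# differential V x J tiles between two groups
thymorep diffusage --group-a manifestA.tsv --group-b manifestB.tsv \
    --weighting total --min-detected 3 --out tiles.tsv

# junction features; PCA; full simulated-cohort run
thymorep cdr --in sample.tsv --out cdr.json
thymorep pca --manifest samples.tsv --features vxj --subset adult --out pca.json
thymorep run --config study.yaml --out results --seed 0
```

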