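# tailtop

Integrated analysis of poly(A) tail-length processing, RNA turnover and
translational engagement of 5′TOP transcripts, driven by a seeded
synthetic-data generator with known ground truth.

## The problem

During stem-cell differentiation into neurons, global translation drops
and the transcripts encoding the translational machinery — **TOP mRNAs**,
marked by a 5′-terminal oligopyrimidine tract of ~4–15 pyrimidines — are
transcriptionally silenced, yet they remain unusually stable (half-lives
around 20 h), accumulate with poly(A) tails ~60 nt long, and become
*more* translationally active.  Detecting that signature requires
combining four assays: nanopore direct-RNA poly(A) tail calls, SLAM-seq
metabolic-labeling time courses, RNA-seq and ribosome-footprint (RFP)
count matrices.  `tailtop` implements the full analysis stack for those
inputs, plus a generator that emulates all four with configurable ground
truth, so every statistic can be validated against what was actually
simulated.

## What is computed

* **Tail profiles** — per transcript × sample, the fraction of PASS reads
  with tails <30 nt, 30–90 nt ("~60 nt") and >90 nt; transcripts need
  ≥30 reads pooled across samples and must not be mitochondrial or
  pseudogenes.  Band-fraction changes between conditions are tested per
  transcript with a pooled two-sample Student's t-test (p ≤ 0.05).
* **Kinetic fits** — T→C conversions normalized to each transcript's
  saturation conversion (chase t = 0); decay fitted as `A·exp(−k t)`,
  synthesis as `1 − exp(−k t)`; half-life `t½ = ln2/k`; fits kept only if
  R² > 0.6 and 0 < t½ < 5000 min.
* **Differential accumulation** — NB Wald test with median-of-ratios size
  factors, moment/trend dispersion, BH correction, q ≤ 0.05.
* **Translational engagement** — `Δlog2TE` from paired, within-assay
  normalized RNA/RFP counts, permutation p-value (pairing preserved),
  engaged iff `|Δlog2TE| > 0.5`.
* **Enrichment & motifs** — upper-tail hypergeometric enrichment
  P(X ≥ k | s, M, N); TOP-motif classification; assumption-guided test
  selection (Shapiro-Wilk/Levene → t / Wilcoxon / ANOVA+Dunnett /
  Games-Howell / Kruskal-Wallis).

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from tailtop import SimulationConfig, run_differentiation_analysis

summary = run_differentiation_analysis(SimulationConfig(), seed=0)
e = summary.enrichment_60nt
print(f"TOP enrichment among ~60-nt gainers: k={e.k} s={e.s} M={e.M} N={e.N} "
      f"p={e.p_upper:.3g}")
print(f"median decay half-life: TOP {summary.top_median_half_life_min/60:.1f} h, "
      f"non-TOP {summary.nontop_median_half_life_min/60:.1f} h")
print(f"TOP transcripts engaged (|dTE|>0.5): {100*summary.top_engaged_fraction:.0f}%")
```

prints

```
TOP enrichment among ~60-nt gainers: k=86 s=113 M=100 N=979 p=1.72e-83
median decay half-life: TOP 14.5 h, non-TOP 4.9 h
TOP transcripts engaged (|dTE|>0.5): 82%
```

i.e. on a simulated study of 1000 transcripts (10% TOP, 3 replicates) the
pipeline recovers the TOP signature: 86 of the 113 transcripts gaining
~60-nt tails are TOP (hypergeometric p ≈ 2e-83), TOP decay half-lives sit
about 3× above the rest of the transcriptome, and 82% of TOP transcripts
are called translationally engaged.

A CLI mirrors the library (`tailtop simulate | tails | kinetics |
diffacc | translation | enrich | classify-top`); run any command with
`--help`.

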