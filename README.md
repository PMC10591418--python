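# isodyn

Comparative time-course transcriptomics for two groups sampled over a shared
developmental series — built around the design of a two-breed chicken
breast-muscle study (fast-growing broiler `AA` vs. slow-growing indigenous
`LS`, sampled at E10, E14, E18, D1, W1, W3 and W5 with three biological
replicates), but applicable to any two-group, multi-stage, replicated
transcript quantification.

It answers four questions from transcript-level count/FPKM matrices:

1. **Which transcripts drive each group's developmental trajectory?**
   Per group, the log-transformed expression matrix `X` (transcripts x
   samples) is decomposed by SVD, `X = Σ_α λ_α w^α (v^α)ᵀ`; the sample-space
   singular vectors `v^α` are *developmental axes* (smoothed over stages by
   local-quadratic LOESS), `λ_α²/Σλ²` is each axis's variance share, and the
   transcripts with the largest absolute loadings `|w^α|` (top 10%) are its
   contributors. Contributors unique to one group's leading axes are that
   group's *specific* transcripts.
2. **Which transcripts differ between groups at each stage?** A
   negative-binomial GLM (log link, library-size offset, fixed dispersion
   `φ` with variance `μ + φμ²`) with a 1-df likelihood-ratio test per
   transcript; DETs are calls with `|log2FC| > 1` and BH `q < 0.05`.
3. **Which expression profiles differ over the whole course?** The
   two-group quadratic regression
   `y = β0 + β1·t + β2·t² + β3·z + β4·t·z + β5·t²·z + ε`
   (`z` = group indicator, reference group 0) with a global F-test, BH FDR,
   backward term elimination, an R² ≥ 0.6 retention filter, and hierarchical
   clustering of retained profiles into k = 9 characteristic patterns.
4. **Which genes switch their dominant isoform?** Within each multi-isoform
   gene at each group x stage, the isoform significantly above every sibling
   (`log2FC > 1`, `q < 0.05` in pairwise NB tests; or the sole nonzero
   isoform) is *dominant*. Cross-group events are classified as **class I**
   (groups disagree at the same stage) or **class II** (disagreement only
   across stages); within-group timelines of dominance changes are also
   reported.

The integration layer intersects group-specific axis contributors with
stage-wise upregulated DETs, optionally filters by a user-supplied gene→term
annotation (e.g. muscle-development GO terms), and crosses the result with
switch genes in a three-set Venn whose triple intersection is the headline
candidate list. Hypergeometric over-representation, the relative
protein-content formula `2^-(corrected − control mean)` and qPCR
`2^-ΔΔCT` utilities round out the toolkit.

Because the original sequencing data are not required, the package ships a
first-class synthetic-data generator (`isodyn.simulate`) that emulates the
full study design — NB count noise, polynomial gene trajectories, planted
breed x stage effects, planted dominant isoforms and class I/II/within-breed
switch events — together with machine-readable truth tables for recovery
testing.

## Worked example

Generate a seeded dataset and run the whole pipeline:

```sh
isodyn simulate --out fix --seed 7
isodyn run --config pipe.yaml          # pipe.yaml points at fix/*
```

with `pipe.yaml`:

```yaml
inputs:
  counts: fix/counts.tsv
  gtf: fix/ann.gtf
  meta: fix/meta.tsv
  go_map: fix/go_map.tsv
```

Output (the per-stage record counts from the manifest):

```
{
  "axis_specific_transcripts": 105,
  "candidate_genes": 6,
  "class_II_genes": 15,
  "class_I_genes": 15,
  "clusters": 9,
  "det_down": 96,
  "det_up": 178,
  "expressed_genes": 500,
  "expressed_transcripts": 1016,
  "timecourse_retained": 809,
  "timecourse_significant": 967,
  "triple_intersection": 6,
  "variance_top4_AA": 0.943015,
  "variance_top4_LS": 0.944443,
  "within_breed_genes": 55
}
```

Reading: of 1016 expressed transcripts, the top four principal components
capture ~94% of each breed's variance; 105 transcripts are specific to the
AA breed's leading axes; 178 transcripts are upregulated in AA at
post-hatching stages; 15 genes show class-I and 15 class-II dominant-isoform
switches; and the triple intersection of DET genes, switch genes and
term-filtered axis candidates recovers exactly the 6 planted candidate
genes. Each step is equally available as a library call
(`TimecourseModel(...).fit().stepwise().cluster_profiles()`,
`NBTwoGroupModel(...).fit()`, `decompose`/`top_contributors`,
`call_dominant_all`/`classify_switches`, ...) or as the per-step CLI
subcommands `normalize`, `timecourse`, `axis`, `det`, `dominant`,
`switches`.

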