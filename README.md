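# virocell

Tools for asking how well a phage's codon usage matches its host's — and
what that mismatch costs during infection — together with the time-course
transcriptomics machinery needed to watch the takeover happen.

When a lytic phage redirects a bacterium's gene expression (turning the
cell into a *virocell*), every phage protein must be translated by host
ribosomes using host tRNA pools. A phage whose codon usage diverges from
the host's therefore carries a translational handicap. This package
implements:

* **Codon complementarity.** Codon counts, relative frequencies and RSCU
  over a genome's annotated CDS set; the cosine distance

  D_c(phage, host) = 1 − (v_p · v_h)/(‖v_p‖‖v_h‖)

  between the 64-dimensional codon-frequency vectors (0 for identical
  usage); and a per-codon **impact** score: each phage codon frequency is
  substituted by the host's value in turn and the absolute change in D_c,
  Δ_c = |D_c′ − D_c|, attributes the mismatch to individual codons.
  Impact distributions are compared across phage–host panels with pairwise
  t or Wilcoxon rank-sum tests under Holm–Bonferroni adjustment.

* **Virocell transcriptomics.** The post-mapping chain
  counts → FPKM (host and phage strata normalized separately) → log2 →
  per-gene z-score; hierarchical clustering of temporal profiles on
  1 − Pearson r with resampling-based stability and early/middle/late
  stage labels; and infected-fraction-adjusted fold changes: with a
  fraction *f* of cells infected, the virocell signal is deconvolved as
  X_v = (X_I − (1−f)·X_U)/f before log2FC = log2((X_v+1)/(X_U+1)).

* **Global trend models.** Per-sample total counts fit by least squares as
  `counts ~ treatment + time + time² + treatment:time`, with sequential
  nested-model F tests, Bonferroni-corrected simultaneous confidence
  bands, and Tukey (studentized-range) pairwise comparisons of levels and
  linear slopes.

* **Synthetic data with known truth** for every input: genome pairs with
  controlled within-family codon-usage divergence, and replicated
  infected/uninfected negative-binomial count time courses with planted
  temporal clusters, known infected fraction and true fold changes.

`TemporalClusterer` and `TimeTrendModel` are scikit-learn style estimators
(`fit`, `get_params`, trailing-underscore attributes) and compose with
sklearn model selection; everything else is plain functions over Biopython
and pandas containers.

## Worked example

```python
from virocell import synthetic, complementarity

spec = synthetic.GenomeSimSpec(seed=11)               # ~300-CDS host
host = synthetic.synth_host(spec)[:2]
phage, cds, truth = synthetic.synth_phage_from_host(  # divergence delta=0.3
    spec, delta=0.3, seed=1011, host=host
)
res = complementarity.pair_analysis((phage, cds), host)
print(f"D_c = {res.d_c:.4f}")
print(f"GC phage/host = {res.gc_phage:.3f}/{res.gc_host:.3f}")
top = sorted(res.profile.impact, key=res.profile.impact.get, reverse=True)[:6]
print("top-impact codons:", top)
print("planted codons:   ", sorted(truth.shifted_codons))
```

prints

```
D_c = 0.0764
GC phage/host = 0.473/0.438
top-impact codons: ['CTC', 'GCC', 'GGC', 'GTC', 'CGC', 'AGC']
planted codons:    ['AGC', 'CGC', 'CTC', 'GCC', 'GGC', 'GTC']
```

The phage was built from the host's codon profile with six codons' usage
deliberately shifted; the impact ranking recovers exactly those six, and
D_c ≈ 0.07 quantifies the resulting mismatch (a codon-adapted phage pair
generated with `delta=0` gives D_c ≈ 0.001, pure sampling noise).

The same generators drive the expression half end to end:

```bash
virocell synth expression-data --out demo --seed 1
virocell expression --counts demo/counts.tsv --sample-meta demo/sample_meta.tsv \
    --annotation demo/annotation.tsv --out demo/results --f 0 0.95 --f 15 0.95 \
    --f 30 0.95 --f 45 0.95 --f 60 0.95
virocell validate --seed 1   # one-command truth-recovery summary
```

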