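# epistax

Transcriptome-wide epistasis and combinatorial dissection of genetic
interactions from genotype-design RNA-seq.

Classical epistasis analysis asks how the phenotype of a double mutant *AB*
relates to those of the single mutants *A* and *B*. When the phenotype is the
whole transcriptome, every transcript contributes one measurement, and the
relationship can be summarized in a single coefficient. `epistax` implements
that analysis — as used to dissect longevity pathways such as insulin/IGF-1
signaling in *C. elegans*, where perturbations like *daf-2* and *daf-16* are
profiled alone and in combination — together with the surrounding pipeline:
differential expression, cross-dataset batch correction and global
comparisons, gene-set enrichment, RNA-element statistics and consensus
network inference, plus a synthetic-data generator so that every stage is
testable without external sequencing data.

## The epistasis coefficient

For each transcript, let β_A, β_B, β_AB be log2 expression changes of the
three genotypes relative to wild type. Writing x = β_A + β_B (the expected
additive effect) and δ = β_AB − x (the deviation from additivity), the
epistasis coefficient *s* is the slope of the through-origin
orthogonal-distance regression of δ on x over the selected transcripts:

    minimize over m:   Σᵢ (δᵢ − m·xᵢ)² / (1 + m²)

solved in closed form from the stationarity quadratic
m²·Sxy + m·(Sxx − Syy) − Sxy = 0. Its value classifies the interaction:

| s | interaction |
|---|---|
| 0 | additive (independent pathways) |
| −1/2 < s < 0 | branched (partially shared pathway) |
| −1/2 | unbranched (single linear pathway) |
| −1 | repressive (double mutant reverts to wild type) |

Masking regimes (A>B, B>A), where the double mutant resembles one single
mutant, are distinguished by comparing the observed bootstrap distribution
of *s* against distributions simulated under each candidate architecture
from the observed single-mutant effects.

## Worked example

Simulate a repressive interaction (β_AB = 0: the double mutant is
transcriptionally wild type), run the three contrasts, and estimate *s*:

```sh
epistax simulate --model repressive --n-features 500 --noise-sd 0.05 \
    --seed 11 --out data
epistax de --counts data/counts.tsv --meta data/sample_meta.tsv --contrast A:WT  --out de_A.tsv
epistax de --counts data/counts.tsv --meta data/sample_meta.tsv --contrast B:WT  --out de_B.tsv
epistax de --counts data/counts.tsv --meta data/sample_meta.tsv --contrast AB:WT --out de_AB.tsv
epistax epistasis --res-a de_A.tsv --res-b de_B.tsv --res-ab de_AB.tsv \
    --n-boot 1000 --seed 11 --out epistasis.json
```

which prints:

```
147 DEGs at |FC|>2.0, q<0.05 -> de_A.tsv
192 DEGs at |FC|>2.0, q<0.05 -> de_B.tsv
0 DEGs at |FC|>2.0, q<0.05 -> de_AB.tsv
s = -0.986 (95% CI -0.998..-0.975), best model: repressive [n=297]
```

The single mutants each move one to two hundred genes past the fold-change-2
threshold, while the AB-vs-WT contrast finds nothing — exactly the repressive
signature — and the fitted coefficient lands on s ≈ −1 with the repressive
architecture ranked first among the six candidates. The same stages are
available as library calls (`epistax.EpistasisAnalysis`,
`epistax.test_contrast`, ...), and `epistax run` executes the whole pipeline
(simulation → DE → epistasis → integration → enrichment → RNA elements →
network) from one YAML config with a reproducibility manifest.

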