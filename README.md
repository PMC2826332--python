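# mimosa

**Mixture modeling of gene-pair co-expression and modifier-gene detection.**

A transcription factor (TF) and its target gene are often co-expressed only
in a *subset* of the samples of an expression compendium — for instance when
the TF's activity depends on a post-translational modification delivered by
some other enzyme. Global correlation measures average over both regimes and
miss such conditional regulation. `mimosa` addresses this in two steps:

1. **Soft sample partitioning.** For a gene pair with z-scored expression
   values (x_k, y_k) across N_s samples, the observations are modeled as a
   two-component mixture

       p(x, y) = f · p_u(x, y) + (1 − f) · p_c(x, y)

   where p_u is the product of two standard normals (the *uncorrelated*
   samples) and p_c is an elongated Gaussian obtained by rotating an
   axis-aligned Gaussian through θ = ±π/4 with axis variances
   σ_u² = 1 − |α| and σ_v² = 1 + |α| — equivalently, the unit-variance
   bivariate normal with correlation ρ = −α. The mixing fraction
   f ∈ [0, 1] and the aspect parameter α ∈ (−1, 1) (aspect ratio
   r = σ_v/σ_u, |α| = (r² − 1)/(r² + 1); α < 0 ⇔ positive correlation) are
   estimated per pair by direct numerical maximum likelihood. The posterior
   probability that sample k belongs to the correlated group,

       q_k = (1 − f) p_c(x_k, y_k) / [ f p_u(x_k, y_k) + (1 − f) p_c(x_k, y_k) ],

   yields a *soft partition* of the compendium (the q-vector).

2. **Modifier screening.** A candidate modifier is a gene whose expression
   differs between the two groups. Group sizes, means and standard
   deviations are computed as q-weighted sums (n_c = Σ q_k,
   μ_c = Σ q_k z_k / n_c, …), giving a **weighted t-statistic** that needs
   no arbitrary threshold on q; Kendall's τ between q and the candidate's
   expression is the non-parametric alternative for small candidate sets.
   Candidates are ranked by p-value with Bonferroni correction.

The package also ships the synthetic TF–Gene–Modifier benchmark used to
validate the approach (planted threshold-gated partitions), evaluation
utilities (per-bin median rank and top-rank fraction, labeled-partition
Wilcoxon tests, within-TF q-vector coherence), pair-level screening filters
(Kendall-τ prefilter, windows on f̂ and |α̂|), and a log-likelihood-ratio
diagnostic against the nested f = 0 model with a permutation utility.

## Worked example

Generate a small planted benchmark (one bin, f = 0.5, α = 0.8, 10 triplets
of modifier/TF/gene over 300 samples), fit a pair, and screen for its
modifier:

```python
from mimosa import (generate_benchmark, extract_pair, fit_mixture,
                    llr_statistic, partition_probabilities, rank_modifiers,
                    modifier_rank)

matrix, truth = generate_benchmark(f_values=(0.5,), alpha_values=(0.8,),
                                   triplets_per_bin=10, n_samples=300, seed=7)
row = truth.iloc[0]
pair = extract_pair(matrix, row.tf_id, row.gene_id)
fit = fit_mixture(pair)
print(f"f_hat={fit.params.f:.3f}  alpha_hat={fit.params.alpha:.3f}  "
      f"LLR={llr_statistic(fit):.2f}")

q = partition_probabilities(pair, fit.partition_params)
scores = rank_modifiers(q, matrix, exclude={row.tf_id, row.gene_id})
top = scores[0]
print(f"top candidate: {top.gene_id}  t={top.statistic:.2f} "
      f"p={top.p_value:.3g}  p_bonf={top.p_corrected:.3g}")
print("true modifier rank:", modifier_rank(scores, row.modifier_id))
```

Output:

```
f_hat=0.514  alpha_hat=0.794  LLR=14.85
top candidate: b00_t000_M  t=3.54 p=0.000459  p_bonf=0.0128
true modifier rank: 1.0
```

The fitted mixing fraction (0.514) and aspect parameter (0.794) recover the
planted values (0.5, 0.8); the planted modifier `b00_t000_M` ranks first
among the 28 candidates, with a Bonferroni-corrected weighted-t p-value of
0.013.

## Command line

```sh
mimosa simulate  -o sim/                 # benchmark matrix + truth table
mimosa fit       sim/matrix.tsv pairs.tsv -o fits/ --write-q
mimosa scan      sim/matrix.tsv pairs.tsv -o scan/ --method weighted_t
mimosa benchmark -o bench/ --seed 1      # full recovery grid
mimosa evaluate labeled   fits/qvectors.tsv labels.tsv -o eval/
mimosa evaluate coherence fits/qvectors.tsv -o eval/
```

Every run echoes its resolved configuration to `config.json`; `scan` logs
the pair counts after each filter stage.

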