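# paleodrift

Population-genomic analyses for panels of ancient, low-coverage genomes
represented as pseudo-haploid calls: f4-statistics and outgroup
coancestry, a drift-mixture model that decomposes individual genetic
affinities into K ancestry components, a likelihood-ratio test of direct
ancestry from read counts, spatiotemporal isolation-by-distance testing,
Weir–Cockerham F_ST scans, and BioNJ trees with a per-sample goodness-of-fit
diagnostic.  A forward Balding–Nichols simulator generates panels with
known ground truth, so every estimator ships with a validation path.

The package is aimed at researchers analysing ancient-DNA time series
(e.g. domestication or population-turnover studies), where genotypes are
single sampled alleles per site, polarized ancestral/derived against an
outgroup, and sample metadata carry ages (years BP) and coordinates.

## The statistics at the core

For individuals *i*, *j* and an outgroup *O*, the coancestry

&nbsp;&nbsp;&nbsp;&nbsp;c\_ij = E[(p\_i − p\_O)(p\_j − p\_O)]

measures their shared drift since the outgroup split, and equals the
f4-statistic f4(i, O; j, O).  If each individual is a mixture of K
ancestral populations with mixing vector q\_i (rows of Q on the simplex)
and the ancestral populations have pairwise coancestry Ω, then

&nbsp;&nbsp;&nbsp;&nbsp;c\_ij = q\_iᵀ Ω q\_j&nbsp;&nbsp;&nbsp;(i ≠ j),

and every f4 among panel members is a linear combination of such terms.
`paleodrift.structf4` fits (Q, Ω) to the observed coancestry semi-matrix
with an adaptive Metropolis–Hastings sampler, resolving the model's
stochastic-matrix gauge freedom by anchoring at the vertex-spanning
decomposition (see `docs/methods.md`).  The continuity test
(`paleodrift.continuity`) places an ancient specimen either on a direct
line of ancestry to a target population (private drift t2 = 0) or as a
sister group (t2 > 0) and refers 2·(LL\_full − LL\_null) to the
boundary-corrected null ½χ²₀ + ½χ²₁.

## Worked example

`examples/03_ancestry_decomposition.py` simulates 75 individuals (25 per
population plus 25 admixed) from a three-population star, computes the
outgroup coancestry matrix and fits the K = 3 mixture model:

```
log-likelihood of reported state: 23557.7
residual scale sigma: 0.00196
mean |Q_hat - Q_true| after component alignment: 0.0624
estimated ancestry of the first admixed individual vs truth:
  estimate: [0.447 0.168 0.385]
  truth   : [0.492 0.186 0.322]
MDS: first two eigenvalues 0.006, 0.003 (axis 1 separates the most drifted populations)
```

The mean absolute error of the recovered mixing matrix is ~0.06 at this
modest panel size and drops below 0.03 at the 200-individual / 50,000-site
scale used in the tests.  `examples/04_continuity_test.py` shows the
continuity test accepting a true direct ancestor (LRT = 0.00, p = 1) and
rejecting a drifted sister group (LRT = 4.85, p = 0.014 at 2,000 sites),
and `examples/05_isolation_by_distance.py` walks a sliding-window masked
partial-Mantel analysis.

## Layout

- `src/paleodrift/` — the library (`simulate`, `panel`, `io`, `stats`,
  `njtree`, `structf4`, `continuity`, `spacetime`)
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
- `tests/` — pytest suite with brute-force oracles for every estimator
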