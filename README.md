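# finecomp

Fine-scale chromatin compartment, loop, and transcriptional-pausing analysis of
sparse Hi-C contact maps.

## The problem

A/B compartments are the two spatial classes of chromatin read off the sign of
the leading eigenvector of a Hi-C correlation matrix (A ≈ active, B ≈
inactive). Calling them at sub-kilobase bin sizes is blocked by a linear-algebra
wall: for a chromosome binned at 500 bp the contact matrix `X` is sparse, but
its correlation matrix

```
A = YᵀY,   Y⁽ⁱ⁾ = (X⁽ⁱ⁾ − cᵢ) / σᵢ
```

is dense with millions of rows — far too large to form. `finecomp` computes the
top eigenpairs of `A` *implicitly*: since `A x = Yᵀ(Y x)` and
`Y = XS − 1rᵀ` with `S = diag(1/σᵢ)` and `rᵢ = cᵢ/σᵢ`, each matrix–vector
product touches only the nonzeros of `X`. Power iteration gives the leading
eigenpair; deflation (re-orthogonalizing the iterate against all previously
found eigenvectors) gives the next ones; the eigenvector error is bounded by
`‖Av − λ₁v‖ / |λ₁ − λ₂|`. Auxiliary storage stays `O(n + nnz)`.

Before standardization the map can be distance-normalized: observed/expected
(`obs / expected(d)`) or Pearson residuals (`(obs − expected(d)) / √expected(d)`,
the default for compartment calling — it variance-stabilizes Poisson counts and
its distance-only offset is applied as an FFT Toeplitz product, preserving
sparsity).

On top of the eigensolver, the package implements the downstream analyses of
fine-scale compartment maps:

* **compartments** — sign-oriented eigenvector tracks, contiguous compartment
  intervals (≥2 same-sign bins), interval-size statistics, element assignment
  with a stringent B threshold;
* **genes** — concordant (A/A) vs discordant (A/B) genes by TSS/TTS
  compartment, discordance by gene size, TSS-anchored eigenvector profiles and
  their zero-crossing distance, GRO-seq-style pausing indices and
  ranked-difference pausing tertiles;
* **loops** — Manhattan-ring radial profiles around loop anchors,
  center-normalized decay rates (kb per 10% loss; compounding %/kb),
  Simpson's-rule AUC, AUC quintiles (punctate → diffuse), diagonal-decay
  reference;
* **qc** — Boolean coverage fraction, lag-1 autocorrelation noise
  (`(ACF − 1)·(−1)`) of the O/E map, depth sweeps via exact
  without-replacement subsampling;
* **simulate** — synthetic plaid maps, loop fields, and gene sets with planted
  ground truth, so every analysis is testable without external data.

It is aimed at genomicists who want compartment calls at kilobase scale from
sparse contact data, and at method developers who need a reference
implementation with a fully synthetic, seeded test harness.

## Worked example

```sh
python examples/01_compartments_from_synthetic_map.py
```

```
map: 2000 bins, 499441 contacts, 229171 nonzero bin pairs
lambda_1 = 18120.6, converged in 23 iterations, residual 1.64e-04
sign agreement with planted labels: 99.2%
54 compartment intervals, median size 14.0 kb
```

A 1-Mb synthetic chromosome (2,000 bins × 500 bp) with planted 2–50 kb
compartment intervals and 5×10⁵ Poisson contacts is generated; the implicit
eigensolver converges in 23 products; the oriented eigenvector sign matches the
planted compartment on 99.2% of bins, and the called intervals have a median
size of 14 kb (the planted median for this seed). The other example scripts
cover loop radial decay (`02`), discordant genes and pausing (`03`), and depth/
noise QC (`04`).

The same analyses are available as a CLI for file-based workflows:

```sh
finecomp simulate plaid --out-dir sim --seed 1
finecomp eigenvector --contacts sim/contacts.txt --bin-size 500 --out-prefix eig
finecomp compartments --eigen-bedgraph eig.pc1.bedGraph --bin-size 500 \
    --n-bins 2000 --out-prefix comp
```

Every command writes a JSON provenance sidecar (parameters, seed, input
checksums).

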