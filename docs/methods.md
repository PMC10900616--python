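# Methods

This note documents the model implemented by `lspaint`, the numerical
choices that make it reproducible, the design decisions taken where the
design was genuinely open, and what the synthetic fixtures do and do not
establish about real data.

## The copying model

For a panel of N phased haplotypes observed at L biallelic variants, each
haplotype *i* (the *recipient*) is modelled by an independent HMM whose
hidden state Xᵢˡ ∈ {1..N}\{i} is the *donor* haplotype it copies at variant
l. The pieces are:

- **Emission.** Symmetric model: probability 1−μˡ of emitting the donor's
  allele, μˡ of the other allele. μ is proportional to the local mutation
  rate; it may be a scalar or a length-L vector and must lie strictly in
  (0, 1) — at the endpoints the log-distances of the decoding stage
  degenerate, so those values are rejected at construction.
- **Derived-allele (Relate-style) emission**, behind `use_speidel=True`:
  match → 1−μ; recipient derived (1) vs donor ancestral (0) → μ; recipient
  ancestral vs donor derived → 1. The intent is that a donor carrying a
  derived allele is not penalised against an ancestral recipient. The
  published description of that copying model does not print its kernel, so
  this kernel is this package's documented stand-in: anyone requiring
  numerical agreement with Relate's output must validate it against that
  tool before relying on cross-tool comparisons.
- **Transition.** Between consecutive variants the donor is retained with
  probability 1−ρˡ, and with probability ρˡ is resampled from the prior
  column Π·ᵢ (so a "switch" may re-select the same donor). Π is
  left-stochastic with Πᵢᵢ = 0; the uniform prior (1/(N−1) off-diagonal) is
  represented by a marker and never materialised.
- **Map.** ρˡ = 1 − exp(−Nₑ·(mˡ)^γ) from per-interval distances mˡ in
  Morgans, evaluated as `-expm1(-Ne * m**gamma)` so that switch
  probabilities remain accurate down to arbitrarily short intervals. Nₑ is
  the *scaled* quantity consumed directly by this formula; the helper
  `scaled_ne` converts a diploid effective size via Nₑ = 4·Ñₑ/N. γ defaults
  to 1; γ > 1 sharpens recombination-map peaks, γ < 1 flattens them. ρ is
  stored as a length-L vector whose final entry is a sentinel 1.0: only L−1
  intervals exist, and no recursion ever reads the last slot. ρ = 0
  (no switching) and ρ = 1 (full reset to the prior) are both legal
  pointwise.

## Rescaled recursions

The textbook forward/backward quantities α̃ˡ = P(Xˡ=j, h¹:ˡ) and
β̃ˡ = P(hˡ⁺¹:L | Xˡ=j) underflow on long chromosomes. Defining the scaling
sums Fˡ = Σⱼ α̃ⱼˡ (F⁰ := 1) and Gˡ = Σⱼ β̃ⱼˡ⁺¹ θⱼˡ⁺¹ Πⱼᵢ (G^L := 1), the
package propagates the rescaled columns αˡ = α̃ˡ/Fˡ⁻¹ and βˡ = β̃ˡ/Gˡ:

    α¹ = θ¹ ⊙ Π·ᵢ
    αˡ = θˡ ⊙ ((1−ρˡ⁻¹)·αˡ⁻¹/Σⱼαⱼˡ⁻¹ + ρˡ⁻¹·Π·ᵢ)        l > 1
    β^L = 1
    βˡ = (1−ρˡ)·(βˡ⁺¹⊙θˡ⁺¹)/Σⱼ βⱼˡ⁺¹θⱼˡ⁺¹Πⱼᵢ + ρˡ        l < L

Each rescaled column stays at unit scale, so no per-step clamping is
applied anywhere in the recursions; all underflow handling is deferred to
the decoding stage. Forward tables only move towards larger variant
indices, backward tables towards smaller ones; violating either direction
is an error, as is propagating a table under a parameter set whose SHA-256
content hash differs from the one it was initialised with.

Stored metadata follows the table layout of the field's engines: the
rescaled matrix, the latest scaling sums (`alpha_f`/`beta_g` hold the
*pre-normalisation column sums*, i.e. the ratios Fˡ/Fˡ⁻¹ and the step
denominators Gˡ/Gˡ⁺¹ — the running products reconstruct F and G when
needed), the current variant, the recipient slice bounds, and the parameter
hash. A backward table can be left in *rescaled space* (`beta_theta=True`),
in which the stored matrix additionally carries the current variant's
emission factor; a later propagation first completes the pending step from
that space, and decoding completes it on an internal copy.

### Self-copying mask

Πᵢᵢ = 0 keeps the forward diagonal analytically zero, but the backward
recursion's `+ρ` term would leave βᵢᵢ > 0. Both tables explicitly hold the
diagonal entry of each recipient column at 0 after every step, for
symmetry; no normalising sum is affected because every sum involving Π
already excludes j = i.

### Bit-exactness

Three properties are guaranteed exactly, not to tolerance:

1. propagating k variants in one call equals k single-variant calls;
2. a recipient-slice table equals the matching columns of a full-panel
   table;
3. results are independent of the worker count.

(1) holds because multi-step propagation literally iterates the
single-step code with a fixed evaluation order (previous column sum, then
normalise, decay, add switch mass, then the emission product — implemented
in place, preserving that per-element order). (3) holds because workers
partition recipient columns, which never interact. (2) required one
numerical decision: library reductions (`ndarray.sum`, `einsum`) choose
SIMD paths and association orders that depend on the array's width and
layout, so column sums inside the recursions use a fixed pairwise tree over
rows (`_colsums`) whose associativity depends only on N. Summation accuracy
is comparable to pairwise library summation.

## Decoding

pˡ·ᵢ = (α·ᵢ ⊙ β·ᵢ)/Σⱼ αⱼᵢβⱼᵢ. If the denominator is exactly 0 — possible
when the forward and backward supports of a recipient have become disjoint
through underflow to exact zeros — every off-diagonal entry of that column
is set to ε = double machine epsilon (≈2.22×10⁻¹⁶), the smallest observable
posterior, and pᵢᵢ stays 0 (never ε).

Distances: dⱼᵢ = −(log(pⱼᵢ ∨ ε) + log(pᵢⱼ ∨ ε))/2 for j ≠ i, dᵢᵢ = 0. The
clamp floor is a parameter (`clamp_eps`) defaulting to ε so the standard
behaviour is the default but remains testable at other floors. No distance
can exceed −log ε ≈ 36.04. Distances require full-panel tables because
symmetrisation needs both (j,i) and (i,j).

Standardisation centres and scales each column by the mean and *sample*
(n−1) standard deviation of its **off-diagonal** entries; a column with
zero off-diagonal spread becomes all zeros, the diagonal stays 0, and
standardising twice is rejected via a flag. Whether the field's engines
standardise over all entries or off-diagonal only is not published;
off-diagonal-only is this package's choice (the diagonal is a convention,
not a distance) and is flagged here deliberately.

## Haplotype cache

Variant-major, bit-packed: variant l's N alleles occupy ⌈N/32⌉ little-endian
32-bit words, padded to the next multiple of 8 words (a 32-byte row
boundary, retained as a layout contract from the SIMD-oriented design this
layout comes from, although this implementation does not issue vector
intrinsics). All pad bits are zeroed so whole-word row operations are safe
and testable. Inputs are validated strictly: only 0/1 alleles (no missing
data — the model is undefined for it, and imputing silently would be
worse), N ≥ 2 (a single haplotype has no donors), consistent row lengths.
Internal indexing is 0-based half-open; file formats and the CLI speak
1-based variant indices, converted at the boundary.

The HDF5 container layout is package-defined (dataset `haps`, L×N int8,
attributes `N`, `L`, with a transposed orientation accepted behind a flag):
it is a documented stand-in, not an interchange format with other tools.

## Parameters object

Immutable after construction (arrays are write-protected), carrying a
SHA-256 digest over a canonical little-endian serialisation: model-flag
byte, L, N as int64, ρ doubles, a scalar/vector marker byte + μ doubles, a
uniform/matrix marker byte + Π doubles. Fixing the byte layout makes hashes
portable across platforms and sensitive to 1-ulp changes in any entry,
which is what lets tables refuse propagation under a changed parameter set.

## Reference oracle (tests only)

A separate module re-derives everything independently for the test suite:
literal unscaled recursions with their F/G sums (valid while the unscaled
probabilities stay above the double-precision floor; tests back off to
shorter targets when a column underflows to exact zero, which the oracle
reports as an error rather than silently returning zeros), an independent
re-derivation of the rescaled recursions, and an exhaustive posterior that
enumerates all (N−1)^L hidden paths (guarded at 10⁶ paths). The oracle
shares no arithmetic helper with the optimised path; its emission kernel is
written out case by case on purpose.

## Synthetic data

`simulate_panel` draws founders i.i.d. Bernoulli(0.5) per site (redrawing
until at least one site segregates) and generates each additional haplotype
by the copying process itself over the founders — donor path from the
ρ/Π law, emissions flipped with probability μ — retaining the true paths.
Copies draw donors among the founders only, because a copy cannot copy
from a haplotype that does not yet exist; with a matrix prior, the column
is restricted to founder rows and renormalised.

This fixture has full allelic diversity and no linkage structure beyond
what copying induces; it is deliberately *not* a coalescent simulation.
Consequently, passing tests establish the correctness of the inference
machinery under the model's own generative law — they do not establish
calibration on real genomes, where allele frequencies, LD and marker
ascertainment differ.

## Validation quantities and problem sizes

The acceptance script and test suite compute, at sizes chosen to keep a
laptop-scale run comfortable:

- **Gold-master sweep**: 200 random instances spanning N ∈ 3..40,
  L ∈ 1..64, random exponential maps, scalar and vector μ, uniform and
  Dirichlet-random Π, both emission models; rescaled tables must match the
  unscaled reference through the scaling identities to ≤1e-10 relative at
  every variant (measured ~1e-15), and posteriors must match exhaustive
  enumeration to ≤1e-10 absolute wherever (N−1)^L ≤ 10⁶.
- **Cost exponents**: log–log regression of per-variant full-table
  propagation time over N ∈ {250, 500, 1000, 2000} (slope ≈ 2) and of
  total time over L ∈ {64, 128, 256, 512} at N = 500 (slope ≈ 1), with
  warm-up passes and best-of-repeats timing to damp allocator and cache
  noise. These verify the expected O(N²)/O(L) scaling shape, not absolute
  speed.
- **Degenerate instance**: N = 3, L = 8, ρ ≡ 0, μ = 10⁻¹²⁰, with one donor
  matching the recipient only upstream and the other only downstream of the
  decoding variant; because the rescaled forward recursion normalises by
  the total column sum, the trailing donor underflows to exact zero within
  three mismatches, forcing Σ α⊙β = 0 and exercising the all-ε rule and the
  −log ε distance ceiling.
- **Donor recovery**: a 5-founder/10-copy panel at L = 60, μ = 10⁻³,
  ρ = 0.02; the posterior argmax must identify the generating donor (or a
  founder with an identical sequence — distinct founders can coincide over
  short windows) at a majority of sampled (recipient, variant) pairs;
  measured ≈0.9–1.0.

## Known limitations

- No missing data, multiallelic sites, or unphased genotypes.
- No Viterbi paths or path sampling; decodings are marginal posteriors.
- No estimation of μ, ρ, Π from data; they are inputs.
- Worker parallelism is thread-based column chunking; it guarantees
  determinism but, this being Python/NumPy, yields limited wall-clock gain.
- The derived-allele emission kernel is a documented stand-in (above).
- The simulator is a fixture generator, not a population-genetics model.
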