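# Methods

## The reference-ratio construction

Let q(x) be a probability distribution over fine-grained conformations x
(here: per-residue backbone dihedrals plus hidden basin states) and c(x) a
deterministic coarse-grained map (radius of gyration, or the 8-integer
hydrogen-bond descriptor). q induces a marginal f(c) over the coarse
variable. Given a desired target g(c), the distribution

    p(x) ∝ q(x) · g(c(x)) / f(c(x))

has coarse marginal exactly g while leaving the conditional distribution of
x given c untouched. The division by f removes the information about c that
q already carries; omitting it (the naive product q·g) biases the marginal
towards regions where f is large. Metropolis–Hastings sampling of p with a
proposal that leaves q invariant needs only the coarse-level ratio in its
acceptance probability; the package exploits this throughout.

All claims are validated two ways: exactly, on a fully enumerable discrete
toy chain (`toy` module; K^L ≤ 2²⁰ paths are summed directly), and
statistically, on protein chains.

## The local model q

A transparent first-order Markov chain over five Ramachandran basins
(helix H, strand E, PPII-like coil, left-handed, extended coil), each with a
centre (mean φ, mean ψ) and an angular spread; emissions are independent
wrapped normals per angle (wrap sum truncated at ±3 periods — error is
negligible for spreads below ~60°). Sequence conditioning uses four residue
classes (generic, glycine, proline, pre-proline) that select the transition
row used when entering a residue. The default parameters
(`data/local_model.yaml`) use literature-typical basin centres and persistent
helix/strand states; they were fixed once when the model was written, and any
YAML file with the same schema can replace them. The model deliberately
plays the role a trained local-structure model or fragment library would
play in practice: plausible local geometry, no non-local information. Under
these defaults the 76-residue ubiquitin chain has an Rg distribution centred
near 32 Å with standard deviation ≈ 8.6 Å.

The proposal used in every sampler is conditional window resampling: a
window of residues (length uniform on a configured range, position uniform)
is redrawn from the exact conditional distribution of the Markov chain given
the flanking states (backward messages, forward sampling), with fresh
emissions. Because the window is drawn from q's exact conditional, the move
has unit Hastings ratio with respect to q, so the fine-grained terms cancel
in the acceptance probability. The default window range is 1–10 residues;
the Rg application uses 1–20, since Rg is a global quantity and larger
windows decorrelate it faster (integrated autocorrelation time of Rg ≈ 11
steps at 1–20 on ubiquitin).

## Geometry

Coordinates are built by sequential internal-coordinate (NeRF) chain
extension with fixed ideal geometry (Engh–Huber-like: N–CA 1.458 Å, CA–C
1.525 Å, C–N 1.329 Å, C=O 1.231 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA
121.7°; ω = 180°). Dihedrals follow the IUPAC sign convention (verified
against Bio.PDB's `calc_dihedral`). Each non-glycine residue carries one
side-chain pseudo-atom at the ideal Cβ position (improper C–N–CA–Cβ =
+122.9°, derived from the CORN rule for L-amino acids; for alanine this *is*
the true Cβ); it is written to PDB as "CB". The carbonyl O of residue i is
placed trans to N(i+1) (torsion ψᵢ+180°); the C-terminal O uses torsion 180°
by convention. The undefined terminal angles φ(1) and ψ(L) are NaN sentinels
and never enter construction. Radius of gyration is computed over all
emitted atoms, unweighted; the selection is configurable.

## Hydrogen bonds and the 8-category descriptor

The representation carries no hydrogens, so a bond is defined on heavy
atoms: donor N(i) to acceptor carbonyl O(j) with N···O < 3.5 Å (a cutoff
appropriate for the N···O distance), angles C(j)–O(j)···N(i) and
O(j)···N(i)–CA(i) both > 100°, and |i−j| ≥ 2 (adjacent-residue contacts are
trivial and excluded). Each carbonyl accepts at most one bond; among
competing donors the smallest distance wins. An ideal α-helix built from
(φ,ψ) = (−63°,−43°) produces exactly the canonical O(i)···N(i+4) ladder at
3.04 Å.

Each residue is assigned to one of eight categories by the bonding state of
its carbonyl: unbonded residues count as s_H/s_E/s_C by their own
secondary-structure label (labels come from the local model's basin states,
not from coordinates), bonded residues as b_HH/b_EE/b_CC/b_HC/b_EC by the
unordered label pair of the two partners. Counting per-residue-at-the-
carbonyl makes the eight integers a partition of the chain length, which the
multinomial target requires. The H–E partner pair, which the five bonded
categories do not name, is tallied with E–C; it is rare in practice.

The native-like protein-G target counts shipped as the default fixture are
**synthetic**: they are derived from the idealized protein-G topology (one
α-helix against a four-stranded mixed sheet; helix i→i+4 bonds, antiparallel
registers for the two hairpins, a parallel register between the terminal
strands, a few capping contacts) by the same categorization rules. Building
the strands from ideal dihedrals alone cannot pair them in space, so
geometric detection on such a conformation would yield a target without any
strand-strand bonds and defeat the purpose of the application; the
topology-derived counts (4, 9, 11, 10, 16, 2, 2, 2) preserve the essential
feature — a substantial E–E fraction that the local model almost never
produces spontaneously. Counts measured on any real structure may be
supplied instead.

## Estimating the reference

**Rg (continuous):** f is estimated on a fixed grid (default 0.08 Å bins on
[19, 31] Å, chosen to cover the target support generously while lying inside
the local model's range) by Wang–Landau-style flat-histogram MCMC: per-bin
log-weights S grow by a modification increment δ on every visit, sampling
with weights e⁻ˢ; δ is halved each stage (10 stages × 20 000 steps by
default, δ₀ = 1). A final refinement stage (400 000 steps) runs with frozen
weights and recovers f ∝ H·eˢ by histogram reweighting, which is unbiased
regardless of residual weight error. The chain is confined to the grid
window (moves that would leave it are rejected; a chain starting outside
drifts in before estimation begins). Bins never visited are floored at mass
10⁻⁸ before normalization so ratios stay finite. Flatness of the final
histogram (min/mean over visited bins, ≥ 0.8 at default settings) and any
unvisited-bin warning are recorded in the histogram's metadata. Normalization
is only defined on the window, which suffices: constant factors in f cancel
in acceptance ratios. The same estimator, validated against exact
enumeration on the toy chain, is accurate to ~1% per bin at the budgets the
tests use.

**Hydrogen-bond descriptor (discrete, high-dimensional):** f cannot be
tabulated, so it is approximated within the multinomial family and refined
iteratively. Iteration 1 samples the plain product q·g (uniform reference).
After iteration n, a multinomial f_n is fitted by pseudocounted maximum
likelihood (pseudocount 0.5 per category — the strand-strand category is
extremely sparse under q and must never be assigned probability zero) to the
pooled samples, and the accumulated log-reference is updated by a damped,
clipped stochastic-approximation step:

    log R_n = log R_{n−1} + (1/n) · clip(log(f_n / g), ±1.2),   R_0 uniform

Iteration n+1 then samples q·g/R_n. At the fixed point the sampled category
fractions equal the target and R stops moving. The damping and clipping are
essential, not cosmetic: because the ratio acts per residue, the descriptor
responds to any net per-category tilt with winner-take-all composition
swings (≈ 50 residues × tilt), and the undamped update — whose idealized
iteration map has Jacobian eigenvalue −1 — oscillates between all-helix and
all-sheet populations instead of converging. Two further stabilizers, both
validated empirically against the alternatives: the sampling within each
iteration uses a population of independent chains (default 25) rather than
one long chain, and chains are warm-started from their previous iteration's
final state, so secondary structure formed early persists and is refined
rather than rebuilt. With the default budget (150 000 steps per iteration,
six iterations, protein G), the total-variation distance between sampled
category fractions and the target falls from ≈ 0.26 to ≈ 0.10–0.15, and the
strand-strand fraction rises from ≈ 0.05 to ≈ 0.20–0.25, across seeds.

The per-iteration "best structure" is the thinned sample maximizing
log q(x) + log g(c) − log R(c), the quantity the sampler targets.

## Numerical and design choices

- **Gaussian target defaults** (mean 24 Å, sd 1 Å for the Rg application):
  any choice is valid — the target is an external modelling input — and the
  default deliberately sits several Å below the local model's own mean so
  the reference correction has something visible to do.
- **KL divergences** are reported in bits on the reference grid, target
  discretized by CDF differences, empirical histograms floored at 10⁻⁸
  relative mass in empty bins.
- **Burn-in** 10% of steps, then thinning (default every 10th step). Both
  configurable; the iterative refinement uses 40% per chain segment because
  segments are short and warm-started.
- **Bins are half-open** [lo, hi); a value on a shared edge belongs to the
  right bin. Out-of-support values get a log-density one ln 10 below the
  smallest in-support bin.
- **Acceptance arithmetic**: log-ratios of +-inf (impossible states under a
  zero-probability category) resolve by preferring the state the target
  permits; NaN differences never propagate into chain state.
- **Determinism**: every sampler threads a single numpy Generator seeded
  from the run seed; identical (config, seed) gives byte-identical
  artifacts. The Rg sampler has a block-stepping compiled fast path
  (numba) that pre-draws its randomness per block; it samples the same
  chain law as the generic driver (cross-checked statistically in the
  tests) but consumes the random stream differently, so traces from the
  two paths match in distribution, not sample-by-sample.
- **Problem sizes**: the shipped test and demo budgets (1.2×10⁷ MH steps
  for the ubiquitin Rg run, ≈ 1.1×10⁶ retained samples; 6 × 1.5×10⁵ steps
  for protein-G refinement; 2×10⁶ refinement steps for toy flat-histogram
  checks) are the package's desk-scale defaults; all scale linearly.

## What the synthetic setting does and does not show

The local model is a stand-in with realistic basin geometry but far less
sequence specificity than a trained model; the protein-G target counts are
topology-derived, not measured from the crystal structure. Passing tests
therefore demonstrate the *method* — exact marginal control given the true
reference, accurate reference estimation, funnel sculpting — on faithful
miniature conditions, not the predictive quality of any particular energy
function on real proteins. Conclusions that depend on the detailed shape of a
trained local-structure model (e.g. the exact uncorrected-sampling bias, or
how sparse β-sheets are under q) transfer qualitatively, not numerically.

Known limitations: side chains are a single pseudo-atom, so steric exclusion
is nearly absent and compact conformations are more accessible than in real
chains; the H-bond criterion has no explicit hydrogen; the multinomial
family cannot represent correlations between descriptor categories, which is
precisely why the iterative scheme is needed and why its fixed point is an
approximation within that family.
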