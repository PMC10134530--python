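# Methods

## The model

### Duplicate-fate process

Each pillar (ancestral post-WGD locus) evolves independently down the rooted
species tree of the n polyploid genomes. The root is the WGD event itself;
the branch above the first divergence (the "stem") is part of the model. The
locus state follows a 4-state continuous-time Markov chain with state order
(U, F, S1, S2):

* `U` — undifferentiated duplicate pair (both copies present, fate unresolved);
* `F` — fixed duplicate pair (both copies preserved); absorbing;
* `S1` — subgenome-2 copy lost, subgenome-1 copy survives; absorbing;
* `S2` — subgenome-1 copy lost, subgenome-2 copy survives; absorbing.

Rates out of `U`: φ to `F`, 1 to `S1`, ε to `S2`. Fixing the U→S1 rate at 1
is the scale convention that makes branch lengths identifiable: lengths are
expected duplicate-resolution events per gene, not substitutions. ε ∈ [0, 1]
is the biased-fractionation parameter; ε < 1 means subgenome-1 copies are
lost more rarely, so subgenome 1 ends up less fractionated. φ and ε are
global across branches (the simplest identifiable variant; per-branch rates
are out of scope). With total exit rate R = φ + 1 + ε the transition
probabilities have the closed form

    P(U→U) = e^{-Rt},   P(U→X) = (q_X / R)(1 - e^{-Rt})  for X in {F, S1, S2}

with q_F = φ, q_S1 = 1, q_S2 = ε, and identity rows for the absorbing
states. The implementation uses this closed form; tests verify it against a
generic matrix exponential to 1e-10 and check Chapman–Kolmogorov
composition.

### Emissions: pillar likelihoods

An orthology configuration assigns, per genome, the two physical tracks of
the pillar to the two subgenomes (IDENTITY or SWAPPED; 2^n configurations in
total). Given a configuration, a genome's slot pattern becomes one of four
tip observations with conditional likelihood vectors over (U, F, S1, S2):
both genes (1,1,0,0); a single gene on subgenome 1 (0,0,1,0); on subgenome 2
(0,0,0,1); genome absent from the pillar (1,1,1,1). Absence is treated as
missing data, not as evidence of double loss — the chain has no double-loss
state, and pillars are by construction observed in at least one genome.

The pillar likelihood under a configuration is the Felsenstein pruning sum
over internal states, with the root in state `U` with probability 1 and the
stem transition applied before the first split. Internally the pruning runs
in linear space with per-node rescaling and an accumulated log scale
(4-state partials never underflow between nodes; the scale capture makes
whole-pillar products safe for any n ≤ 12), vectorized jointly over unique
presence patterns and all configurations. Two exact symmetries are tested:
at ε = 1, a configuration and its global complement have equal likelihood;
for general ε, complementing the configuration is equivalent to exchanging
the roles of S1 and S2.

### The tracking HMM

The hidden state at pillar p is the orthology configuration. Between
adjacent pillars each genome's assignment flips with probability s,
independently across genomes, so the transition kernel is
T[c, c'] = s^h (1-s)^(n-h) with h the Hamming distance between
configuration bitmasks. s is shared across genomes and pillars — the
simplest synteny-persistence model. The chain restarts from the uniform
distribution at every ancestral-block boundary: tracking cannot persist
across block breaks, and blocks are statistically independent.

Decoding is standard scaled forward–backward (posteriors and total
log-likelihood) plus Viterbi in log space, both respecting block resets.
Viterbi ties break deterministically toward the smaller configuration index.
The reported per-pillar confidence is the posterior mass of the Viterbi
configuration at that pillar — the probability of the displayed orthology
relationship conditional on the entire pillar set; displays round it to one
decimal. Both decodes are validated against exhaustive path enumeration to
1e-8 on small instances. Degenerate numerical corners (a pillar whose
likelihood underflows to zero under every configuration at extreme
parameters, or an impossible switch under s = 0) return a total
log-likelihood of −∞ rather than propagating NaNs; the backward pass
rescales freely per pillar, which is harmless because posteriors are
normalized per pillar.

## Estimation

The total HMM log-likelihood is maximized over all branch lengths (including
the stem), φ, ε and s with L-BFGS-B. Branch lengths and φ are optimized in
log coordinates; ε and s on their natural bounded scales. Bounds: lengths
and their log-transforms over [1e-6, 20], φ over [1e-6, 50], ε over
[1e-4, 1], s over [0, 0.4999]. Initialization: all lengths 0.2, φ = 0.5,
ε = 0.8, s = 0.01; by default 3 restarts with seeded Gaussian jitter (σ =
0.3 in transformed coordinates) keep the best optimum; convergence tolerance
1e-6 in relative log-likelihood. Pillars are collapsed to unique
presence/absence patterns for the pruning step (the emission depends only on
the pattern), which makes each objective evaluation cheap even for thousands
of pillars.

The biased-fractionation test refits with ε fixed at 1 and refers
2(lnL_free − lnL_{ε=1}) to χ² with 1 df. Because the free model nests the
constrained one, a free fit that lands below the constrained optimum is
restarted from the constrained solution before the statistic is formed;
statistics more negative than −1e-4 after that raise an optimizer-failure
error. Note that ε = 1 lies on the boundary of the parameter space, so under
the null the statistic follows the ½χ²₀ + ½χ²₁ mixture and the nominal-5%
χ²₁ test is conservative (observed size ≈ 2.5–3% in the calibration runs the
acceptance script reproduces).

An ε profile utility evaluates the log-likelihood on an ε grid with the
other parameters held at their joint MLEs (a slice through the optimum, used
as a convexity/diagnostic check, not a profile likelihood in the
confidence-interval sense).

## The simulator

The generator makes the assumed model executable: per pillar it samples the
fate chain down the tree from `U` (using the same closed-form transition
matrices), and per genome an independent track-labeling chain along the
pillar order (fair-coin start per block, flip probability s per step).
Surviving genes are placed into track slots per the true labeling; dummy
in-frame CDS (ATG + 98 random non-stop codons + TAA, 300 nt) and
coordinate tables (genes laid on per-block, per-track chromosomes with fixed
spacing) exercise the I/O paths. `fraction_missing` blanks whole genome
entries of random pillars to exercise missing-data handling, never leaving a
pillar empty. Everything derives from one integer seed; reruns are
byte-identical.

Default generating conditions (four genomes, all branches and stem 0.3,
φ = 0.5, ε = 0.8, s = 0.02, five blocks) represent a moderately fractionated
tetraploidy in which roughly a third of loci stay duplicated per lineage and
tracking switches are rare; validation scenarios vary ε (0.3 for recovery,
0.5 for decoding accuracy, 1.0 for null calibration) with sizes of 500–5,000
pillars chosen so the full suite runs in minutes on one CPU.

What the simulator deliberately omits — and therefore what passing tests do
not establish about real genomes: tandem duplication, single-gene
translocations, pillar-order error from assembly fragmentation, loss-rate
variation among loci and branches, and any correlation of losses along a
chromosome (the model assumes independent losses given the configuration
chain). On real data these violations surface as depressed confidences
rather than as detected model misfit.

## Validation results the test suite recomputes

* Pruning likelihoods match exhaustive state enumeration (≤ 3-tip trees) to
  1e-10; the closed-form transition matrix matches `expm` to 1e-10.
* Forward–backward and Viterbi match exhaustive path enumeration (2 genomes,
  ≤ 5 pillars, random emissions and switch rates) to 1e-8.
* Parameter recovery: at 2,000 pillars × 4 genomes, ε = 0.3 is recovered
  within [0.2, 0.4] and the bias LRT rejects in ≥ 90% of 20 replicates; the
  null rejection rate over 200 ε = 1 replicates stays below 10% (see the
  boundary note above).
* Decoding: ≥ 90% exact-configuration accuracy in the moderate regime;
  binned confidence matches empirical accuracy within ±0.1 at 5,000 pillars.

## Known limitations

* **Switch-position ambiguity.** When a genuine tracking switch borders a
  single-copy pillar, the data cannot pin the switch to one side: the only
  signal at the boundary pillar is the bias factor 1/ε. The decoder may
  confidently place the switch one pillar off, and a confident single-copy
  "ortholog" set can then contain a true reciprocal loss. The truth-based
  zero-reciprocal-loss contract is therefore tested on switch-free
  simulations, where it holds exactly; with switches it holds up to this
  boundary effect (order one leaked pillar per few hundred selected, at
  s = 0.02).
* The gene-tree branch lengths attached to batch products are the fitted
  loss-model lengths — event scale, not substitution scale.
* Hexaploidies (three subgenomes), per-branch ε, and rate variation among
  pillars are out of scope; n is capped at 12 genomes (4,096 configurations)
  with a warning above 8.
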