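# Methods

## Model

Nucleotide substitution follows the general time-reversible model with
invariable sites and discrete-gamma rate variation (GTR+I+Γ). The rate matrix
has off-diagonals `q_ij = s_ij π_j` for six exchangeabilities `s` (order AC,
AG, AT, CG, CT, GT) and stationary frequencies `π`; it is normalised so that
`−Σ_i π_i q_ii = 1`, making branch lengths expected substitutions per site.
Gamma rate categories are the means of `n_cat` equal-probability slices of
Gamma(α, α) (mean-of-slices, the MrBayes convention; medians would be the
other defensible choice), computed from the incomplete-gamma identity rather
than by quadrature. `n_cat` defaults to 4 — the value baked into the storage
accounting, where one site's conditional-likelihood block is 16 floats and one
branch's transition block 64 — but is configurable. The invariable-site class
is *not* folded into the category rates; it enters only in the final root
combination, so the gamma mixture always has mean rate 1.

Transition probabilities are computed by eigendecomposition of the symmetrised
matrix `diag(√π) Q diag(1/√π)` (exact for reversible Q); `t = 0` returns the
identity exactly, which makes degenerate zero-length-branch cases (conflicting
states across a zero-length cherry → likelihood 0) exact rather than
round-off-sized.

## Data representation

Alignments are encoded as 4-bit state masks (A=1, C=2, G=4, T=8; IUPAC
ambiguity codes are unions; `-` and `?` are treated as fully ambiguous, mask
15 — the standard likelihood convention, chosen because nothing in the
pipeline distinguishes the two) and compressed to unique site patterns with
multiplicities, in first-occurrence order for reproducibility. All likelihood
work is per-pattern and weighted, which the tests tie back to the
uncompressed computation.

## Fused single-pass evaluation

One postorder pass visits each internal node exactly once. Down nodes
(internal non-root, two children) are classified `down_x`,
`x = left-is-leaf + 2·right-is-leaf` — the left/right assignment for x∈{1,2}
is a fixed convention required for deterministic dispatch — and a scaler
shortcut `T = 2S + N` is computed from the node's scalersSet flag S (an old
stored scaler must be removed) and scalerNode mark N (a new scaler must be
computed). The `(x, T)` pair selects one of 16 specialised variants; variants
with `T = 0` contain no scaler code at all, so no per-site flag branching
happens inside a pass.

Within a variant, a terminal child's transition block is transformed into an
ambiguity-summed *prelike* table in-pass (only for masks actually present in
that child's column) and consumed immediately — never written to a persistent
intermediate store; an internal child contributes through its cached
conditional-likelihood buffer. Rescaling is fused into the same pass: the old
scaler is divided out of lnScaler, the new per-site scaler is the maximum of
the site's 16-value block, the block is divided through, and the flag
switches are queued and committed only after the node's pass completes
(deferred semantics; an `immediate` mode exists solely so tests can show the
two orderings give identical results now and on the next pass).

The root combination corrects the invariable-site term by `exp(−lnScaler)` so
scaled and unscaled evaluations agree; it is evaluated through `logaddexp`, so
a large accumulated scaler cannot overflow the correction. Conditional
likelihoods stay in the linear domain with per-site multiplicative scalers
(not log-domain), which is what makes the transfer accounting of the
reference pipeline meaningful. Old scalers are stored per scaler node so that
removal on a revisit is exact.

Two layouts evaluate the same inner products in different orders:
`state_major` computes each of the 16 per-site elements in its own sweep over
sites; `site_major` computes whole per-site blocks (batched matrix products).
`auto` selects `state_major` below 512 unique sites — the threshold is a
configuration knob with this documented default, since the choice only
affects speed, never values (tested to 1e-12 relative).

## Multipass reference pipeline and transfer ledger

The reference pipeline computes the identical likelihood through five
discrete per-node stages — prelike transform, clp computation, old-scaler
subtraction, rescale, root combination — each materialising to a simulated
global store that the next stage re-reads. The store counts every access at
whole-object granularity: one clp access moves L residues of 16 floats, one
tip/prelike access 64 floats, one lnScaler access L floats (bytes = 4× the
float count in the single-precision convention). The final root-stage read
fetches the root clp once more; the concluding lnScaler read during the
per-site summation is attributed to the host, not the store — this is what
reproduces the extra root-side clp read in the accounting.

Closed-form ledgers are given for the idealised accounting scenario: `N−2`
down nodes and a root, each composed of one terminal and one internal child,
every node a scaler node *in steady state* (carrying an old scaler to
remove). No finite binary tree realises that composition at its deepest
internal node — a binary tree with N leaves has N terminal-child edges and
N−2 internal-child edges, while the scenario needs N−1 of each — so
verification measures per-node unit transfer costs on a real caterpillar
evaluation (its mid-chain down nodes and root do realise the composition),
then scales by the scenario's node counts. The unit costs are measured, not
assumed; only the node-count multiplication is the same idealisation the
closed forms embody. A warm pass (second evaluation) is used so every scaler
node also exercises the old-scaler-removal stage.

## MC³ sampler

Chains are heated as `β_i = 1/(1 + λ i)` with λ = 0.1 (cold chain i = 0);
defaults follow the standard protocol of two independent runs, four chains
(three heated), sampling and diagnosis every 1000 generations. Within a
generation the chains are advanced one by one, then one swap between a
uniformly chosen pair is attempted with acceptance
`min(1, (p_i/p_j)^(β_j−β_i))` on the unheated posterior kernels.

Moves (relative weights in parentheses): branch-length multiplier (4) with
log-uniform factor `exp(2 ln 1.6 (u−½))`; NNI (3) with a multiplier on the
crossed branch; subtree prune-and-regraft (1) with uniform reinsertion point
and Hastings ratio `n_prune·a / (n'_prune·m)` for target length `a` and merged
origin length `m`; Dirichlet proposals (1 each) on exchangeabilities and
frequencies with concentration 300·current; reflected sliding windows (1
each) on α (half-width 0.5, reflect at 0) and P (half-width 0.15, folded into
[0,1)). A proposal that leaves its support (branch length outside
[1e-8, 100], a Dirichlet component under 1e-5, no prunable subtree) raises
the abort flag and is discarded before any likelihood work; aborted moves
commit nothing. The move set is a documented minimal surrogate for a
production sampler's mix, not a claim of move-for-move parity with any
particular one.

Priors: flat Dirichlet on exchangeabilities and frequencies, Exponential(10)
branch lengths, Exponential(1) shape, Uniform(0,1) invariable proportion.
Heating applies to the full posterior kernel (likelihood × prior).

Likelihood work is incremental: a proposal dirties only the ancestor chain of
what it touched; the evaluator snapshots those nodes, re-runs them (the
scalersSet machinery removes and re-adds per-node scalers exactly), and rolls
everything back on rejection. A property test drives random accept/reject
sequences and checks the cached value against a from-scratch evaluation. The
multipass evaluator is plugged into the sampler through a full-recompute
adapter (cold evaluation per proposal), which is stateless and therefore
trivially correct; with the same seed the two evaluators produce identical
chains because their likelihoods agree to ~1e-13.

Randomness: one master seed spawns independent streams per (run, chain) plus
a per-run swap stream and an initial-tree stream, so per-chain reproducibility
holds under any chain count and outputs are byte-identical across repeats.

Diagnostics: split frequencies are computed over canonical bipartition
bitmasks (bit = rank of taxon label in sorted order, side not containing the
first label) after discarding a 25% burn-in (configurable); ASDSF averages
`|f₁−f₂|/√2` over splits reaching frequency ≥ 0.1 in at least one run.

## Synthetic data

The simulator draws, per column: invariability with probability P (root state
copied to all taxa); otherwise a uniformly chosen discrete gamma category — 
matching the likelihood's equal-probability discretisation, rather than a
continuous gamma draw, so simulated truth and inference model coincide
exactly — a root state from π, and a multinomial transition draw per branch.
Truth records (tree, parameters, per-column category, invariable mask) are
kept alongside.

Random topologies come from sequential random addition (each new leaf
subdivides a uniformly chosen branch), which is exactly uniform over the
(2n−5)!! unrooted labelled topologies; branch lengths are i.i.d.
Exponential(10) by default (mean 0.1 substitutions/site). Dataset presets
mirror the shapes of published rDNA benchmark groups (26×1546 up to
288×3386) and a 60-taxon scalability grid. The *strong-signal* presets used
for recovery experiments draw branch lengths Uniform(0.05, 0.2) instead, so
that at 2000 sites every split expects on the order of a hundred
substitutions — that bound is what "strong signal" means here; with
exponential branch lengths an occasional near-zero internal branch would make
topology recovery a property of the draw, not of the sampler.

What the simulator does *not* emulate: indels and alignment error (columns
are generated aligned), rate heterotachy, base-composition drift across the
tree, and among-gene partitioning. Passing recovery tests therefore
demonstrate correctness of the inference machinery under its own model, not
robustness to model violation.

## Test-scale choices

Problem sizes in the test suite are chosen so the whole suite runs in minutes
on one core: exhaustive-enumeration cross-checks use ≤6 taxa and ≤4 patterns
(200 random fixtures); pipeline-equivalence runs use 4–30 taxa; the
evaluator-equivalence sampler comparison uses 12 taxa × 500 sites × 5000
generations; parameter/topology recovery uses 20 taxa × 2000 sites × 20000
generations and 12 × 2000 × 10000, with two runs of two coupled chains each
(coupling retained, chain count halved from the four-chain default) and
cold-chain sampling every 100 generations so credible intervals rest on ~150
post-burn-in draws.

For the coverage check, "six free parameter groups" are: exchangeabilities,
base frequencies, α, P, total tree length, and mean terminal branch length; a
vector-valued group counts as covered when more than half its components'
truths fall inside their marginal 90% credible intervals.

## Numerical notes and limitations

- Double precision throughout by default; a float32 mode exists for parity
  experiments with 4-byte-float hardware, where the scaler-free linear-domain
  reference demonstrably underflows near 200 taxa while the scaled evaluator
  stays finite.
- A site whose likelihood is exactly 0 (impossible data, e.g. conflicting
  states across zero-length branches) yields lnL = −inf with a warning; a
  zero scaler at a scaler node raises an error naming the pattern.
- Branch lengths are floored at 1e-8 by proposal rejection, not clamping, so
  Metropolis reversibility is untouched.
- The sampler has no convergence criterion beyond ASDSF reporting, no
  checkpointing, and no reversible-jump model averaging; alphabets other than
  nucleotides and partitioned models are out of scope.
- The transfer ledger models traffic at whole-object granularity; it is an
  accounting device, not a cycle-accurate memory simulation, and deliberately
  ignores caches, overlap and scheduling.
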