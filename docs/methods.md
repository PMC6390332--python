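# Methods

This note documents the model semantics, the estimation and numerical
choices, the synthetic benchmark, and the limitations a user should know
before trusting output on real data.

## Pathway model

A normalized pathway is a directed graph over genes with activation-family
edges (activation, phosphorylation/dephosphorylation activation, indirect
effect, expression) and inhibition-family edges (inhibition and its
phosphorylation variants).  Normalization merges nodes annotated with the
same gene, removes non-gene nodes (compounds, maps) while reconnecting
their neighbours with the sign product of the two hops, drops self-edges,
and keeps at most one edge per (source, target, polarity).  Relations
without an activation/inhibition polarity (e.g. binding/association) are
dropped and logged rather than guessed.

Each gene becomes a variable over {−1, 0, 1, 2, 3, 4} (uninitialized, not
expressed, expressed, differentially expressed, activated, differentially
activated), initial value −1.  The command set is:

* **init** (every gene): `A=−1 → prob1:(A'=1) + prob2:(A'=2)`.  For a gene
  called differentially expressed at FDR cutoff `v`, `(prob1, prob2) =
  (α_e, 1−α_e)` with `α_e = v` (the DE call itself has error `v`);
  otherwise `(1−α_e, α_e)`.  Default `v = 0.05`.
* **source** (genes with no incoming edge of any kind): from {1,2} the gene
  self-activates (+2) with probability `prob_init = P(A)`, else drops to 0.
* **activation edge** `A→B`: if `A` is active (>2) and `B ∈ {1,2}`, then
  with `prob_active` the target moves to 3 — or to 4 when the source is at
  4 or the target was at 2 — else to 0.
* **inhibition edge** `A⊣B`: two commands.  While the inhibitor is not
  active (`A<3`, which includes "not yet initialized" — read literally from
  the command's guard) the target may still activate (`B+2`) with
  `prob_inhibit1`; when both are active, the inhibitor demotes the target
  (`B−2`) with `prob_inhibit2`, else sends it to 0.

Parameters combine a DE-pair ladder `diff(A,B) ∈ {α, 2α, 3α}` with
`α = 1/6` (so the term never exceeds 1/2; the absolute value of `α` only
rescales all scores), the gene evidence `P(A)`, and cross-collection
interaction frequencies:

```
prob_active   = diff(A,B) · P(A) · P(A→B)
prob_inhibit1 = P(A⊣B)
prob_inhibit2 = diff(A,B) · P(A) · P(A⊣B)
```

`prob_inhibit1` deliberately omits the `diff·P(A)` damping — the asymmetry
is part of the model definition and is implemented literally.
`P(A→B)` is the number of collection pathways containing the edge divided
by the number containing both genes; the scored pathway is always counted,
so the denominator is at least 1.

## Gene-level evidence

Differential expression uses the empirical-Bayes moderated two-sample t:
per-gene pooled variances `s_g²` (d_g df) are shrunk toward a prior
`s0²` with `d0` df, both estimated by method of moments on `log s_g²`
(trigamma inversion by Newton iteration; `d0 = ∞` handled by capping the
reference-distribution df at 10⁶).  The implementation reproduces the
standard R reference implementation to 12 decimals on a frozen fixture.
P-values are BH-adjusted (scipy) and genes with `q < v` are flagged DE.

`Fn(A) = sqrt((f(A) − min f)/(max f − min f))` maps a gene's pathway
frequency into [0,1].  Two readings are shipped because the formula and its
motivating prose point in opposite directions: `literal` (default) gives
frequent genes weight near 1; `inverted` gives pathway-specific genes
weight near 1, matching the stated down-weighting rationale.  Choose
explicitly (`AnalysisConfig.freq_mode`).

`P(A) = |T(A)·Fn(A)|` is unbounded, so a rescaling is always applied:
`max_normalize` (default) divides |T| by the largest |T| among measured
genes; `clip` truncates the product at 1.  Both have measurable drawbacks
discussed under *Limitations*.  Genes that occur in a pathway but not in
the expression matrix are treated as expressed non-DE with `T = 0`, so
platform coverage cannot silently switch a pathway off.

## Engines

The score of a pathway is `Σ_g P[F (g = 4)]` over its final effectors
(out-degree-0 genes — the operational definition adopted here; pathway
formats carry no effector flag).  Local nondeterminism (several commands
enabled in a state) is resolved by the **uniform scheduler**: the successor
distribution is the uniform mixture of the enabled commands' branch
distributions.  Deadlocks self-loop.

*Exact engine.*  Before enumeration the model is restricted to the
ancestors of the query gene: commands targeting other genes can never
change the query variable or the enabledness of its ancestors' commands,
and conditioned on a relevant command firing, the choice among relevant
commands is uniform — so the jump chain of the retained commands equals
the sub-model's chain and eventual reachability is unchanged.  The
reachable space is explored breadth-first (cap: 500 000 states,
configurable), target states are found structurally, the states that
cannot reach the target are zeroed by backward graph search, and the
remaining linear system `x = Px + b` is solved by sparse LU with a value
iteration fallback (tolerance 1e−10, iteration cap 10⁶; value iteration
converges to the least fixed point, which is the correct reachability
value even for singular systems).  Results are independent of enumeration
order.

*Monte-Carlo engine.*  A numba-compiled kernel simulates seeded
trajectories under the same scheduler (default 20 000 trajectories, step
cap `10·|commands|·|genes|`); the estimate is a success fraction with
binomial standard error, and the censored fraction (trajectories that hit
the step cap) is reported.  On inhibition-free models every trajectory
reaches an absorbing state well inside the default cap, so censoring is 0.
A batch mode scores all effectors of a model from one trajectory set,
which is what the permutation loops use.

*Auto* tries exact under the state cap and falls back to Monte Carlo with
a logged notice.

## Permutation significance

`P_F` is the fraction of class-size-preserving label permutations whose
recomputed score (moderated t → DE calls → P(A) → parameters → model →
score, all recomputed per permutation) is at least the real score — no
pseudocount, exactly as defined; an optional `(1+k)/(1+N)` smoothing is
off by default.  Permutations are drawn over *sorted sample names*, making
results invariant to column order, and are enumerated exhaustively when
fewer than `n_perm` distinct labelings exist.  Whole-collection analysis
shares one permutation set across pathways (one moderated-t pass per
permutation); per-pathway `P_F` is unchanged by this sharing.

Within one permutation test the real and all permuted scores share a
single simulation seed (**common random numbers**), so Monte-Carlo noise
largely cancels from the score comparison; under the null the scores
remain exchangeable because all labelings are scored by the same
function.  Default `N_perm = 200` (no published value to adopt);
benchmark protocols below use 100.

## Synthetic benchmark

The generator emulates the structure of a target-pathway validation:
random simple directed pathways (default 20 pathways × 12 genes, 15 edges,
20 % inhibiting edges, one node forced terminal so an effector always
exists), drawn from a shared pool of 5× `genes_per_pathway` genes so that
gene frequencies spread like a real database's (mean frequency ≈ 4), plus
500 unaffiliated filler genes in the expression matrix.  Expression is iid
Gaussian noise (σ = 1) with a mean shift of `effect_size·σ` applied to a
`de_fraction` of the designated target pathway's genes in case samples
(defaults 1.5 and 0.3, n = 10 vs 10).  What this does *not* emulate:
correlated genes, heavy-tailed noise, heterogeneous variances, batch
effects, and curated topologies — passing these benchmarks shows the
pipeline is internally consistent and detects planted signal, not that it
ranks well on microarray compendia.

Evaluation protocols: false-positive rate under relabeled samples
(fraction of pathways with `P_F` below a threshold, averaged over trials),
decoy discrimination (decoys are label-shuffled copies of real pathways;
AUC is the rank statistic of real vs decoy, ties ½), target summaries
(median target p, median/mean rank percentage, mean reciprocal rank), and
robustness curves (similarity = fraction of edge-removed/rewired versions
whose `P_F < 0.05` call matches the unperturbed call; the analysis seed is
held fixed so only topology noise moves the call).

Problem sizes used by the shipped tests and `scripts/acceptance.py` —
desk-scale by design: 25 random models (≤ 8 genes) for exact-vs-simulation
agreement at 200 000 trajectories; 5 null replicates and 10 target-recovery
replicates of the default 20-pathway collection at `N_perm = 100` and 1 000
trajectories per score; 20 real + 20 decoy pathways for the AUC; 10
rewiring repetitions per fraction.

## Limitations

* **Score semantics favour activation-routed perturbations.**  `P(A)`
  enters the model only as an edge-source factor, a root-source
  `prob_init`, and inhibitor strength.  Expression shifts on sink genes
  contribute nothing unless the gene passes the DE cutoff, and shifts on
  inhibitor genes *reduce* downstream differential activation (an active
  inhibitor closes the `prob_inhibit1` window) — biologically meaningful,
  but it means a pathway perturbed through its inhibitors scores *lower*
  than its permutation null.  With weak shifts that leave the DE-flag
  channel off (few genes with `q < v`), prioritization is therefore
  erratic and depends on where the topology places the shifted genes; with
  the DE channel on (in the generator: `effect_size ≈ 3`, `de_fraction ≈
  0.6`) the target pathway is recovered at the top with `P_F ≈ 0`
  (asserted by the test suite).
* **`max_normalize` couples genes through the normalizer**: a strong
  signal anywhere inflates `max|T|` and deflates every other gene's
  `P(A)` relative to permuted data, which can push `P_F` of
  weakly-affected pathways toward 1.  `clip` avoids the coupling but
  saturates at `|T| ≳ 1.4/Fn`, blunting discrimination.  Neither rescaling
  is ideal; they are retained as the two canonical readings of the
  unbounded definition.
* The plain effector sum grows with effector count (no normalization), so
  effector-rich pathways carry larger raw scores; the permutation null
  absorbs this only partially.
* Overlapping pathways genuinely share evidence; cross-talk is not
  corrected.
* Exact checking is limited by state-space growth (six states per gene);
  full-size curated pathways need the Monte-Carlo engine.
* Multiple-testing correction across pathways is intentionally not
  applied (raw `P_F` is reported).
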