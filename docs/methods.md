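# Methods

## The model

An *affordance landscape* is an m×n real matrix **A** whose entry a_bc is
the value of some action possibility (graspability, climbability, …) when
two ambient energy arrays — think ambient light and ambient sound — are in
observation states o^B_b and o^C_c.  Observation states default to the
integers 1..m and 1..n, and the (b, c) cells are uniformly distributed:
p(o^B_b, o^C_c) = 1/(m·n).  Every other random variable in the model (the
signals, the affordance value, every estimate) takes the distribution given
by the frequency of its values under this uniform cell measure.

Each axis is read by a deterministic, capacity-limited encoder
E: observation state ↦ signal ∈ {0, …, L−1}.  With L signals the encoder's
rate is R = log2 L bits; the interesting regime is R < H(O), where the
encoder must merge observation states.  The rate–distortion trade-off is
embodied entirely by L — the package never computes a rate–distortion curve
R(L); it minimizes expected distortion at fixed L.

For fixed encoders the mean-squared-error-optimal decoder is the
conditional expectation: a signal pair (i, j) decodes to the mean of **A**
over the preimage product E_B⁻¹(i) × E_C⁻¹(j).  The same construction on a
single axis yields *sensory estimates* Ô^B (mean observation state per
signal) and *unidimensional affordance estimates* Â^B (mean of the row-mean
profile A^B per signal).  The whole pipeline is the Markov chain
A ↦ O ↦ Z ↦ Â, and the reported I(A;Â) can never exceed I(O^B,O^C;A)
(data-processing; asserted as a test invariant).

Signals with an empty preimage are permitted (the hill climber may pass
through such assignments); their decoder cells are flagged unused and can
never be addressed by an actual observation, so looking one up is an
internal-consistency error rather than a modelling choice.

## Encoding strategies

*Direct* encoding formalizes direct-perception: each encoder maximizes
affordance information about its own axis, i.e. minimizes the MSE of the
row-mean (resp. column-mean) profile reconstruction — the two axes are
optimized independently.  *Indirect* encoding optimizes the encoder pair
jointly against the full-matrix reconstruction MSE, which amounts to
relaying sensory information for downstream integration.  On synergistic
landscapes the two objectives pull encoders in opposite directions; on the
worked 4×4 example they are exactly antagonistic (direct: I(A^B;Â^B)=1,
I(O^B;Ô^B)=0; indirect the reverse).

Both strategies use the same optimizer: stochastic hill climbing with
random restarts.  Per step, one uniformly random observation per encoder is
reassigned to a uniformly random signal; for the indirect strategy the two
encoders' proposals are evaluated and accepted *as a unit* (the loop
structure would also permit per-encoder acceptance; the joint-unit variant
is the package's choice, and on all certified fixtures reaches the
enumerated optimum).  Moves are kept only on a *strict* decrease, so every
run trace is non-increasing.  Defaults: 20 restarts, 100·max(m, n) steps,
mandatory integer seed (no clock seeding).  An exhaustive-search oracle
certifies results whenever the assignment space has at most 10⁶ points.

The per-signal decoder inside the direct objective averages the
*unidimensional affordance values* over the preimage, not the raw
observation indices: averaging indices would contradict the worked example
(whose direct coding reconstructs A^B exactly while collapsing Ô^B).

## Information measures

All logarithms are base 2, all information is in bits, and 0·log 0 := 0.
Probability tables are sparse (absent outcome = zero mass) and validated to
1e-9; renormalization is explicit, never silent.

**Synergy.**  For sources Z^B, Z^C and target A,
I_syn = I(Z^B,Z^C; A) − I_union, where the union information is the minimum
of I*(Z^B,Z^C; A) over all joint distributions Pr* that preserve both
(Z_i, A) pairwise marginals.  Because p(A) is fixed on that polytope the
objective equals const − H*(A | Z^B,Z^C), which is convex, and the program
is solved by a log-barrier interior-point Newton method:

- coordinates forced to zero by a zero pairwise marginal are eliminated
  first (otherwise the feasible set lies in a proper face and both the
  solver's parameterization and the grid oracle misbehave);
- the equality constraints are eliminated by a null-space parameterization
  q = q₀ + N·t, so feasibility is exact by construction; the start
  q₀ = p(y)·Πᵢ p(xᵢ|y) is the maximum-entropy feasible point and strictly
  positive on the reduced coordinates;
- the barrier parameter follows μ = 1e-2 → 1e-11 (factor 10), each stage
  solved by damped Newton with Armijo backtracking; iteration cap 10,000;
  the reported residual is the final max pairwise-marginal violation.

Two sources are the primary case; n > 2 sources are accepted (solver only).
A brute-force oracle grids the polytope's free coordinates inside their
LP-computed bounding box and is used in tests only (supports ≤ 64
outcomes); solver and oracle agree within 1e-2 bits on every fixture.
Bracketing bounds are reported alongside: WMS = I(joint) − Σᵢ I(Zᵢ;A)
(may be negative) and the Smax synergy based on maximal specific
information, with WMS ≤ I_syn ≤ Smax on every fixture.

**Spatial entropy.**  H_Cl(X) = −Σᵢ dᵢ p(xᵢ) log2 p(xᵢ), where dᵢ is the
mean Euclidean distance from support point i to all others.  Support points
are the *unique values* of the estimate variable placed at their numeric
value on the (1-D) observation axis; a single-point support has d := 0 and
hence entropy 0.  The coordinate space and log base are genuinely open
choices; this one makes the toy direct coding score 0 (all sensory states
collapse to 2.5) and the indirect coding score 2.0 (values 1.5 and 3.5 at
distance 2), units distance·bits.

## Synthetic data

The generators define the study conditions:

- **toy** — the fixed 4×4 matrix [[0,0,1,1],[0,0,2,1],[1,2,0,0],[1,1,0,0]]
  (row means 0.5, 0.75, 0.75, 0.5), and **toy_swapped** with a_23 ↔ a_42
  exchanged.  On the swapped matrix the direct strategy's optimal *row*
  partition coincides with the indirect halves partition {1,2}|{3,4}; the
  two strategies' full joint optima do not coincide (enumeration gives 1/6
  vs 1/16), because the swapped matrix's column means single out column 2.
- **xor** — the 2×2 matrix [[0,1],[1,0]]: with identity encoders all 1 bit
  of affordance information is synergistic.
- **random_synergistic** — balanced contiguous blocks per axis; the value
  depends only on (row block + column block) mod B, an XOR-style coupling,
  so no single axis predicts the value but the pair does.  Balanced blocks
  matter: unbalanced ones leak block identity through the axis means.  A
  noise fraction of cells is resampled uniformly from the value set.  The
  generator returns the block labels, so ground-truth encoders are known.
- **blob_image** — 32×32 grayscale-like matrices: Gaussian background
  (mean 60, sd 15 on a 0–255 scale) plus 1–3 bright Gaussian blobs that are
  tall (σ_r ≈ 0.25–0.45·m) and narrow (σ_c ≈ 0.03–0.08·n), mimicking small
  photographs of standing figures, whose vertical variance concentrates in
  a few columns while horizontal variance spreads over many rows (the top-8
  columns by variance capture a larger variance share than the top-8 rows
  in ≥ 90% of seeds; asserted in tests).  Values are then reduced to 5
  unique levels by seeded 1-D k-means (k-means++ initialization, ≤ 100
  iterations, tol 1e-6), because exact synergy computation needs a small
  target alphabet.  Quantized values are the cluster *centroids* (reals,
  averageable), not level indices.  An optional loader ingests user image
  files (Rec. 601 luma for RGB).
- **separable** — the negative control a_bc = f(b) + g(c) with f, g drawn
  from a *continuous* uniform.  Continuity is essential and deliberate:
  integer-valued separable matrices generically produce value collisions
  (f_b − f_b' = g_c' − g_c), which alias the matrix into a sum-type gate —
  and the sum of two uniform bits famously carries 1 full bit of BROJA
  synergy despite being "additively separable".  With continuous values
  collisions have measure zero, every cell value identifies its cell, the
  marginal-preserving polytope degenerates to a point, and synergy is
  exactly 0 — which is the sense in which separability excludes synergy.

These generators emulate the *structure* the model needs (synergistic
coupling, vertical/horizontal variance asymmetry, small value alphabets);
they do not emulate natural image statistics, class semantics, or pixel
correlations beyond the blob geometry.  Passing tests therefore show that
the model behaves as theorized on landscapes with controlled synergistic
structure, not that the effect sizes transfer to any particular natural
image corpus.

## Batch experiment

`run_batch` draws per-landscape seeds from a root `SeedSequence`, optimizes
both strategies on each landscape, computes the full metric set (affordance
MSE, synergy, sensory MI and MSE per axis, unidimensional MI per axis,
spatial entropies), and compares strategies with paired one-sided Wilcoxon
signed-rank tests (indirect expected to give lower affordance MSE and
higher synergy).  The default conditions are 30 landscapes of 32×32 at 5
levels with 8 signals (3 bits) per encoder and the default optimizer
schedule; one full run takes a few minutes on one CPU.  The Wilcoxon choice
is the package's own: a paired, distribution-free test matching the
per-landscape pairing of the two strategies.  Records flagged by a PID
solver failure are excluded from the paired summaries and logged.

## Numerical choices and limitations

- Ties in the hill climber are rejected (strict decrease only); ties in the
  Smax maximum need no tie-breaking (max of reals).
- MI values in (−1e-12, 0) from round-off are floored to 0; synergy is
  clipped to [0, joint MI] only after verifying the violation is within
  solver tolerance (1e-6 bits), otherwise a solver error is raised.
- Metrics are stored at full precision; only report rendering rounds to two
  decimals.
- The hill climber is a local optimizer: certification against enumeration
  exists only at small sizes; at 32×32 the indirect objective values are
  upper bounds on the true optimum.
- Stochastic encoders/decoders, more than two modalities, and non-uniform
  observation priors are out of scope by design.
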