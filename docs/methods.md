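# Methods

## The meta-organism model

A microbial community is represented as a single organism with one pooled
reaction set. Species are (metabolite, compartment) pairs written
`met@c` — the same metabolite in two compartments is two distinct species.
Compartments are cytoplasm (`c`), mitochondrion (`m`), nucleus (`n`),
peroxisome (`x`) and the shared extracellular space (`e`); vacuole (`v`)
and lysosome (`l`) are admissible only before pruning. Reactions are
`metabolic` (one compartment, two-sided), `transport` (species span ≥ 2
compartments) or `exchange` (one-sided, extracellular only — environment
boundary). Intracellular demand/sink pseudo-reactions are deliberately not
representable; material leaves a model only through the extracellular
space, which keeps the boundary of every model explicit.

Assumptions inherited from the input data: metabolite formulas and charges
are stated at intracellular pH 7.2 and are consumed, not recomputed;
ΔᵣG′ values are inputs (no group-contribution estimation here).

## Stage 1 — reconstruction

* **Generic removal.** A compound without a fully specified elemental
  formula (protein, RNA, DNA, glycan, generic lipid class) is flagged
  generic; every reaction touching one is removed and orphaned species are
  dropped. Idempotent.
* **Balance check/repair.** For each reaction the signed elemental and
  charge totals are computed. If the residual involves only H and O, the
  water coefficient is fixed by oxygen (t_w = −ΔO), the proton coefficient
  by hydrogen (t_h = −ΔH − 2 t_w), and the repair is accepted only when
  t_h also cancels the charge residual and both terms are integers —
  exactly the omissions upstream databases make. Anything else is flagged
  unbalanced and *retained* (strict mode drops it); a reaction with a
  formula-less participant is `unverifiable`. Exchange reactions are
  boundary terms and exempt.
* **Directionality.** |ΔᵣG′| ≥ T ⇒ irreversible (orientation flipped first
  when ΔᵣG′ ≥ +T); otherwise, or with no estimate, reversible. T defaults
  to 30 kJ/mol — a common practice cutoff; the sources give none — and is
  configurable. Bounds always follow the global policy: (0, 100)
  irreversible, (−1000, 100) reversible, in mmol·gDW⁻¹·h⁻¹.

## Stage 2 — compartmentalization

Per-reaction localization probabilities (CELLO-style tables; nonnegative,
unit sum) and reference-model assignments are combined by **union**:
compartments scoring ≥ `min_score` (default 0.3) plus all reference
compartments; if empty, the argmax compartment, ties broken by the fixed
priority c > m > n > x > e. Union (rather than precedence) was chosen
because neither source dominates the other in practice and a false extra
copy is cheaper to the downstream curation than a missing one.

Compartments with fewer than `min_reactions` (default 25) assigned
reactions are pruned — this reproduces the discarding of a 7-reaction
vacuole and a 20-reaction lysosome while keeping anything ≥ 25 — and their
reactions are reassigned to the best-scoring surviving compartment
(fallback cytoplasm). Cytoplasm and extracellular space cannot be pruned.

Each reaction then gets one copy per assigned compartment (`rid@k`, all
species relocated to `k`), which preserves the set of unique metabolite
ids exactly. Transport/exchange templates are injected iff every species
they reference already exists; additions are reported split into
cytoplasm↔extracellular and cytoplasm↔inner classes. A
non-compartmentalized build is the same code path with every assignment
set to {c}.

## Stage 3 — curation (GapFind / GapFill)

**Producibility semantics.** Species i is *producible* when a flux vector
v within bounds exists with S·v ≥ 0 (steady state relaxed to allow
accumulation) and an individual contribution S_ij·v_j ≥ ε for some
reaction j. *Consumability* is producibility in the sign-reversed system:
−S with the same bounds, i.e. S·v ≤ 0 with an individual drain ≤ −ε.
(Negating bounds as well would be an identity transformation — a bug the
chain fixture in the test suite guards against.)

**GapFind MILP.** One binary per candidate producing (species, reaction,
direction) pair, linked to the flux by a big-M constraint
S_ij·v_j ≥ ε − M_p(1 − w); one binary per species bounded by its pair sum;
maximize the number of certified species. Per-pair constants
M_p = ε + |S_ij|·max(|LB_j|, |UB_j|) are derived from the actual bounds so
large stoichiometric coefficients cannot defeat the linearization; the
configured M (default 1000) is the flux-bound scale, ε defaults to 0.001.
Solver verdicts are never trusted bare: the optimum's flux vector is
re-verified numerically (S·v ≥ 0 and each claimed pair contribution ≥ ε up
to tolerance) because a MILP integrality tolerance of 1e-6 times a big-M
of ~2000 can fake a certificate by more than ε; and an infeasible verdict
is re-checked with presolve disabled, because the HiGHS presolve shipped
with SciPy was observed to declare systems infeasible whose all-zero
vector satisfies every constraint. Every species left uncertified by the
verified joint optimum — certificate conflicts, alternative optima,
tolerance artifacts — is then decided by per-pair LP feasibility whose
returned point is verified the same way (certification sweep). The
reported sets therefore equal the per-species definition with numerically
checked certificates, and non-producibility claims rest on LP
infeasibility rather than MIP presolve.

**GapFill MILP.** Candidate database reactions enter with inclusion
binaries gating their bounds; two flux blocks share them — one carrying
production certificates, one consumption certificates — so a filled target
is producible *and* consumable (joint resolution; the sources do not state
whether they resolved the two separately). Per-target solves minimize the
number of additions (MILP optimality is the minimality certificate);
compartment batches solve one MILP maximizing resolved targets with a
weight larger than any possible addition cost, so no target is sacrificed
to save database reactions. Every claimed fill is post-verified by LP on
the augmented network (target producible and consumable with checked
certificates); unverifiable claims are reported infeasible. Ties between
equal-cardinality solutions are
broken toward lexicographically smaller reaction ids via a rank penalty
below 1/(2·|db|). The search space is the candidate database plus exchange
templates only; relaxing directionality of existing reactions is excluded.

**Three-step compartmentalized order.** (1) fill cytoplasmic gaps from the
candidate database; (2) add cytoplasm↔inner exchange reactions — generated
for problem species whose cytoplasmic counterpart exists, plus eligible
transport-database templates — which resolves the large fraction of inner
gaps shared with the cytoplasm; (3) fill the remaining compartments
separately (database instantiated per compartment; boundary exchanges for
extracellular gaps). Reconnection percentages (connected = neither
non-produced nor non-consumed) are reported per compartment over the
*pre-curation* species universe, so added species cannot inflate them;
empty compartments report NA.

## Stage 4 — flux balance analysis

Maximize Z = cᵀv subject to S·v = 0 and the bound policy (HiGHS LP).
Solver failure surfaces as a status, not an exception. Multi-reaction
objectives use unit weights (no weighting is stated anywhere). Because
active-flux counts are not well-defined under degenerate alternative
optima, an optional secondary LP fixes Z and minimizes Σ|v| (split
variables); the pipeline enables it by default. Active-flux fractions are
100·|{j ∈ scope : |v_j| > 1e-6}|/|scope| — the tolerance is the LP noise
floor; empty scopes report NA.

The objective library ships the nitrogen-cycle (4 templates),
sulfur-cycle (4), TCA-related (7, of which 3 are cytoplasm↔mitochondrion
exchanges) and fatty-acid-elongation (3) blocks. The generic electron
acceptor written "A" in the source tables is mapped to oxidized ferredoxin
(it balances the reduced-ferredoxin terms of the same blocks) and is
remappable. Template instantiation matches network reactions by id (or
per-compartment copies `id@k`), falling back to exact stoichiometry match;
unresolved templates are reported explicitly, never silently dropped.
Reaction knockouts are bound-forcing to (0, 0).

The toy models encode the compartment-coupling mechanism: in the
fatty-acid model the mitochondrial CoA pool is closed (regenerated only by
elongation) and acetyl-CoA is made only in the cytoplasm, so the whole
block carries flux iff the acetyl-CoA transport is available — knocking it
out forces Z = 0 exactly. In the TCA model the block reactions are
duplicated in cytoplasm and mitochondrion; with exchanges all copies and
the three transports run (Z = 1000 at the default caps), without them the
transports contribute nothing (Z = 700), and the flattened model merges
the duplicate copies (Z = 400). Only this ordering is a claim; the
magnitudes are properties of the toy's bounds. Scaffolding reactions in
the TCA toy carry a widened upper bound (1000) so that the objective
members, at the standard policy caps, are the only binding constraints.

## Stage 5 — topology and centrality

The metabolite graph is a directed multigraph: an edge per (substrate,
product) pair per reaction, both directions for reversible reactions, no
currency-metabolite filtering (H⁺, H₂O, ATP-like hubs are the signal, not
noise). Degree distributions count parallel edges from distinct reactions
with multiplicity. Conventions for the global metrics, chosen to match
common network-analysis tooling: clustering coefficient on the undirected
simple projection averaged over nodes with degree ≥ 2; path length and
diameter over reachable ordered pairs of the directed simple graph
(community-scale graphs are not strongly connected); radius = minimum
eccentricity over nodes with full reach, else over the largest strongly
connected component, else NA.

Power-law fits: discrete maximum likelihood for P(k) ∝ k^−γ/ζ(γ, k_min)
(the headline estimator) with a log-log regression slope and r² as
diagnostics; k_min defaults to 1. `k_min=None` selects the cutoff by
minimizing the KS distance between tail and model (Clauset-style), which
is the right estimator when the power-law regime starts above the smallest
degrees — as it does for carrier-smeared synthetic networks (below).

Centrality ranking combines in/out degree, total edge count (with
multiplicity), betweenness on the simple digraph, and the absolute loading
on the first two principal components of the column-centered
stoichiometric matrix (no unit-variance scaling — scaling would erase the
hub structure PCA is meant to surface). The combined rank is the mean of
per-measure ranks, ties broken by species id, making the ranking invariant
to input order.

## Synthetic data: what it emulates, and what a green test establishes

The generator's world is a polymer chemistry: metabolite formulas are
C_s H_(2s+2h+q) O_(s+h) for size s (5 ± 1 unit), hydration h ∈ {0, 1} and
charge q ∈ {−1, 0}; every backbone reaction converts one metabolite into
another and is closed exactly by three carriers — a one-carbon CH₂O unit
carrier, water and the proton. Consequently (a) every quantitative
reaction is exactly mass- and charge-balanced by construction, (b) the
carriers become high-degree currency hubs as in real networks, and
(c) deleting the H₂O/H⁺ terms of a reaction produces precisely the
repairable imbalance class of stage 1.

Degrees are planted: in/out degree targets are zipf(γ_in), zipf(γ_out)
samples (defaults 1.8 and 2.0); reversible reactions (a planted 45% share)
consume an in- and an out-stub at both endpoints, directed ones an
out-stub at the source and an in-stub at the target; surplus stubs on the
larger side are *thinned* uniformly (thinning preserves the exponent;
padding would flatten it). Carrier and generic-participant edges smear the
small-k end of the realized distribution while leaving the tail exponent
intact, which is why exponent-recovery checks use the KS-selected cutoff.
Compartment ground truth follows the mixture c ≫ m > n > x (0.68 / 0.20 /
0.093 / 0.027, the typical compartment-size ranking), with 7
vacuolar and 20 lysosomal reactions planted to exercise pruning.
Localization tables are Dirichlet draws concentrated (α = 15) on the true
compartment; reference tables report the truth for a 30% subset; ΔᵣG′ is
present on all irreversible reactions (irreversibility is called from it)
and on 60% of reversible ones.

Planted gaps are removals verified by the gap finder to turn at least one
previously connected species into a dead end; such species are exactly
restorable by re-adding the removed reaction, so the recovery key plus
decoys is a faithful gap-filling benchmark.

What the generator does **not** emulate: annotation noise and missing
reactions beyond the planted gaps, realistic biochemistry (cofactor
couples, nitrogen/sulfur/phosphorus chemistry), organism boundaries within
the community, and correlated localization errors. A green planted-gap or
exponent-recovery test therefore establishes the *machinery* (detection,
minimal filling, fitting) on networks with the right statistical shape,
not performance on real metagenomes.

## Numerical choices and degenerate inputs

* Stoichiometric coefficients are doubles compared at 1e-9; matrix rows
  and columns are ordered lexicographically so serialization is
  bit-stable; two runs with identical config and inputs produce
  byte-identical tables (timings go to the log only).
* MILPs run with mip_rel_gap = 0; HiGHS is deterministic single-threaded.
* A network with zero reactions yields a gap report marking every species
  non-produced and non-consumed; an empty metabolite graph is a
  degenerate-support error for the distribution fitter (< 3 distinct
  degrees likewise).
* SBML Level 3 export carries bounds, reaction type, ΔᵣG′, EC numbers,
  formulas, charges and the original ids in a package annotation
  namespace; import is the exact inverse (libsbml drops empty attribute
  strings — handled on read).

## Known limitations

* GapFind's accumulation relaxation certifies production through
  flux-sustained cycles (two antiparallel reactions can certify each
  other's metabolites without an external source). This is faithful to the
  method; callers wanting seed-based expansion semantics need a different
  tool.
* Gap filling is purely structural/stoichiometric; no thermodynamic or
  taxonomic plausibility screening of the added reactions (done manually
  in the source workflow).
* The per-species certification sweep makes gap detection quadratic-ish in
  the number of uncertified species; fine at the tested scales (≤ ~1000
  reactions), not profiled beyond.
* Active-flux fractions remain solver-dependent when multiple Σ|v|-minimal
  optima exist.
* PCA loadings use a dense SVD; very large networks would need a sparse
  truncated decomposition.
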