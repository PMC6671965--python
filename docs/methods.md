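# Methods

## Model

The state is a fully connected directed signed network on *n* ≥ 3
actors: one real relation *x*<sub>ij</sub> ∈ [−1, 1] per ordered pair,
no self-relation variables (the diagonal is stored as 0 and ignored).
Relations evolve by

dx<sub>ij</sub>/dt = (1 − x<sub>ij</sub>²) · Σ<sub>k∉{i,j}</sub> x<sub>ik</sub> x<sub>kj</sub>,

a deterministic gradient-like removal of triadic dissonance: the n − 2
third parties vote on each relation through the products
x<sub>ik</sub>x<sub>kj</sub>, and the saturating prefactor confines the
flow to the hypercube [−1, 1]<sup>n(n−1)</sup>, whose corners
(x<sub>ij</sub> = ±1) are the invariant discrete states. A corner is an
attracting fixed point exactly when every relation agrees with the sign
of its third-party vote, s<sub>ij</sub> = sign(Σ<sub>k</sub>
s<sub>ik</sub> s<sub>kj</sub>); this sign condition is the package's
stationarity test. For odd *n* the vote — a sum of n − 2 odd terms — is
never zero, so stationarity is unambiguous; even *n* is allowed but
flagged, and exact zero votes are reported as degenerate rather than
resolved silently.

The self-evaluation index of actor *i* is
F<sub>i</sub> = ½ Σ<sub>k</sub> (1 + x<sub>ik</sub>) x<sub>ki</sub>:
the sum of reciprocal relations over the actors *i* likes. At a corner
it is an integer in [−(n−1), n−1]; F<sub>i</sub> < 0 identifies actors
whose liking is answered mostly with hostility.

Assumptions worth keeping in mind: the network is complete (every actor
has an opinion on every other and all relations are mutually known —
a small-group assumption), relations are scalar, and the dynamics is
deterministic with no noise, aging or link rewiring.

## Archetype configurations

Four block structures recur as fixed points and are treated in closed
form. With class sizes N1, N2, (N3, N4):

| kind | structure | stationarity | per-class F |
|------|-----------|--------------|-------------|
| HB   | two friendly cliques, mutual hostility, symmetric | always | N1−1, N2−1 |
| CII  | clique 1 rejects internally hostile class 2, which likes 1 | N1 > N2 + 2 | N1−1, −N1 |
| CIII | two hostile cliques + internally hostile class 3 that likes 1 (unreturned) and is liked by 2 (unreturned) | N1 + N2 > N3 + 2 | N1−1, N2−N3−1, −N1 |
| CIV  | two hostile cliques + internally hostile classes 3, 4 that like each other; 3 likes 2, is liked by 1; 4 likes 1, is liked by 2 | N1 + N2 > N3 + N4 + 2 | N1−N3−1, N2−N4−1, N4−N2, N3−N1 |

Each inequality is the binding one; the votes of the remaining links
give strictly weaker conditions (verified exhaustively against the sign
condition for every size split with 5 ≤ n ≤ 11 in the test suite). The
CIII/CIV arrow patterns are fixed by requiring that direct evaluation of
F on the constructed matrices reproduce the closed-form per-class values
and that the stationarity conditions come out as above; the stationarity
oracle in the tests guards this reconstruction. The CIV pattern admits
the automorphism (1↔2)(3↔4), so size tuples (a, b, c, d) and
(b, a, d, c) label the same configuration; the identification routine
reports the lexicographically larger representative. Degenerate empty
trailing classes delegate downward (CIV with N4 = 0 is CIII with
classes 1, 2 exchanged; CIII with N3 = 0 is HB).

## Classification into class graphs

A corner state is summarised by the coarsest partition of actors that is
(a) *equitable* — all members of a class have the same number of liked /
liking neighbours in every class — and (b) *sign-uniform* — each ordered
block of the sign matrix carries one sign. Refinement starts from the
coloring by the per-actor totals (M(i), L(i)) of positive out- and
in-links and iterates splitting on per-class signed neighbourhood
profiles (both directions; directed states such as CII need both) to a
fixed point, which is the coarsest equitable partition. If a block still
mixes signs — possible only for highly symmetric states, e.g. the
two-clique balanced state with N1 = N2, where every actor has identical
counts — the mixed class is split along connected components of the
positive subgraph (label-free, and exactly the two cliques in the HB
case), with singletons as the last resort, and refinement is re-run.
Agreement with a brute-force search over the full set-partition lattice
is tested exhaustively for n ≤ 5.

Class graphs are tallied by a canonical key: classes are grouped by
local invariants (size, internal sign, sorted row/column sign
multisets) and the key is minimised over invariant-respecting class
orders, i.e. exact isomorphism for the class counts that occur in
practice (a deterministic fallback ordering applies beyond 100 000
candidate orders, only reachable for graphs with many interchangeable
classes).

## Numerical integration

The stepper is an embedded Dormand–Prince 5(4) pair (the classical
`ode45` tableau) specialised to the matrix form of the right-hand side,
(1 − x∘x) ∘ (x·x), compiled with numba for ensemble throughput; it is
validated pointwise against `scipy.integrate.solve_ivp` in the tests.
Defaults:

- local error tolerances rtol = atol = 10⁻¹⁰ — two orders tighter than
  the stop criterion, so the stopping rule, not the solver, limits
  accuracy;
- stop criterion max<sub>ij</sub> |1 − |x<sub>ij</sub>|| ≤ 10⁻⁸,
  **and** the sign pattern must satisfy the stationarity condition.
  The second clause matters: a trajectory can pass within 10⁻⁸ of a
  corner that is not a fixed point (one relation's vote has flipped late
  and the relation is still escaping); stopping on distance alone would
  tally such transient sign matrices, and roughly 1% of runs at n = 7 do
  exactly that. Zero votes (even n) do not block the stop;
- overshoots beyond ±1 (bounded by the local error) are clipped just
  *inside* the hypercube, never onto ±1: at ±1 exactly the saturating
  factor would freeze the relation even if its vote later reverses.
  Drift beyond 1 + 10⁻⁶ raises, signalling misconfiguration;
- integration horizon t_max = 40 model-time units. Random-start runs at
  n = 7–11 typically reach a corner near t ≈ 10–20; the slowest 2–3%
  (long passages near saddle corners) are counted as non-converged,
  which matches the generic ~97% convergence rate of this dynamics at
  these sizes. Raising t_max to 10³ drives convergence to ≈ 100% and
  raises the asymmetric-state shares by one to two points, since slow
  runs end disproportionately in jammed states.

## Ensembles

Initial relations are i.i.d. uniform on (−1, 1) — the maximally
uninformative prior on the relation scale. Per-run generators derive
from a counter-based scheme, `default_rng([master_seed, run_index])`,
so ensembles are reproducible and order-independent. Every converged
corner is classified and tallied by canonical key; integration failures
and t_max exceedances become non-converged records, never exceptions.
"Asymmetric" is defined operationally as the final sign matrix differing
from its transpose; summaries report this share and the CIII + CIV
archetype share separately, each both per converged run and per sample,
because the two measures differ by the CII/unclassified states (3–5
points) and the two denominators by the non-converged fraction (2–3
points).

Scaled-down sizes are used where full 10⁴-run ensembles are not needed:
the test suite uses 2 000 runs per network size (binomial SE ≲ 1 point)
and the acceptance script 10⁴ / 4 000 / 2 500 runs at n = 7 / 9 / 11.
The rank–frequency reduction (counts sorted ascending with ranks, and a
collapse exponent fitted across sizes by minimising inter-curve spread
of log-count against log rank − α log n) is provided for large-scale
experiments but tested only structurally: the published collapse
concerns 10⁴-run ensembles at n = 41–71, which are cluster-scale.

What the synthetic generator does *not* emulate about real sociometric
data: valued nomination matrices are sparse, bounded integers with
strong reciprocity correlations, whereas the generator draws dense
independent uniforms. Passing frequency tests therefore validates the
dynamics-and-classification pipeline under the stated random ensemble,
not distributional claims about empirical groups; the sociomatrix module
exists precisely to feed real valued pairs (X − Y)/scale through the
same pipeline.

## Known limitations and observed discrepancies

- At matched study conditions our ensembles reproduce the *composition*
  of published tallies closely (the modal CIII (3, 3, 1) split at n = 7;
  the leading n = 9 rows; the CIII share and the CIII:CIV ratio at
  n = 11), but the aggregate CIII + CIV share runs a few points above
  the published totals — 75 vs 73 per cent at n = 7, and most visibly
  94 vs 88 per cent at n = 11, where the excess sits almost entirely in
  the aggregate CIV share. The shares are sensitive to integrator
  accuracy and patience (looser tolerances and earlier cutoffs lower
  them), so comparisons across implementations should fix those
  settings; the per-configuration fingerprints are the robust check.
- The stability analysis is at the sign-condition level only; no
  continuous (Jacobian) linear stability is computed.
- No sparse or incomplete networks, no weighted generalisation of F,
  and no stochastic update variants.
- Numerical behaviour near n ≈ 100 (where this dynamics is reported to
  become hard to integrate) is out of scope; defaults are calibrated
  for n ≤ 11 and the API merely permits larger n.
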