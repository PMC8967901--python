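# Methods

## Model

The unit of analysis is an *interface-resolved* interaction network:
molecules (proteins, membrane lipids, or cargo classes — groups of
transmembrane receptors recognized through a shared motif and treated as one
node) carry named binding interfaces, and undirected edges join interface to
interface.  A self-edge (an interface binding itself) models
homodimerization.  Interface resolution is essential: two partners binding
*different* interfaces of a protein can be satisfied simultaneously
(cooperation), while partners sharing one interface compete for the same
copies.

Balanced copy numbers are defined by equal-strength competition: every copy
of an interface should pair with a partner copy, with no affinity
weighting.  Formally, each edge `e` receives a non-negative complex count
`c_e`; the implied copy number of interface `i` is

```
x_i = Σ_{e ∋ i, non-self} c_e + 2 Σ_{self e on i} c_e
```

and the optimizer minimizes, over `c ≥ 0`,

```
Σ_p (w_p/α) Σ_{i∈p} (x_i − x̄_p)²            (consistency)
+ Σ_{p observed} w_p (x̄_p − C_obs(p))²       (target)
+ Σ_e r_e c_e²                                (ridge)
```

where `x̄_p` is the mean over `p`'s connected interfaces.  This is an
equilibrium supply/demand calculation — no kinetics, no affinities, no
temporal ordering of assembly.

### Assumptions

- Total cellular abundance is the relevant supply; no correction is made
  for a protein's engagement in other pathways.
- All partners of an interface compete with equal strength.
- Complex counts are continuous: copy numbers are large enough that
  integrality is irrelevant.
- Interfaces never listed in an edge are excluded from `x̄_p`, from
  `C_balanced(p)`, and from the partner-stoichiometry average — an
  interface with no known partner carries no information about balance.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| `alpha` | 1.0 | Trade-off between within-protein consistency and matching observed copies.  `1/α` multiplies the consistency term, so small α forces a protein's interfaces to equal copies; α = 1 permits fluctuations comparable to experimental copy-number variance.  Values down to 1e-3 are exercised in tests. |
| `ridge_eps` | 1e-10 | Ridge coefficient (dimensionless).  Cycles in the interface graph (square motifs) make the complex allocation non-unique at fixed interface copies; the ridge deterministically selects the minimum-norm allocation.  It is scaled per connected component (see below) so its bias on any balanced copy is ≲1e-6 relative. |
| `objective_mode` | `relative` | `relative` weights each protein's terms by `1/C_obs(p)²`; `absolute` uses unit weights.  With abundances spanning six decades, absolute squared deviations are dominated entirely by the most abundant proteins; relative weighting makes every protein's *fractional* imbalance count equally, which matches the log10 scale on which all comparisons are made.  Absolute mode is retained for sensitivity analysis, and is the natural mode for the small equal-scale worked examples. |
| cell volumes | HeLa 2.2e-12 L; fibroblast 2.0e-12 L; synaptosome HeLa/6000 | Used only to report µM concentrations.  Every stoichiometry statistic is scale invariant, so volumes never affect SP, SBR, or the perturbation indices.  The fibroblast value is a typical literature volume; the synaptosome is a compartment ~6000× smaller than a HeLa cell. |
| `C_BALANCED_FLOOR` | 1e-6 copies | Floor applied to balanced copies inside log ratios, so molecules whose balanced copies are driven to exactly zero still report a (large, clamped) SBR instead of ∞.  Floored values are flagged with a warning. |

### Weighting details

- Proteins with **unknown** copies stay in the network, contribute only the
  consistency term, and in relative mode use the geometric-mean abundance
  of their connected component as a surrogate weight scale.
- The **ridge** coefficient for an edge is `ridge_eps / s²` in relative
  mode, where `s` is the geometric mean of observed copies in the edge's
  connected component.  A single global scale would let the ridge
  measurably bias components sitting decades above the global mean.
- A connected component with no observed molecule at all is solvable but
  determined only by the ridge (its copies collapse to ~0); this is
  reported as a warning.

## Solver

The objective is a sum of squares of linear forms in `c ≥ 0`, i.e. a
non-negative linear least-squares problem `min ‖Ac − b‖², c ≥ 0`.  It is
solved with active-set NNLS (`scipy.optimize.nnls`), which terminates at
the exact optimum of this convex problem — no initialization, no
randomness.  KKT optimality is verified to a relative tolerance of 1e-9;
violation raises an error rather than returning a partial solution.  An
independent brute-force oracle (direct loop evaluation of the objective,
multi-start L-BFGS-B) is kept for instances of up to four edges and is used
only in tests; the two routes agree to better than 1e-3 relative on 100
random instances.

A full balance solve on an ~80-protein, few-hundred-edge network takes well
under a second, so a complete single-knockdown scan (one re-optimization
per molecule) runs in a couple of seconds.

## Metrics

- `SP_p` skips interfaces with no partners; partners with unknown copies
  contribute zero to the denominator (no observed count exists, matching
  their exclusion from correlation plots); a partner bound through two
  distinct interfaces counts once per interface; a self-interaction adds
  the molecule's own copies once.  If every partner is unknown, SP is
  reported missing.
- `SBR_p = log10(C_obs/C_balanced(p))` with `C_balanced(p)` the mean of
  connected-interface copies; the per-interface variant uses each `x_i`.
- The interface **CV** (population std over mean of a protein's balanced
  interface copies) flags proteins whose interfaces are pushed to very
  different copy numbers — typically one interface competing at a hub and
  another locked to a single exclusive partner.
- Disruption/sensitivity sums skip molecules whose SBR is undefined in
  either the baseline or the reduced network (unknown copies, or removed).
- All correlations over copies, concentrations, and distances are Pearson
  R on log10 values; SBR vectors, already log ratios, are correlated
  directly.  Zero distances are floored at 1e-12 before logging.

## Synthetic data

The generator emulates the statistical structure of curated
interface-interaction networks:

- **Topology**: disconnected motif modules — selective pairs, hubs (one
  central interface, 3–8 spokes by default), and squares (4-cycles) in
  proportions 0.45/0.35/0.20 — with a small fraction (5%) of self-binding
  interfaces, the only licensed source of triangles.  Proteins may host
  interfaces from several modules, which couples the balance problem
  across motifs.
- **Abundances**: log-normal, log10 sd 1.25 about a mean of 1e4 copies, so
  ~80 proteins realize the roughly six-decade span seen in proteomic
  copy-number surveys.  Small fractions of proteins carry unknown (5%) or
  zero (3%) copies.
- **Balanced mode** draws ground-truth complex counts first, derives
  interface copies by summation (self-edges ×2), and sets observed copies
  to each protein's mean interface copies.  In this mode every protein
  carries exactly one interface: with multi-interface proteins the
  consistency penalty would be nonzero at the constructed truth, which
  would then not be the optimum and "recovery" would be ill-posed.  As
  built, the construction attains objective ≈ 0, and the optimizer
  recovers it to max |SBR| < 1e-5 in both objective modes.

What the generator does **not** emulate: the dense, overlapping competition
of a natural interactome (its modules are far more disconnected), realistic
degree distributions, functional-class-specific abundance patterns, or
correlated abundances between partners.  Passing tests on synthetic data
therefore validate the machinery — optimizer correctness, metric
definitions, perturbation bookkeeping — not biological conclusions about
any particular pathway.

## Numerical choices and degenerate cases

- Duplicate undirected edge rows collapse to one edge with a warning.
- Edges are canonically ordered (lexicographic endpoints), making written
  files and solver input deterministic.
- Cargo classes read their abundance directly from the copy table, falling
  back to the sum of their members' abundances.
- Single-interface molecules have CV = 0 by definition; a protein whose
  balanced copies are all zero reports CV = 0 (the ratio is 0/0 and
  carries no information).
- **Zero-pinned interfaces.**  The non-negativity bound frequently fixes
  some complex counts at exactly zero — e.g. an abundant protein whose
  only partner is orders of magnitude scarcer.  Such interfaces report
  floored SBR values.  Two documented consequences: SBR scale invariance
  holds exactly for all molecules above the floor but not for clamped
  ones (balanced copies themselves scale exactly); and as α → 0 the raw
  CV of an all-but-zero protein is numerically indeterminate (0/0), so
  the small-α limit is monitored as the within-protein interface spread
  normalized by observed copies, which decreases monotonically to zero.
- On small disconnected motif networks, perturbation distances computed
  per interface correlate positively with the per-protein route but well
  below the near-unity agreement expected on dense natural networks: the
  per-protein average hides oppositely-moving interfaces within small
  modules.

## Known limitations

- Equal-strength competition ignores binding affinities; for interfaces
  with chemically diverse partners the affinity spread, not abundance,
  may dominate complex formation.
- Results are conditional on the network: adding or removing edges can
  change any molecule's SBR, which is also what the knockdown machinery
  exploits.
- No temporal or spatial resolution: the balance is a whole-cell
  equilibrium statement.
- Obligate complexes receive no special stoichiometry constraints (e.g. a
  trimer's 3:3 chain ratio); their subunits are balanced through ordinary
  edges.
- Multi-node simultaneous knockdowns, overexpression, and single-interface
  deletions are out of scope.
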