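# Methods

## Model

netthermo treats a snapshot of an evolving network as a thermodynamic
system. The scaled normalized Laplacian L̃/|V| of a simple undirected graph
is a density matrix (unit trace when no node is isolated, positive
semidefinite, eigenvalues λ̃_s ∈ [0, 2]); its eigenstates are the system's
microstates with occupation probabilities p_s = λ̃_s/|V|. Three entropy
evaluations are exposed:

1. **Spectral exact** — the von Neumann entropy −Σ p_s ln p_s, with the
   0·ln 0 = 0 convention. Cubic cost (full eigendecomposition).
2. **Spectral quadratic** — Σ p_s(1 − p_s), the entropy after replacing
   −x ln x by x(1 − x). Identical to Tr[L̃]/|V| − Tr[L̃²]/|V|².
3. **Degree form** — 1 − 1/|V| − (c/|V|²) Σ_{(u,v)∈E} 1/(d_u d_v), which
   needs only degrees of edge endpoints and is the form used for
   trajectories over long snapshot sequences.

The degree form carries a deliberate coefficient ambiguity. Expanding the
trace form exactly gives c = 2 over unordered edges, but the widely used
printed form of this approximation — together with every closed form
derived from it (the K_n and P_n values, the entropy bounds, and the
fluctuation formulas behind the temperature) — uses c = 1. We expose both:
`variant="printed"` (c = 1, the default, internally consistent with all
downstream formulas) and `variant="spectral_consistent"` (c = 2, which
reproduces the quadratic spectral entropy to machine precision on graphs
without isolated nodes and is used as an oracle identity in the tests).
Changing variants shifts H by a graph-dependent amount but rescales no
transition ordering on typical sequences.

Internal energy is U = |E| (microstate energies proportional to node
degrees make the occupation-weighted mean energy proportional to the edge
count; we adopt the edge count itself, and by analogy U = |E_D| for
directed snapshots, where the framework leaves directed energy undefined).

### Temperature between snapshots

For consecutive snapshots G → G′ on the same node set, 1/T = dH/dU with
dU = Δ|E| and dH computed in one of three modes:

- `printed`: Σ over **surviving** edges E∩E′ of
  (d_u Δ_v + d_v Δ_u + Δ_u Δ_v)/(d_u(d_u+Δ_u) d_v(d_v+Δ_v)) — the published
  fluctuation formula verbatim, with no 1/|V|² prefactor.
- `first_order`: the same sum with numerator d_u Δ_v + d_v Δ_u and
  denominator d_u² d_v², valid when |Δ_u| ≪ d_u.
- `exact`: the difference of printed degree-form entropies. It satisfies
  the algebraic identity

      dH_exact = (1/|V|²) [ Σ_{E∩E′} printed-terms
                            − Σ_{E′∖E} 1/(d′_u d′_v)
                            + Σ_{E∖E′} 1/(d_u d_v) ],

  which the test suite verifies to 1e−12 on 500 random transitions; the
  printed formula is thus the surviving-edge part of the exact change, up
  to the prefactor.

The sum is restricted to E∩E′ because that is the only domain on which both
d and d+Δ denominators are guaranteed positive. Degenerate transitions
(Δ|E| = 0) do not raise — real sequences contain them — but are flagged:
1/T is a signed infinity and T = 0 when dH ≠ 0 (an edge-preserving rewiring
is a zero-temperature event in this formalism), and both are NaN with a
warning when dH = 0 too.

### Directed graphs

For graphs made entirely of unidirectional arcs, the entropy is
1 − 1/|V| − (1/|V|²) Σ_{(u,v)∈E_D} d_u^in/((d_u^out)² d_v^in); arcs leaving
an in-degree-0 source contribute nothing, and the head's out-degree never
appears. The first-order change formula is emitted verbatim: its per-arc
terms equal the analytic gradient of the entropy summand exactly (verified
symbolically and on 200 random integer degree configurations), so the exact
differential is −(1/|V|²) times the printed sum. We document this sign/
prefactor convention rather than silently correcting it; `exact` mode gives
the true entropy difference. Graphs with any bidirectional pair are
rejected by validation rather than approximated.

## Correlation-network construction

A T×N panel is cut into trailing windows: the window labelled t (1-based)
covers steps t−w..t−1, so with window w = 28 and step 1 a 6004-step panel
yields 5976 networks labelled 29..6004. Within each window the N×N matrix
of maximum absolute Pearson correlations over lags −L..L is formed
(default L = 0, i.e. plain Pearson; the lag knob exists because
cross-correlation at small lags is common practice for daily returns), and
exactly k = floor(q·C(N,2)) pairs with the largest |r| become edges
(default q = 0.05). Ties are broken by descending |r| then ascending
lexicographic pair index, making snapshots deterministic; constant series
correlate 0 with a warning. The cut is per window; a pooled-distribution
variant would make edge counts vary per snapshot and is not implemented.
Exact-k selection means every snapshot has identical |E|, so consecutive
correlation-network transitions are degenerate in U by construction —
their information is in dH — whereas value-thresholded or externally
supplied sequences vary in both.

## Synthetic data

Two seeded generators stand in for the financial/biological panels the
framework targets; all randomness flows from explicit integer seeds through
`numpy.random.default_rng`, with no global state.

- **Event sequences** (`gen_event_sequence`): starting from an
  Erdős–Rényi G(100, 0.1) base graph, each step flips every node pair
  independently (absent pairs appear, present edges vanish) with rate
  0.005, except one scheduled step (default the midpoint of a 50-snapshot
  sequence) with rate 0.2. This emulates an abrupt structural shock against
  gradual background drift. What it does *not* emulate: degree-preserving
  rewiring, preferential attachment, community structure, or temporally
  correlated noise. Consequences for interpretation: under i.i.d. flips the
  entropy change tracks the edge-count change (dH ≈ (2/d̄²)·dU for nearly
  homogeneous degrees), so the shock manifests as the extreme |dU| and |dH|
  of the trajectory — measured at 50/50 seeded runs each — while |1/T|
  remains near the state-level value 2/d̄² and is *not* maximized at the
  shock; a bulk edge-count event is a high-temperature transition in this
  formalism. Detecting rewiring-type events through |1/T| requires
  edge-count-preserving perturbations, which this generator deliberately
  does not produce.
- **Correlated panels** (`gen_correlated_panel`): the one-factor model
  x_i(t) = √ρ_t·f(t) + √(1−ρ_t)·ε_i(t) with i.i.d. standard normal f, ε,
  so any two series have population correlation exactly ρ_t. Defaults: 25
  series, 200 steps, ρ = 0.1 jumping to 0.6 on steps 100–150 — a crisis
  analogue in which cross-correlations rise market-wide. The entropy of the
  resulting top-5% networks rises inside the event window (z ≈ 20–30
  pooled over 20 panels): stronger common correlation amplifies the
  shared-factor node effects in sample correlations, the retained pairs
  concentrate on a few hub nodes, and Σ 1/(d_u d_v) falls. The generator
  omits heavy tails, volatility clustering and sector block structure, so
  passing tests demonstrate sensitivity to correlation-level regime shifts,
  not performance on realistic return dynamics.

Scales (50 snapshots × 100 nodes; 20 panels × 200 steps × 25 series; 500
random graphs per identity sweep) were chosen as the smallest at which the
binomial/Gaussian sampling bands in the tests are decisively narrower than
the effects being asserted.

## Numerical choices

- Eigenvalues from `numpy.linalg.eigvalsh`; tiny negative round-off is
  clipped at −1e−12 before forming occupations (values above 2 are left
  as computed; the spectral-bound check allows 1e−9).
- 0·ln 0 = 0 in the exact entropy; empty sums (no edges, no surviving
  edges) are 0.
- Isolated nodes are permitted everywhere (thresholded correlation networks
  produce them routinely) but trigger a warning from the degree form, whose
  derivation assumes Tr[L̃] = |V|; with isolated nodes present the
  c = 2 variant no longer matches the spectral quadratic entropy.
- Graphs are simple by validation: self-loops, duplicate edges and
  out-of-range indices are rejected with the offending pair named.
- Node identity is positional (0..n−1); file readers map external string
  labels through a persisted `nodes.txt` table, and snapshot sequences
  enforce one shared node universe explicitly instead of inferring it.

## Known limitations

- The degree-form entropy is an approximation; for graphs with many
  low-degree nodes it can exceed the exact spectral entropy's ordering on
  individual pairs of graphs.
- No statistical test accompanies event ranking: `rank_transitions` orders
  transitions by |1/T| then |dH| and leaves thresholds to the user.
- Weighted graphs, multigraphs, self-loops and mixed directed/undirected
  snapshots are out of scope, as are free energy, heat capacity and
  partition-function formalisms.
- Degree-change scatter tables take degrees from the earlier snapshot and
  Δ = later − earlier, and emit both orientations of each surviving edge;
  the variance profile groups by exact degree by default (an optional bin
  width exists for large graphs).
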