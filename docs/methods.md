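# Methods

## Model

SGII scores essentiality of long noncoding RNAs on a heterogeneous
lncRNA–protein–protein interaction (LPPI) graph `G = (V, E)`: undirected,
unweighted, with typed nodes and two edge types (lncRNA–protein,
protein–protein; the input formats cannot express lncRNA–lncRNA edges).
The method assumes (i) essential lncRNAs occupy hub-like positions in the
LPPI network, as essential coding genes do in PPI networks, and (ii) where
interaction knowledge is too sparse for topology to be informative, sequence
composition still carries an essentiality signal.

### Centralities

All four measures are computed on the **full** graph — protein nodes and
dummy lncRNAs included — because those nodes shape shortest paths, degrees
and the adjacency spectrum even though only scoreable lncRNAs are ranked:

- degree: `d_i = s_i / (n−1)`, `s_i` the raw degree;
- betweenness: `b_i = 1/((n−1)(n−2)) Σ_{u≠i≠v} σ_uv(i)/σ_uv` over ordered
  pairs, hop-count shortest paths, disconnected pairs contributing 0. The
  ordered-pair reading makes the stated normalizer fill `[0, 1]` (a star's
  hub scores exactly 1); the unordered reading would cap at 0.5;
- closeness: the reachable-set-corrected form
  `c_i = (|R(i)|−1)² / ((n−1)·Σ_{j∈R(i)} d_ij)`, well defined on
  disconnected graphs; isolated nodes score 0;
- eigenvector: the non-negative (Perron) eigenvector of the adjacency
  matrix with `‖x‖₂ = 1`. The norm is taken as Euclidean; that choice is
  checkable against the closed-form star solution (hub `1/√2`, leaves
  `1/(2√2)`, λ_max = 2).

Degree, betweenness and closeness are delegated to networkx (Brandes
betweenness with `normalized=True` is algebraically identical to the
ordered-pair form above; closeness uses `wf_improved=True`). The
eigenvector is computed by power iteration on the *shifted* matrix `A + I`
(tolerance 1e-9 on the L2 step difference, cap 1000 iterations, uniform
positive start): the shift makes the dominant eigenvalue strictly largest
in magnitude, so the iteration converges on bipartite(-like) graphs where
`−λ_max` is also an eigenvalue, without changing eigenvectors.
Non-convergence raises an error reporting the residual. On disconnected
graphs the vector concentrates on the component with the largest
eigenvalue; entries elsewhere are ≈ 0 and are accepted as such. Tiny
negative rounding noise is clipped to 0.

### Sequence score (GIC)

`θ = β₀ + β₁·L + β₂·(e/L) + Σ_{i=1..5} αᵢ·fᵢ`, `g = 1/(1+exp(−θ))`.
Coefficients are the published mouse and human sets, taken as fixed (no
refitting). Choices:

- the folding-energy term is read as `β₂·(e/L)` — length-normalized MFE.
  MFE scales roughly linearly with length, so `e/L` is the standard
  normalization; the alternative reading `β₂/(L·e)` diverges as `e → 0`.
  The term is isolated in one function so the alternative is a one-line
  change; no printed worked example exists to discriminate the two;
- triplet frequencies use overlapping windows with denominator `L−2`
  (the window count), matching the magnitude of the printed α values;
- sequences are uppercased and U→T-normalized before counting; characters
  outside A/C/G/T/U are errors naming the offending position;
- the logistic is evaluated with an overflow-safe split; `g` saturates to
  exactly 1.0 in double precision for θ ≳ 37, which is why **ranking uses
  θ, not g** — the order is identical (the logistic is strictly monotone)
  but θ keeps resolution where g saturates.

MFE backends are pluggable. The default `SurrogateMFE` is a deterministic
GC-content proxy, `e = −0.15·(#G + #C)` kcal/mol: fast, dependency-free,
right sign and rough length scaling — adequate wherever only the *relative*
ordering of scores matters (tests, synthetic benchmarks). `RNAfoldMFE`
shells out to ViennaRNA's RNAfold for real energies. Sequences of length
≥ 20 000 nt are never folded: the lncRNA becomes a dummy node (as does one
with no FASTA record, since no GIC is computable for it).

### Decision rule

Ranks are 1-based, descending, computed **within the scoreable-lncRNA set**
of size N; ties break by lexicographic id for cross-platform
reproducibility. The rank universe is the scoreable set rather than all
nodes: proteins and dummies have no GIC score and are never called, and
including them would silently rescale the percentage thresholds k and t.
Indicators use the strict inequality `rank/N < threshold/100`; in a
degenerate universe of one, `1/1 < 1` is false, so nothing is called.

The gate compares the **raw degree** `s_i` on the full heterogeneous graph
(not degree centrality) against z. On the centrality branch the call is the
product of the configured subset's indicators (default all four); an empty
subset routes every scoreable lncRNA to the GIC branch (pure sequence
mode). Published presets: mouse z=15, k=5, t=9; human z=5, k=20, t=5.

### Evaluation and calibration

`s = n_t/n_+`, `r = n_f/n_−`, `f = −log₁₀ p` with p the one-sided
(upper-tail hypergeometric) Fisher's exact p of the 2×2 table
`[[n_t, n_+−n_t], [n_f, n_−−n_f]]`. One-sidedness is the enrichment
question — are known essentials over-represented among the calls — and
reproduces the published mouse headline p = 5.73×10⁻⁹ from its printed
counts, which a two-sided reading does not guarantee at the printed
precision. p is computed with scipy's hypergeometric survival function
(accurate to p ≈ 1e-300) and clamped away from 0 before the log.

Calibration sweeps every `(z, k, t)` cell (standard grids: z ∈ {5,10,15,20},
k and t ∈ {1,3,5,7,9} mouse-style or {5,10,15,20,25} human-style),
maximizing f alone; sensitivity and FPR are reported but not part of the
objective. Ties break deterministically toward the smallest z, then k,
then t. No train/test split or multiple-testing correction across cells is
applied — the known-essential sets are far too small for cross-validation,
and f is a descriptive quality score, not an inference.

## Synthetic benchmark

The generator emulates the structure the method relies on, not any
particular database release:

- PPI: Barabási–Albert preferential attachment (200 proteins, 2 edges per
  arrival) — heavy-tailed protein degrees;
- LPI: each of 2000 lncRNAs attaches to distinct proteins chosen with
  probability ∝ (PPI degree + 1); partner counts are Zipf(2.5) truncated at
  15, so the lncRNA degree histogram is approximately power-law (log-log
  slope negative, |Pearson r| > 0.9 on the default fixture);
- 20 planted essentials get partner counts uniform in [25, 45] — above the
  mouse gate z=15 — *and* sequences with the four positively weighted
  triplets (CGA, GCG, TCG, ACG) planted at ≈3× the background window rate,
  so each decision branch is independently exercisable;
- ordinary sequences are i.i.d. uniform A/C/G/T of length 200–2500 nt; 2%
  of non-essential lncRNAs get 20 001–25 000 nt sequences to exercise the
  dummy-node path;
- one seeded `numpy.random.Generator` drives everything, so a fixed seed
  reproduces byte-identical files.

What passing on this fixture shows — and does not. It validates the
plumbing and the decision logic end to end: planted hubs with enriched
sequences are recovered essentially perfectly (the benchmark saturates at
sensitivity 1.0, FPR 0 at the calibrated optimum, f ≈ 47). Real data are
much harder: real essential lncRNAs are not guaranteed to be hubs, GIC
separates far less cleanly than a 3× planted enrichment, interaction
catalogs are incomplete and biased, and the surrogate MFE is not a folding
energy. Benchmark numbers therefore say nothing quantitative about
performance on real networks; the published-count Fisher statistics are
reproduced exactly, but re-deriving the underlying calls would require the
full public datasets.

## Numerical and degenerate-input choices

- Merging is idempotent and edge-order independent; duplicate edges and
  self-interactions are dropped at merge; id matching is case-sensitive
  (silent case-folding can merge distinct genes).
- Centralities require n ≥ 2 (degree, closeness) or n ≥ 3 (betweenness);
  eigenvector requires ≥ 1 edge.
- `rank_descending` rejects NaN scores and empty maps.
- Fisher counts are validated (`0 ≤ n_t ≤ n_+`, `0 ≤ n_f ≤ n_−`, non-empty
  universe); labels outside the scoreable universe are dropped with a
  warning (they were unscoreable, so no call exists for them).
- Problem sizes used by the default test run and the acceptance script:
  the 2000-lncRNA benchmark fixture once per session (~10 s of centrality
  computation), 100-cell calibration grids, 50 brute-force-checked random
  graphs of ≤ 12 nodes.

## Known limitations

- The surrogate MFE is a composition proxy, not a thermodynamic energy;
  absolute θ values under it are not comparable to RNAfold-based ones.
- Power iteration reports a single dominant eigenvector; on graphs with
  (near-)tied component eigenvalues the result mixes components.
- No id mapping across gene-naming systems: inputs must already share
  protein names, and lncRNA/protein namespaces must be disjoint.
- The centrality subset is a configuration, not a learned weighting; with
  so few known essentials, learning weights is deliberately out of scope.
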