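# Methods

## Objects

**Tree shapes.** The atomic object is an unlabeled rooted strictly bifurcating
tree considered up to isomorphism. Shapes are held in a canonical interned
form: the children of every internal node are ordered by
(subtree leaf count, canonical key), and the canonical key is the unlabeled
newick string of that ordering. Any total order would do; this one makes the
caterpillar's key minimal and is cheap to maintain. Interning means two
isomorphic trees are the *same* Python object, so isomorphism tests, set
membership and hashing during graph construction are O(1).

**Shape spaces.** `enumerate_shapes(l)` generates every isomorphism class by
the recursion "a shape on *l* > 1 leaves is an unordered pair of shapes on
*k* and *l* − *k* leaves, 1 ≤ *k* ≤ *l*/2", and sorts the result
lexicographically by canonical key. The sizes follow the
Wedderburn–Etherington recurrence, which `count_shapes` implements separately
as a cross-check. The sorted order is what fixes the coordinate system of
every vector and matrix, and it is identical across runs and platforms; the
resolutions themselves are invariant under any consistent reindexing.

## Statistics

All statistics derive from one post-order pass collecting leaf depths
*N<sub>j</sub>*, internal-node subtree heights *M<sub>j</sub>*, and left/right
leaf counts (*r*, *s*) per internal node. Conventions that needed fixing:

* Inside each formula *n* is the number of leaves of the tree (not the number
  of trees in a space).
* `colless` = 2/((*n*−1)(*n*−2)) · Σ|*r*−*s*|, so it is 0 on the maximally
  balanced shape and 1 on the caterpillar. `sackin` is the *mean* leaf depth.
  The raw sums are exposed separately as `colless_raw` and `sackin_raw`
  because optimal-combination coefficients depend on the normalization (see
  below); scaled resolutions do not, being affine-invariant.
* `i2` averages |*r*−*s*|/(*r*+*s*−2) over internal nodes with more than two
  descendant leaves, normalized by 1/(*n*−2). Every qualifying node of a
  caterpillar contributes exactly 1, so *I₂*(caterpillar) = 1 at every size.
* `b1` sums 1/*M<sub>j</sub>* over internal nodes **excluding the root**
  (the Shao–Sokal convention). With the root included the published
  Laplacian-resolution table is not reproduced; excluding it, every entry
  matches to 5 × 10⁻⁵.
* `b2` sums *N<sub>j</sub>*/2^*N<sub>j</sub>* over leaves.

`statistic_vector` evaluates a statistic over a whole space and validates
non-constancy eagerly, since the centered unit vector
*x<sub>f</sub>* = *H y<sub>f</sub>*/‖*H y<sub>f</sub>*‖ is undefined for a
constant statistic.

## NNI moves and the Cayley graph

An NNI move acts on an internal edge (parent *u*, internal child *v*): the
sibling of *v* is exchanged with one of *v*'s children, giving two candidate
rearrangements per internal edge — the rooted-tree reading of the move, with
at most 2(*l*−2) neighbors. Moves that produce a shape isomorphic to the
source are dropped, so the graph is simple. Construction verifies that every
generated neighbor exists in the enumerated space and that the directed edge
set is symmetric; both would fail loudly on an enumeration/move mismatch.
The graph is connected for every leaf count tested (4–17), which the distance
and spectral code asserts rather than assumes.

All-pairs NNI distances are computed by breadth-first search from every
vertex over the CSR adjacency, in a numba kernel (the pure-scipy path was the
pipeline bottleneck at 24 631 vertices), stored as int16 — diameters are
tiny (12 at *l* = 17). The squared-distance matrix *D<sub>s</sub>* is never
materialized in float64 at large sizes: quadratic forms and operator products
against −½*D<sub>s</sub>* are evaluated blockwise from the integer matrix,
which is exact (the squares are small integers) and keeps peak memory at one
row block.

## Resolutions, bounds, scaling

*R<sub>D</sub>*(*f*) = −½ *x<sub>f</sub>*ᵗ*D<sub>s</sub>x<sub>f</sub>*
(higher better) and *R<sub>L</sub>*(*f*) = *x<sub>f</sub>*ᵗ*L x<sub>f</sub>*
(lower better) are Rayleigh quotients, bracketed by extreme eigenvalues:

* for *X<sub>D</sub>* = −½*H D<sub>s</sub> H*: the extremes on the centered
  subspace. *X<sub>D</sub>* annihilates the constant vector exactly, so the
  dense path (used below 3000 shapes) removes one copy of that zero
  eigenvalue — in practice moot, because the centered spectrum straddles zero
  at every size tested. Above that, Lanczos iteration on a matrix-free
  centered operator finds both extremes.
* for *L*: the lower bound is the Fiedler value (second-smallest eigenvalue;
  the smallest, 0, belongs to the constant vector, which centering removes).
  Small graphs are solved densely. For large graphs the Fiedler value is
  computed by LOBPCG constrained against the constant vector with a Jacobi
  (inverse-degree) preconditioner, i.e. deflation of the known null vector;
  shift-invert factorization was tried first and abandoned — the Cayley
  graph's sparsity pattern causes catastrophic LU fill-in. The LOBPCG path
  matches dense eigendecomposition to 10⁻⁸ where both are feasible, and a
  numerically zero Fiedler value is treated as an error (disconnected graph).
  The eigensolver start vector is drawn from a fixed-seed generator so
  results are bit-reproducible run to run.

Scaled resolution is (raw − min)/(max − min) ∈ [0, 1]; each function keeps
its own orientation (no flipping), so rankings read "higher better" for
*R<sub>D</sub>* and "lower better" for *R<sub>L</sub>*. Tolerances: dense
eigensolves are exact to LAPACK precision; iterative solves use tolerance
10⁻⁹–10⁻¹⁰, far below the 3–4 decimals of any reported table.

`mds_embed` is classical (Torgerson) MDS — rows of *V*Λ^½ from the top
nonnegative eigenpairs of *X<sub>D</sub>* — with zero-padding when fewer
positive eigenvalues exist than requested dimensions. The CLI `embed`
command attaches each shape's statistic value and its quartile class
(lower/inter/upper quartile) for the standard three-color tree-space plot.

## Optimal combinations

For centered raw vectors ŷ<sub>f</sub>, ŷ<sub>g</sub> and quadratic form *A*
(*X<sub>D</sub>* or *L*), the resolution of λ*f* + *g* is
R(λ) = v(λ)ᵗA v(λ)/v(λ)ᵗv(λ) with v(λ) = λŷ<sub>f</sub> + ŷ<sub>g</sub>.
Both numerator and denominator are quadratics in λ, so stationarity
(f′g = g′f) reduces to

  (aq − bp)λ² + (ar − cp)λ + (br − cq) = 0,

with a, b, c the *A*-forms and p, q, r the Gram entries of the two vectors.
The root with the better objective wins (ties toward smaller |λ|); the
discriminant is reported and checked nonnegative (numerically — across all
statistic pairs and sizes tested it always is, consistent with the quotient
of quadratics having real critical points). Degenerate inputs — centered
vectors (nearly) parallel, Gram determinant below 10⁻¹² relative — raise
rather than returning an arbitrary λ. A closed-form solution is also
cross-checked in the test suite against an independent dense grid search
with local refinement.

**Normalization convention.** The scaled resolution of a single statistic is
affine-invariant, but λ is not: it rescales inversely with the statistics'
scale factors. The published coefficients correspond to the *unnormalized*
forms — total depth Σ*N<sub>j</sub>* for Sackin and total imbalance
Σ|*r*−*s*| for Colless (the quantities the standard R packages compute) —
not to the per-leaf normalized definitions. The package therefore forms
combinations from `sackin_raw`/`colless_raw` by default; with the normalized
forms the same scaled resolutions result but λ differs by the obvious factor.
One related asymmetry: in the Laplacian-resolution combination table the
"Saless" coefficient is conventionally stated for the orientation
λ·Colless + Sackin, the reciprocal of the defining orientation
λ·Sackin + Colless used with the geometric resolution; both orientations are
available since `optimal_lambda(f, g, ...)` puts λ on its first argument.

The **Saless index** is λ·Sackin + Colless (raw sums) with λ maximizing
*R<sub>D</sub>*. Its coefficient is positive at every size computed here
(7–17 leaves) and appears to settle near 1.3 as *l* grows; negative-λ
combinations of other pairs are flagged `plausible=False` rather than
rejected, since they optimize the resolution but mix statistics with
opposite signs.

## Random shape generators

Two classical null models, used as test fixtures:

* **Yule (equal-rates Markov):** grow from one lineage, repeatedly splitting
  a uniformly chosen extant lineage until *l* tips.
* **PDA (uniform labeled topology):** attach each new leaf to a uniformly
  chosen edge (including the root edge), which makes every labeled rooted
  binary topology equally likely; dropping labels gives each shape
  probability proportional to its number of labeled representatives.

These emulate the standard null distributions on tree shape only; they do not
model branch lengths, extinction, sampling fractions, or any rate
heterogeneity, so tests based on them certify combinatorial correctness of
the generators and enumeration, not realism of any biological process.

## Problem sizes and limits

Everything is exact enumeration, so cost is governed by the number of shapes
*n* (≈ 2.483^*l*·*l*^(−3/2)): the full Laplacian pipeline is run to
*l* = 17 (24 631 shapes; seconds for the graph, < 1 s per eigensolve) and the
distance pipeline to *l* = 13 for tables (983 shapes) and *l* = 17 for
ranking checks (all-pairs BFS ≈ 1.5 min, 1.2 GB int16). The CLI guards
dense-distance work above *l* = 14 and Laplacian work above *l* = 20 behind
`--force`. Beyond that, memory for the distance matrix is the binding
constraint, as it is for any exact treatment of this space; sampling-based
extensions are out of scope.

Known limitations: only rooted bifurcating shapes (no multifurcations, no
unrooted spaces); only the NNI metric (no SPR/TBR); combinations of more
than two statistics are not implemented.
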