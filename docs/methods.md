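# Methods

`ctgenome` analyses the arrangement of intra-chain contacts in a folded
linear polymer — a chromosome modelled as a bead-on-a-string chain at
100 kb per bead, or a Hi-C contact map — using circuit topology: the
classification of every *pair* of contacts rather than of individual
contacts. This note records the model, the parameters that matter, the
numerical choices, and what the synthetic study conditions do and do not
establish.

## Contacts

A contact is an unordered pair of beads `(i, j)` with `j >= i + 2`;
first neighbours (`|i - j| <= 1`) are never contacts, because backbone
adjacency carries no fold information. Contacts are binary and
deduplicated, as in single-cell contact maps.

Two extraction routes are supported:

* **Spatial cutoff** on a 3D chain: a contact is called when the
  Euclidean distance is `<= r_c` particle radii. Supported cutoffs are
  0.5, 1.0, 1.5 and 2.0, with 1.0 as the default; no numeric criterion
  selects among them, so `r_c` stays a free parameter. The comparison is
  inclusive (`<=`, with a 1e-9 relative epsilon) so that exact-grid
  distances in lattice chains classify deterministically.
* **Count threshold** on a Hi-C matrix: bins with counts `>= t`
  (default `t = 250`) become contacts at the bin midpoint. Upper-triangular
  storage is mirrored by the element-wise maximum; genuinely asymmetric
  matrices are rejected.

Bead indices are 0-based in the API; all files written or read by the
package use 1-based indices, stated in their headers.

## Relation algebra

Contacts are closed integer intervals. For distinct contacts
`[i, j]` and `[r, s]` the relation of the first toward the second is:

| relation | condition |
|---|---|
| CS (concerted series) | one shared site and the intervals touch only there (`i = s` or `j = r`) |
| CP / CP⁻¹ (concerted parallel) | one shared endpoint with containment (`i = r` or `j = s`); the shorter interval is CP |
| S (series) | disjoint intervals |
| P / P⁻¹ (parallel) | strict containment in the open interior (`r < i` and `j < s`) |
| X (cross) | overlap without containment |

Concerted relations take precedence whenever a site is shared; with
deduplicated contacts this makes the classification total and exclusive
(verified exhaustively against an independent set-algebra oracle over all
admissible pairs with endpoints in {0..9} and on 10⁵ random pairs).
CP keeps its orientation (CP vs CP⁻¹) to mirror P/P⁻¹; the orientation is
collapsed only in the unordered pair counts.

The topology matrix is N×N over the N contacts in chain order
(`(i, j)`-sorted); the diagonal is excluded from every statistic. The
matrix build is vectorised but must agree cell-by-cell with the scalar
classifier, which the tests enforce.

**Entangled set.** Entangled = {P, P⁻¹, X}. Concerted relations are kept
out of the default because they form their own subgroup of arrangements
(they are what the clustering coefficient detects instead); a flag
(`ENTANGLED_WITH_CP`) includes them for sensitivity analyses.

## First-order statistics

* **Entangled fraction**: entangled unordered pairs / `N(N-1)/2`,
  defined for `N >= 2`.
* **Per-contact entanglement**: entangled relations on each matrix row;
  equivalently the number of contacts entangled with that contact. The
  fraction equals `sum(rows) / (N(N-1))` since each pair sits on two rows.
* **Sequence projection**: each bead receives the summed row counts of
  the contacts it terminates (both endpoints credited, so the trace total
  is twice the row sum). Binning is by sums over fixed genomic bins
  (1 Mb standard); contact-level binning credits the bin of the *smaller*
  endpoint (the site reached first along the sequence).
* **Expression coupling**: gene abundance is summed per bin by gene
  midpoint, abundances below 50 per Mb are zeroed, and the association is
  the two-sided Pearson correlation over bins.

## Contact network

Contact sites are nodes, contacts edges; beads without contacts are
absent. Local clustering is `C_n = e_n / K_n` with
`K_n = k_n(k_n-1)/2`; nodes of degree < 2 contribute `C_n = 0` to the
unweighted average (Watts–Strogatz convention — consistent with
zero-clustering reference diagrams that contain such nodes). Triangles
correspond one-to-one with trefoil motifs (two CS contacts enveloped by a
CP contact), the loop-extrusion signature; disjoint trefoils in series
give an average of exactly 1 and shared-site-free sets exactly 0.
Connectivity is reported as mean degree `2|E|/|V|` (the quantity is not
otherwise pinned down; reports label it as such). Cells are split into
high/low clustering states at an inclusive threshold of 0.02, the
empirical boundary between the two subpopulations; the boundary is a
configuration value.

## Topological fractal dimension

The topology matrix is binarised — entangled cells to 1, everything else
(including concerted and series relations and the diagonal) to 0. Since
every off-diagonal cell holds *some* relation, the full matrix cannot
itself be the fractal set; the entangled subset is the structured object
and matches the binarised TIFF route. A flag allows the
"any non-series code" variant.

Box counting pads the matrix with zeros to the next power of two and
covers it with grids of side `l = n/2, n/4, ..., 2, 1`; `D` is the
least-squares slope of `log N(l)` vs `log(1/l)`. Scales with `N(l) = 1`
or `N(l) =` total set cells are excluded from the fit (saturation
plateaus at both ends bias the slope); sets with fewer than two
informative scales (empty or point-like) get `D = 0` with a diagnostic
warning, and a raw slope outside [0, 2] is clamped with a warning.
`D` is exactly invariant under transposition and under reflection on the
padded grid; reflecting *before* padding shifts the set against the grid
anchor and is only approximately invariant. Because `D` grows with
contact count, chromosome comparisons use `D / N`, which puts
chromosome-scale matrices (`D` in [1, 1.7], `N ~ 10³`) in the 10⁻³ decade.

## Cumulative scans

Windows grow from either chain end in 5-bead (0.5 Mb) steps, always
ending at the full chain; a window keeps only contacts with *both*
endpoints inside (a contact is a property of the sub-chain). Windows
with fewer than 2 contacts yield NaN. The series is smoothed by a local
degree-2 least-squares polynomial over a 15-sample window whose fit
window shrinks symmetrically at the edges — so constants and exact
quadratics pass through unchanged. The 15 samples correspond to the
series' natural sampling (a literal 15-bead span would cover only 3
samples, on which a degree-2 fit is the identity, i.e. no smoothing).
Local maxima are selected by topographic prominence (default 0.2 on the
[0, 1] entangled-fraction scale); consecutive peak spacings are
histogrammed at 10-bead width and the mode is the mean spacing in the
most populated bin (earliest bin on ties). Convergence of the
fractal-dimension series is the smallest window beyond which every later
value stays within a relative 0.05 of the full-chain value (the tolerance
is a package choice, reported with the result); a series that never
settles returns the chain length flagged `converged=False`.

## L-patterns

A contact's L-pattern length is the number of entangled codes on its row
*to the right of the diagonal*, attributing each entangled pair to its
earlier contact; lengths therefore sum to the entangled pair count, an
identity the tests check against the oracle. *Turns* are contacts whose
L-pattern length is at least 2 (the canonical loop's third turn envelops
one pocket strictly but also carries a cross stripe, so length — not
strict parallel envelope count — is the operative criterion). Turns
adjacent in chain order, each directly enveloping the next, form one turn
group; each group heads one nested L-pattern, and a non-turn contact
between them breaks the group. Segment barcodes split the chain into
equal-bead segments (remainder to the last) and credit each contact's
length to the segment of its smaller endpoint, mirroring the binning
rule. The quantile split of nonzero lengths puts an odd count's median
element in the upper set.

## Synthetic study conditions

* **Lattice random chain**: a random walk on the unit grid (one particle
  = 100 kb) confined to a box, starting at a uniform in-box site; a step
  may not reverse the previous one (no two-step folding), and the walk is
  otherwise *not* self-avoiding — revisits are what create contacts.
  Blocked walks restart from a fresh site with bounded retries (only
  degenerate boxes can block; walls are required >= 2). Box walls default
  to the per-axis extent of a reference chain.
* **Trefoil series**: triples `{(5t, 5t+2), (5t+2, 5t+4), (5t, 5t+4)}`.
  The stride of 5 keeps consecutive triples bead-disjoint — necessary for
  the exact clustering-of-1 result — while respecting the first-neighbour
  exclusion; the motif diagrams are schematic about spacing.
* **Canonical L-loop**: nine contacts on a 124-bead chain
  (c1=(0,120) ... c9=(60,70)). The exact coordinates are an artifact
  choice; every asserted property (outer length 8, three turn groups,
  27/36 entangled pairs) follows from the motif's textual constraints,
  not from the coordinates.
* **Periodic traces**: sinusoid + seeded Gaussian noise, clipped at 0,
  baseline 0.5. The length-scale recovery study uses traces of 8 periods:
  a histogram mode needs several spacings (three spacings land in three
  separate 10-bead bins and the "mode" degenerates to a single noisy
  spacing).
* **Correlated expression**: per-bin abundance is an affine map
  (mean 500, sd 100) of `rho·z + sqrt(1-rho²)·eps` with `z` the
  standardised trace; the scale keeps zero-clipping negligible so the
  planted correlation survives.

What these conditions do **not** emulate: polymer physics beyond the
two-step rule (no excluded volume, no equilibrium ensembles), sequencing
noise or coverage bias in Hi-C counts, trans-chromosomal contacts, and
the genome-specific contact statistics of real nuclei. Passing tests
establish the correctness of the algebra, the estimators and their
contracts — not biological conclusions about any particular dataset.

## Statistical reporting

Two-sample comparisons run Shapiro–Wilk per sample and Levene across
samples at alpha = 0.05, then select Student's t (normal, equal
variance), Welch's t (normal, unequal), Mann–Whitney U (non-normal,
equal) or Kolmogorov–Smirnov (non-normal, unequal); all two-sided.
The same alpha applies to diagnostics and inference. Group means carry
t-distribution 95% CIs (per-group sample sizes are small). No
multiple-testing correction is applied, and reports say so.

## Problem sizes

Default test and example runs use chains of 100–400 beads, contact sets
of up to ~1,700 contacts, 20-seed random-chain ensembles, 50-replicate
recovery studies and 500-replicate null calibrations — sizes at which
every statistic is well within its asymptotic regime while the whole
suite runs in seconds.

## Known limitations

* Box-counting on very small matrices (N below ~30 contacts) has few
  informative scales; `D` is reported but noisy there, and the
  random-vs-structured contrast is meaningful only at matched,
  chromosome-like contact counts.
* The high/low clustering threshold (0.02) and the Hi-C count threshold
  (250) are dataset-calibrated defaults, not universal constants.
* Binary single-cell contact maps cannot express bead triplets; trefoil
  detection from such maps underestimates clustering relative to 3D
  models (population maps with counts do not have this problem).
* Relations are per-chromosome; trans-chromosomal arrangement is out of
  scope.
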