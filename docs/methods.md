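# Methods

## Scope and model

`udgcoev` analyses residue co-evolution in UDG-superfamily protein
alignments and the catalytic consequences of mutating co-evolving sites,
measured by single-turnover enzyme kinetics. Alignment *computation* is out
of scope: alignments come from external aligners (or the synthetic
generator); the package ingests aligned FASTA/Clustal.

## Family curation

Sequences are sorted into families by exact, contiguous motif matching
(family 1: GQDPY; family 4: GE[A/G][V/P]G). Exact matching — no mismatch
tolerance, no profile/HMM models — reflects the diagnostic character of
these motifs; sequences matching several family motifs are binned
"ambiguous" and excluded downstream but reported, and sequences matching
none are "unclassified". This binning policy (a disjoint partition) is a
package decision; how a curation script should treat such sequences is
genuinely open and we chose the conservative option of excluding them.

Redundancy reduction is greedy single-linkage clustering at 75% identity
and 85% coverage: sequences are processed longest-first (deterministic,
and it favours full-length cluster representatives); each joins the first
cluster whose *founder* it matches at both thresholds, else founds its
own. Identity and coverage come from Biopython global alignment with
BLOSUM62, gap open/extend 11/1; identity is identical columns over
alignment length, coverage is both-residue columns over the longer
sequence's length. Cluster count is therefore monotone in the identity
threshold, and permuting the input can change representatives but never
which ids are covered.

The family reference sequence — the one whose ungapped numbering labels
every report — is the representative of the largest cluster with more than
25% identity to the family's canonical (structure-bearing) sequence,
falling back to the next-largest cluster; "similarity" is interpreted as
sequence identity.

## Alignment preparation

Columns with a gap fraction above 0.3 are removed before analysis
(configurable; 1.0 disables filtering). Only `-` counts as a gap; `X` is
an ambiguous *residue*, so it participates in gap statistics as a residue
but is excluded from frequency counts. Columns where the reference itself
is gapped are retained for the MI computation but reported without a
residue number. Internally all coordinates are 0-based; every exported
table uses 1-based reference numbering.

## Mutual information

For kept columns i, j the joint residue distribution is

    f_ij(a,b) = (λ/400 + Σ_r w_r·[a at i, b at j]) / (λ + Σ_eligible w_r)

where a row is eligible iff it has residues at both columns, λ = 0.05 is a
small pseudocount guarding against zero counts in modest alignments, and
the row weights w_r down-weight redundancy: rows are single-linkage
clustered at 62% identity (over ungapped matching positions) and each row
weighs 1/(cluster size). Both constants are exposed in the model
constructor; 0.62 and 0.05 are conventional choices in MI co-evolution
pipelines of this lineage, not values with special status here.

MI(i,j) = Σ f_ij ln[f_ij/(f_i f_j)] in nats. The marginals in this sum are
taken from the pair's own joint table (row/column sums), not the
per-column marginals: the two coincide exactly on gap-free alignments with
λ = 0, but the joint-derived form keeps MI ≥ 0 when eligibility differs
between columns. Natural-log units were chosen because the base cancels in
Z-scores and closed-form checks (a perfectly coupled 50/50 binary pair has
MI = ln 2) stay exact. Pairs with no eligible rows are flagged and carry
NaN through the matrices.

The average product correction removes the shared background that
inflates MI at variable or phylogenetically clustered columns:
MIp(i,j) = MI(i,j) − M(i)M(j)/M̄ with M(i) the mean off-diagonal MI of
column i and M̄ the grand off-diagonal mean (matrix returned unchanged if
M̄ = 0; fewer than 3 columns is an error since the column means would be
degenerate).

Significance is assessed against a permutation null: each permutation
shuffles every column independently across rows — per-column composition
is preserved, covariation destroyed — and the APC-corrected MI is
recomputed. Z(i,j) = (MIp_obs − μ_null)/σ_null with μ, σ pooled over all
off-diagonal pairs of all permutations (default 200). A pooled rather than
per-pair null matches a single normalisation applied to the whole matrix
and is stable at 200 permutations; with ~1200 column pairs per permutation
the pooled moments rest on ~2.5×10⁵ draws. The reporting threshold
defaults to Z ≥ 6.5 and is applied to the APC-corrected, Z-normalised
score (the pipeline order is MI → APC → Z → threshold). σ_null = 0 raises
an explicit degenerate-alignment error rather than producing infinities.

Per-position summaries: cumulative MI cMI(i) = Σ_j Z(i,j) over significant
pairs (the histogram height of circular co-evolution plots), and
conservation as relative entropy Σ_a f_i(a) ln[f_i(a)/q(a)] with a uniform
default background q (0 for a background-like column, ln 20 ≈ 3.0 for a
fully conserved one).

Significant pairs are tiered by Z-rank percentile *among significant pairs
only* — the circular diagram draws only reported relationships — with a
ceiling tie rule for determinism: top 5% ("top5"), down to the 70th
percentile ("mid"), remainder ("rest"). Data tables (TSV) are the
contract; the bundled matplotlib heatmap is a convenience, not a
publication-grade circular rendering.

## Kinetics

Single-turnover conditions (enzyme in excess over substrate, 100–3200 nM
vs 20 nM) make product formation first-order:
P(t) = P_max(1 − e^(−k_obs t)), fitted by Levenberg–Marquardt least
squares initialised at P_max = max(P) and k_obs = ln 2 / (time to
half-max), with 1e-10 parameter tolerances; non-convergence or k_obs ≤ 0
is a reported fit failure, not a silent NaN.

k_obs vs [E0] is fitted with the hyperbola k_obs = k2[E0]/(Km+[E0]). When
Km ≫ [E0] the hyperbola degenerates and only the efficiency k2/Km is
identifiable from the origin-line k_obs = (k2/Km)[E0] (no intercept — at
[E0] = 0 there is no turnover). The automatic fallback rule
operationalises "Km much greater than [E0]" as: fitted Km > 3×max[E0], or
SE(Km) > Km. At least 3 points spanning ≥ 4-fold in [E0] are required.

Energies use ΔΔG = −RT ln[(k2/Km)_mut/(k2/Km)_wt] with
R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and T defaulting to 333.15 K, the 60 °C
assay temperature, which also reproduces the published one-decimal ΔΔG
values from the published efficiencies. The double-mutant-cycle coupling
energy is
(ΔΔG_A + ΔΔG_B) − ΔΔG_AB; positive values mean the double mutation costs
less than additivity predicts, i.e. the sites interact. Reported tables
round to two significant figures (one decimal for ΔΔG) to match field
conventions; unrounded values are retained on the objects.

## Synthetic data

The generators mirror the conditions of the assays and datasets they stand
in for, so every stage has a known ground truth: ~200-sequence family alignments (the size that 75%/85%
clustering left per family), planted covariation, and the 13-point
single-turnover sampling schedule (2 s–60 min) over 100–3200 nM enzyme
with additive Gaussian yield noise σ = 0.02 truncated at zero (the
simplest model of fraction-cleaved gel quantification noise).

Coupled column pairs use a two-state 50/50 bijection (A/C at one column
mapped to D/E at the other) applied per row with probability equal to the
coupling parameter, else both columns draw independently from the
background. A bijection rather than a full Potts model keeps closed-form
MI targets (→ ln 2 at coupling 1) and fast tests. Motif-bearing sequence
batches derive from one random template per call, mutated outside the
motif at a configurable rate, with the motif window resampled from its
allowed sets so classification is correct by construction.

What the synthetic data does *not* emulate: phylogenetic correlation
between rows (real alignments are tree-structured; the weighting step is
exercised but not stressed), realistic indel structure, composition bias,
or multi-state couplings. Passing the planted-pair tests therefore shows
the pipeline detects covariation against an i.i.d. background, not that it
separates covariation from shared ancestry in real families — the APC and
weighting steps exist for that, and their correctness is checked
analytically rather than phylogenetically.

## Problem sizes and numerical choices

Recovery experiments use 20 seeded replicates: 200×50 alignments at 200
permutations for planted-pair recovery (the planted pair at coupling 0.9
reaches Z ≈ 25–30 against the 6.5 threshold), and the full
simulate→fit→saturate round trip for kinetics (median k2 and Km land
within a few percent of truth at σ = 0.02). Brute-force oracle equivalence
for MI is checked to 1e-10 on alignments up to 10×10, where an explicit
loop-based recount is feasible. Ties in Z-ranked pair lists break
lexicographically on (i, j); tier boundaries use a ceiling rule; all
random draws flow through `numpy.random.default_rng` seeded from the
caller.

## Known limitations

- No direct-coupling/Potts inference; MI+APC cannot distinguish direct
  from chained correlations.
- No structure-based validation of co-evolving pairs (no contact maps).
- The curation of real datasets involved manual steps (outlier removal)
  that are not algorithmic and are not reproduced.
- Only the two high-activity family motifs ship as built-ins; other
  families' motifs can be supplied as `MotifPattern` objects.
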