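"""Mutual-information co-evolution analysis with APC and permutation Z-scores.

Pipeline (for one family alignment): redundancy-aware sequence weighting ->
weighted, pseudocounted pair frequencies -> mutual information (MI, nats) ->
average product correction (APC) -> Z-score normalisation against a
column-shuffling permutation null -> thresholding (default Z >= 6.5) ->
per-position cumulative MI and conservation.

The model interface mirrors the usual statistical-modelling idiom: build a
:class:`CoevolutionModel` from an :class:`~udgcoev.alignment.Alignment`,
call :meth:`~CoevolutionModel.fit`, and read matrices, significant pairs
and tiered edges off the returned :class:`CoevolutionResults`.

Conventions
-----------
* Units are nats throughout (natural logarithm).
* Gap handling: a row gapped (or ambiguous, 'X') at either column of a
  pair is excluded from that pair's counts; there is no 21st symbol.
* The MI sum for a pair uses the marginals of that pair's own
  (pseudocounted, eligibility-filtered) joint table.  On gap-free
  alignments with no pseudocount these coincide with the per-column
  marginals; in general they keep MI non-negative.
* The permutation null shuffles each column independently across rows,
  preserving per-column composition while destroying covariation; the
  Z-score uses the pooled mean and standard deviation over all pairs and
  permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import xlogy

from udgcoev.alignment import Alignment, ColumnMap, filter_gap_columns, map_to_reference
from udgcoev.curation import AMINO_ACIDS
from udgcoev.report import EdgeList, tier_edges

N_AA = 20
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class DegenerateAlignmentError(RuntimeError):
    """The permutation null has zero variance (e.g. fully conserved rows)."""


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Integer codes (n_rows, n_columns): 0..19 residues, -1 gap or 'X'."""
    mat = aln.to_character_matrix()
    codes = np.full(mat.shape, -1, dtype=np.int64)
    for aa, k in _AA_INDEX.items():
        codes[mat == aa] = k
    return codes


def _row_identity_matrix(codes: np.ndarray) -> np.ndarray:
    """Pairwise row identity over positions where both rows have residues."""
    n, L = codes.shape
    onehot = _onehot(codes, np.ones(n))
    valid = (codes >= 0).astype(float)
    matches = onehot @ onehot.T
    both = valid @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(both > 0, matches / both, 0.0)
    return ident


def sequence_weights(aln: Alignment, clustering_identity: float = 0.62) -> np.ndarray:
    """Redundancy-down-weighting of alignment rows.

    Rows are single-linkage clustered at >= ``clustering_identity``
    pairwise identity (over ungapped matching positions); every row in a
    cluster of size k receives weight 1/k, so each cluster contributes one
    effective sequence.
    """
    codes = encode_alignment(aln)
    ident = _row_identity_matrix(codes)
    adj = csr_matrix(ident >= clustering_identity)
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    return 1.0 / sizes[labels]


def _onehot(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """(n, L*20) matrix with ``weights[r]`` at slot (r, c*20 + code)."""
    n, L = codes.shape
    out = np.zeros((n, L * N_AA))
    rows, cols = np.nonzero(codes >= 0)
    out[rows, cols * N_AA + codes[rows, cols]] = weights[rows]
    return out


@dataclass
class FrequencyModel:
    """Weighted, pseudocounted residue frequencies of an alignment.

    ``pair_counts`` holds raw weighted joint counts as an (L*20, L*20)
    matrix whose (i, j) 20x20 block is the joint count table of columns
    i and j; ``pair_table(i, j)`` returns the normalised, pseudocounted
    joint distribution.  ``marginals`` are per-column distributions
    (pseudocount λ/20 per cell).
    """

    marginals: np.ndarray            # (L, 20), each row sums to 1
    pair_counts: np.ndarray          # (L*20, L*20) raw weighted counts
    eligible_weights: np.ndarray     # (L, L) summed weights of rows valid at both columns
    pseudocount: float
    effective_count: float
    n_columns: int

    def pair_table(self, i: int, j: int) -> np.ndarray:
        lam = self.pseudocount
        block = self.pair_counts[
            i * N_AA : (i + 1) * N_AA, j * N_AA : (j + 1) * N_AA
        ]
        denom = lam + self.eligible_weights[i, j]
        if denom == 0:
            raise ZeroDivisionError(f"no eligible rows for column pair ({i}, {j})")
        return (lam / N_AA**2 + block) / denom

    @property
    def flagged_pairs(self) -> np.ndarray:
        """Boolean (L, L) mask of column pairs with zero eligible rows."""
        return self.eligible_weights == 0


def pair_frequencies(
    aln: Alignment | np.ndarray,
    weights: np.ndarray,
    pseudocount: float = 0.05,
) -> FrequencyModel:
    """Weighted pair-frequency model with low-count (pseudocount) correction.

    For columns i, j:
    f_ij(a,b) = (λ/400 + Σ_r w_r·[row r has a at i and b at j]) / (λ + Σ_eligible w_r)
    where a row is eligible iff it has a residue at both columns.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    codes = aln if isinstance(aln, np.ndarray) else encode_alignment(aln)
    n, L = codes.shape
    weights = np.asarray(weights, dtype=float)
    Xw = _onehot(codes, weights)
    X1 = _onehot(codes, np.ones(n))
    pair_counts = Xw.T @ X1
    valid = (codes >= 0).astype(float)
    validw = valid * weights[:, None]
    eligible = validw.T @ valid

    col_counts = Xw.sum(axis=0).reshape(L, N_AA)
    col_eligible = validw.sum(axis=0)
    lam = pseudocount
    with np.errstate(invalid="ignore", divide="ignore"):
        marginals = (lam / N_AA + col_counts) / (lam + col_eligible)[:, None]
    return FrequencyModel(
        marginals=marginals,
        pair_counts=pair_counts,
        eligible_weights=eligible,
        pseudocount=lam,
        effective_count=float(weights.sum()),
        n_columns=L,
    )


def mutual_information(fm: FrequencyModel) -> np.ndarray:
    """Symmetric MI matrix in nats.

    MI(i,j) = Σ_{a,b} f_ij(a,b) · ln[ f_ij(a,b) / (f_i(a)·f_j(b)) ] with the
    marginals taken from the joint table itself; zero joint entries
    contribute nothing.  Pairs with no eligible rows are NaN.
    """
    L = fm.n_columns
    lam = fm.pseudocount
    C = fm.pair_counts.reshape(L, N_AA, L, N_AA).transpose(0, 2, 1, 3)
    mi = np.empty((L, L))
    for i in range(L):
        denom = lam + fm.eligible_weights[i]  # (L,)
        ok = denom > 0
        F = np.zeros((L, N_AA, N_AA))
        F[ok] = (lam / N_AA**2 + C[i][ok]) / denom[ok, None, None]
        fa = F.sum(axis=2)
        fb = F.sum(axis=1)
        ent_joint = -xlogy(F, F).sum(axis=(1, 2))
        ent_a = -xlogy(fa, fa).sum(axis=1)
        ent_b = -xlogy(fb, fb).sum(axis=1)
        row = ent_a + ent_b - ent_joint
        row[~ok] = np.nan
        mi[i] = row
    # symmetrise against floating-point asymmetry
    mi = (mi + mi.T) / 2.0
    np.clip(mi, 0.0, None, out=mi)
    return mi


def apc_correction(mi: np.ndarray) -> np.ndarray:
    """Average product correction: MIp(i,j) = MI(i,j) − M(i)·M(j)/M̄.

    M(i) is the mean MI of column i to all others, M̄ the grand mean over
    off-diagonal pairs.  Removes the shared phylogenetic/entropy background
    that inflates MI at variable columns.  If M̄ = 0 the matrix is returned
    unchanged.
    """
    mi = np.asarray(mi, dtype=float)
    L = mi.shape[0]
    if L < 3:
        raise ValueError("APC is undefined for fewer than 3 columns")
    work = mi.copy()
    np.fill_diagonal(work, np.nan)
    col_mean = np.nanmean(work, axis=1)
    grand_mean = np.nanmean(work)
    if not np.isfinite(grand_mean) or grand_mean == 0:
        return mi.copy()
    mip = mi - np.outer(col_mean, col_mean) / grand_mean
    np.fill_diagonal(mip, 0.0)
    return mip


def _observed_mip(
    codes: np.ndarray, weights: np.ndarray, pseudocount: float
) -> np.ndarray:
    fm = pair_frequencies(codes, weights, pseudocount)
    return apc_correction(mutual_information(fm))


def zscore_normalize(
    aln: Alignment | np.ndarray,
    weights: np.ndarray,
    pseudocount: float = 0.05,
    n_permutations: int = 200,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Z-score the APC-corrected MI against a column-shuffling null.

    Each permutation independently shuffles every column's entries across
    rows (per-column residue composition preserved, covariation destroyed)
    and recomputes the APC-corrected MI.  Z uses the pooled null mean and
    standard deviation over all off-diagonal pairs of all permutations.
    Deterministic given ``seed``.
    """
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    codes = aln if isinstance(aln, np.ndarray) else encode_alignment(aln)
    n, L = codes.shape
    rng = np.random.default_rng(seed)
    mip_obs = _observed_mip(codes, weights, pseudocount)

    off = ~np.eye(L, dtype=bool)
    null_sum = 0.0
    null_sumsq = 0.0
    null_n = 0
    shuffled = codes.copy()
    for _ in range(n_permutations):
        for c in range(L):
            shuffled[:, c] = codes[rng.permutation(n), c]
        mip_perm = _observed_mip(shuffled, weights, pseudocount)
        vals = mip_perm[off]
        vals = vals[np.isfinite(vals)]
        null_sum += vals.sum()
        null_sumsq += (vals**2).sum()
        null_n += vals.size
    mu = null_sum / null_n
    var = null_sumsq / null_n - mu**2
    sigma = np.sqrt(max(var, 0.0))
    if sigma == 0:
        raise DegenerateAlignmentError(
            "permutation null has zero variance; alignment is degenerate"
        )
    z = (mip_obs - mu) / sigma
    np.fill_diagonal(z, 0.0)
    return z


def significant_pairs(
    z: np.ndarray, threshold: float = 6.5
) -> list[tuple[int, int, float]]:
    """Unordered column pairs with Z >= threshold, sorted by descending Z.

    Ties are broken lexicographically on (i, j).
    """
    L = z.shape[0]
    hits = []
    for i in range(L):
        for j in range(i + 1, L):
            if np.isfinite(z[i, j]) and z[i, j] >= threshold:
                hits.append((i, j, float(z[i, j])))
    hits.sort(key=lambda t: (-t[2], t[0], t[1]))
    return hits


def cumulative_mi(z: np.ndarray, threshold: float = 6.5) -> np.ndarray:
    """Per-position cumulative MI: cMI(i) = Σ_j Z(i,j) over Z(i,j) >= threshold.

    The histogram height of the circular (Circos-style) co-evolution plot.
    """
    zz = np.where(np.isfinite(z), z, -np.inf)
    np.fill_diagonal(zz, -np.inf)
    mask = zz >= threshold
    return np.where(mask, zz, 0.0).sum(axis=1)


def conservation(
    aln: Alignment | np.ndarray,
    weights: np.ndarray,
    background: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-column conservation as relative entropy to a background, in nats.

    conservation(i) = Σ_a f_i(a) · ln[f_i(a)/background(a)], gaps excluded
    and no pseudocount.  Default background is uniform over the 20 residues
    (score 0 for a background-distributed column, ln 20 for full
    conservation).
    """
    codes = aln if isinstance(aln, np.ndarray) else encode_alignment(aln)
    if background is None:
        background = np.full(N_AA, 1.0 / N_AA)
    background = np.asarray(background, dtype=float)
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background must sum to 1")
    fm = pair_frequencies(codes, np.asarray(weights, dtype=float), pseudocount=0.0)
    f = fm.marginals
    if np.any((f > 0) & (background[None, :] == 0)):
        raise ValueError("background is zero where observed frequency is positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = xlogy(f, f / background[None, :])
    return np.nansum(terms, axis=1)


class CoevolutionModel:
    """Co-evolution analysis of one protein-family alignment.

    Parameters
    ----------
    alignment
        The family multiple sequence alignment.
    reference_id
        Row whose ungapped numbering labels reported positions.  Defaults
        to the alignment's ``reference_id`` if set.
    max_gap_fraction
        Columns with a higher gap fraction are dropped before analysis
        (default 0.3).
    clustering_identity
        Row-weighting cluster threshold (default 0.62).
    pseudocount
        Low-count correction λ shared across pair tables (default 0.05).
    background
        Residue background for the conservation score; uniform by default.
    """

    def __init__(
        self,
        alignment: Alignment,
        reference_id: Optional[str] = None,
        max_gap_fraction: float = 0.3,
        clustering_identity: float = 0.62,
        pseudocount: float = 0.05,
        background: Optional[np.ndarray] = None,
    ) -> None:
        if reference_id is not None:
            alignment = Alignment(alignment.records, reference_id=reference_id)
        self.alignment = alignment
        self.max_gap_fraction = max_gap_fraction
        self.clustering_identity = clustering_identity
        self.pseudocount = pseudocount
        self.background = background
        self.filtered, self.column_map = filter_gap_columns(alignment, max_gap_fraction)

    def fit(
        self,
        n_permutations: int = 200,
        threshold: float = 6.5,
        seed: Optional[int] = None,
    ) -> "CoevolutionResults":
        """Run the full MI -> APC -> Z -> threshold pipeline."""
        codes = encode_alignment(self.filtered)
        weights = sequence_weights(self.filtered, self.clustering_identity)
        fm = pair_frequencies(codes, weights, self.pseudocount)
        mi = mutual_information(fm)
        mip = apc_correction(mi)
        z = zscore_normalize(
            codes, weights, self.pseudocount, n_permutations, seed
        )
        pairs = significant_pairs(z, threshold)
        return CoevolutionResults(
            model=self,
            weights=weights,
            frequency_model=fm,
            mi=mi,
            mip=mip,
            zscores=z,
            threshold=threshold,
            n_permutations=n_permutations,
            seed=seed,
            pairs=pairs,
            cmi=cumulative_mi(z, threshold),
            conservation=conservation(codes, weights, self.background),
        )


@dataclass
class CoevolutionResults:
    """Fitted co-evolution matrices, significant pairs and annotations."""

    model: CoevolutionModel
    weights: np.ndarray
    frequency_model: FrequencyModel
    mi: np.ndarray
    mip: np.ndarray
    zscores: np.ndarray
    threshold: float
    n_permutations: int
    seed: Optional[int]
    pairs: list[tuple[int, int, float]]
    cmi: np.ndarray
    conservation: np.ndarray
    _edges: Optional[EdgeList] = field(default=None, repr=False)

    @property
    def column_map(self) -> ColumnMap:
        return self.model.column_map

    @property
    def edges(self) -> EdgeList:
        """Significant pairs tiered as in the circular co-evolution plot."""
        if self._edges is None:
            self._edges = tier_edges(
                self.pairs,
                column_map=self.column_map,
                conservation=self.conservation,
                cmi=self.cmi,
            )
        return self._edges

    @property
    def effective_sequences(self) -> float:
        return float(self.weights.sum())

    def top_pair(self) -> Optional[tuple[int, int, float]]:
        off = ~np.eye(self.zscores.shape[0], dtype=bool)
        if not np.any(np.isfinite(self.zscores[off])):
            return None
        masked = np.where(off & np.isfinite(self.zscores), self.zscores, -np.inf)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        i, j = int(min(i, j)), int(max(i, j))
        return i, j, float(self.zscores[i, j])

    def summary(self) -> str:
        aln = self.model.filtered
        lines = [
            "Co-evolution analysis summary",
            "=" * 48,
            f"rows:                 {aln.n_rows}",
            f"columns analysed:     {aln.n_columns}"
            f" (of {self.model.alignment.n_columns},"
            f" max gap fraction {self.model.max_gap_fraction})",
            f"effective sequences:  {self.effective_sequences:.1f}",
            f"pseudocount:          {self.model.pseudocount}",
            f"permutations:         {self.n_permutations} (seed {self.seed})",
            f"Z threshold:          {self.threshold}",
            f"significant pairs:    {len(self.pairs)}",
        ]
        if self.pairs:
            lines.append("")
            lines.append("pos_i  pos_j       Z   tier")
            for e in self.edges.edges[:10]:
                lines.append(
                    f"{str(e.ref_pos_i):>5}  {str(e.ref_pos_j):>5}  {e.z:6.2f}   {e.tier}"
                )
            if len(self.pairs) > 10:
                lines.append(f"... {len(self.pairs) - 10} more")
        return "\n".join(lines)

    def to_tsv(self, out_dir: str | Path) -> dict[str, Path]:
        """Write MI/MIp/Z matrices and the tiered edge report as TSVs."""
        from udgcoev.report import export_report

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, mat in (("mi", self.mi), ("mip", self.mip), ("zscores", self.zscores)):
            p = out_dir / f"{name}.tsv"
            np.savetxt(p, mat, delimiter="\t", fmt="%.10g")
            paths[name] = p
        paths.update(export_report(self.edges, self.column_map, out_dir))
        return paths

    def plot(self, ax=None):
        """Heatmap of Z-scores with significant pairs marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.zscores, cmap="viridis")
        ax.figure.colorbar(im, ax=ax, label="Z")
        for i, j, _ in self.pairs:
            ax.plot(j, i, "r.", markersize=4)
        ax.set_xlabel("alignment column")
        ax.set_ylabel("alignment column")
        ax.set_title("APC-corrected MI Z-scores")
        return ax
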