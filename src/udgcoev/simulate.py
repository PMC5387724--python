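"""Synthetic alignments, motif-bearing sequences, and noisy kinetics data.

Everything the pipeline consumes can be generated here with known ground
truth: family alignments with planted covarying column pairs (for the MI
stage), motif-carrying sequence batches (for the curation stage), and
first-order progress curves over the single-turnover enzyme-concentration
range 100–3200 nM (for the kinetics stage).  All generators are
deterministic given their seed.

Defaults mirror the real assay and dataset conditions: ~200-sequence × ~200-column family
alignments; a 13-point sampling schedule from 2 s to 60 min; Gaussian
yield noise with σ = 0.02 (fraction-cleaved units), truncated at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from udgcoev.alignment import Alignment, _aligned_record
from udgcoev.curation import AMINO_ACIDS, MotifPattern, SequenceRecord, SequenceSet
from udgcoev.kinetics import ProgressCurve

#: Sampling schedule of the single-turnover assay: 2 s .. 60 min.
DEFAULT_TIMEPOINTS_S = np.array(
    [2, 5, 10, 30, 60, 150, 300, 600, 900, 1500, 1800, 2400, 3600], dtype=float
)

#: Enzyme-excess titration, 100 nM to 3200 nM in doubling steps (molar).
DEFAULT_E0_M = np.array([100e-9, 200e-9, 400e-9, 800e-9, 1600e-9, 3200e-9])


@dataclass
class CoupledAlignmentSpec:
    """Recipe for an alignment with planted covarying column pairs.

    ``coupled_pairs`` lists (i, j, coupling): with probability equal to
    ``coupling`` a row draws the two positions jointly from a fixed
    two-state bijection (the state at i determines the residue at j),
    otherwise both are drawn independently from the background.  Coupling
    1 is a deterministic pairing; 0 is independence.
    """

    n_rows: int = 200
    n_columns: int = 200
    coupled_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    background: Optional[np.ndarray] = None   # (20,) or (n_columns, 20)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_columns < 2:
            raise ValueError("alignment must have at least 2 rows and 2 columns")
        seen: set[int] = set()
        for i, j, c in self.coupled_pairs:
            if i == j:
                raise ValueError("coupled positions must be distinct")
            if not (0 <= i < self.n_columns and 0 <= j < self.n_columns):
                raise ValueError(f"coupled pair ({i}, {j}) out of range")
            if not (0.0 <= c <= 1.0):
                raise ValueError("coupling must lie in [0, 1]")
            if i in seen or j in seen:
                raise ValueError("coupled pairs must not share positions")
            seen.update((i, j))


def generate_coupled_alignment(spec: CoupledAlignmentSpec) -> Alignment:
    """Draw an ungapped alignment with the planted covariation of ``spec``.

    Uncoupled columns are i.i.d. from the background distribution.  Each
    coupled pair uses a two-state 50/50 bijection (A/C at i mapped to D/E
    at j), so a fully coupled pair has MI → ln 2 in the large-row limit.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_rows, spec.n_columns
    if spec.background is None:
        bg = np.full((L, 20), 1.0 / 20)
    else:
        bg = np.asarray(spec.background, dtype=float)
        if bg.ndim == 1:
            bg = np.tile(bg, (L, 1))
        if bg.shape != (L, 20):
            raise ValueError("background must have shape (20,) or (n_columns, 20)")
        if not np.allclose(bg.sum(axis=1), 1.0):
            raise ValueError("background rows must sum to 1")

    codes = np.empty((n, L), dtype=np.int64)
    for c in range(L):
        codes[:, c] = rng.choice(20, size=n, p=bg[c])

    # two-state bijection: state 0 -> (A at i, D at j); state 1 -> (C, E)
    state_i = (AMINO_ACIDS.index("A"), AMINO_ACIDS.index("C"))
    state_j = (AMINO_ACIDS.index("D"), AMINO_ACIDS.index("E"))
    for i, j, coupling in spec.coupled_pairs:
        coupled_rows = rng.random(n) < coupling
        states = rng.integers(0, 2, size=n)
        codes[coupled_rows, i] = np.take(state_i, states[coupled_rows])
        codes[coupled_rows, j] = np.take(state_j, states[coupled_rows])

    records = [
        _aligned_record(f"seq{r:04d}", "".join(AMINO_ACIDS[k] for k in codes[r]))
        for r in range(n)
    ]
    return Alignment(records)


def generate_family_sequences(
    motif: MotifPattern,
    n: int = 100,
    length: int = 200,
    substitution_rate: float = 0.3,
    seed: Optional[int] = None,
) -> SequenceSet:
    """Random family members each carrying one embedded motif instance.

    Sequences derive from a common random template mutated outside the
    motif at ``substitution_rate`` per position; the motif window is
    sampled uniformly from its allowed-residue sets, so every output
    matches the motif exactly and rate 0 yields near-identical sequences.
    """
    if length < len(motif):
        raise ValueError("sequence length shorter than the motif")
    if not (0.0 <= substitution_rate <= 1.0):
        raise ValueError("substitution_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    template = rng.integers(0, 20, size=length)
    start = int(rng.integers(0, length - len(motif) + 1))
    out = SequenceSet()
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for k in range(n):
        codes = template.copy()
        mutate = rng.random(length) < substitution_rate
        codes[mutate] = rng.integers(0, 20, size=int(mutate.sum()))
        residues = bytearray(aa[codes].tobytes())
        for p, allowed in enumerate(motif.pattern):
            choice = sorted(allowed)[int(rng.integers(0, len(allowed)))]
            residues[start + p] = ord(choice)
        out.add(
            SequenceRecord(
                id=f"{motif.family_label}_{k:04d}",
                residues=residues.decode(),
                description=f"synthetic {motif.family_label} member",
            )
        )
    return out


@dataclass
class KineticSimSpec:
    """Ground-truth kinetics for simulated single-turnover experiments."""

    k2: float                                    # s⁻¹
    Km: float                                    # molar
    e0_list: Sequence[float] = tuple(DEFAULT_E0_M)
    timepoints: Sequence[float] = tuple(DEFAULT_TIMEPOINTS_S)
    noise_sd: float = 0.02                       # yield units
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k2 <= 0 or self.Km <= 0:
            raise ValueError("k2 and Km must be positive")
        if any(e <= 0 for e in self.e0_list):
            raise ValueError("enzyme concentrations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def k_obs(self, e0: float) -> float:
        return self.k2 * e0 / (self.Km + e0)


def simulate_progress_curves(spec: KineticSimSpec) -> list[ProgressCurve]:
    """Noisy first-order progress curves, one per enzyme concentration.

    P(t) = 1 − e^(−k_obs t) + N(0, noise_sd²), truncated at 0, with
    k_obs = k2·E0/(Km + E0) and P_max fixed at 1 (fraction cleaved).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.timepoints, dtype=float)
    curves = []
    for e0 in spec.e0_list:
        clean = 1.0 - np.exp(-spec.k_obs(e0) * t)
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=t.size)
        np.clip(noisy, 0.0, None, out=noisy)
        curves.append(
            ProgressCurve(
                enzyme_concentration=float(e0),
                timepoints=t,
                product=noisy,
                label=f"E0={e0 * 1e9:g}nM",
            )
        )
    return curves
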