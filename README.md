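# udgcoev

Correlated-mutation and single-turnover kinetics analysis for the uracil DNA
glycosylase (UDG) superfamily.

Uracil arises in DNA by cytosine deamination and is excised by UDGs through
base excision repair. The superfamily's six families share a structural fold
but diverge sharply in their catalytic motifs: family 1 UNG carries the
motif-1 block GQDPY where family 4 UDGa carries GE[A/G][V/P]G. `udgcoev`
implements the two computational halves of studying how such doublets
co-evolve and what they are worth catalytically:

1. **Sequence side.** Curate family sequence sets by diagnostic motif,
   reduce redundancy by greedy clustering (75% identity / 85% coverage),
   and quantify residue covariation in a family alignment by mutual
   information (MI),

   MI(i,j) = Σ_{a,b} f_ij(a,b) · ln [ f_ij(a,b) / (f_i(a)·f_j(b)) ]  (nats),

   computed from weighted, pseudocounted pair frequencies, corrected for
   background signal by the average product correction
   MIp(i,j) = MI(i,j) − M(i)M(j)/M̄, normalised to Z-scores against a
   column-shuffling permutation null, and thresholded at Z ≥ 6.5. Pairs are
   exported with per-position conservation and cumulative MI, tiered the
   way circular (Circos-style) co-evolution diagrams colour their edges.

2. **Bench side.** Fit single-turnover glycosylase progress curves
   P(t) = P_max(1 − e^(−k_obs·t)), fit k_obs vs total enzyme concentration
   with the hyperbola k_obs = k2[E0]/(Km+[E0]) (or a line through the
   origin, k_obs = (k2/Km)[E0], when Km ≫ [E0]), and convert catalytic
   efficiencies k2/Km into fold changes, apparent transition-state
   penalties ΔΔG = −RT·ln[(k2/Km)_mut/(k2/Km)_wt], and double-mutant-cycle
   coupling energies (ΔΔG_A + ΔΔG_B) − ΔΔG_AB.

A synthetic-data module generates family alignments with planted covarying
column pairs and noisy kinetic datasets with known ground truth, so the
whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from udgcoev import (
    CoevolutionModel, CoupledAlignmentSpec, generate_coupled_alignment,
    ddg, fold_change, coupling_energy,
)

# 200 x 50 synthetic family alignment with one strongly coupled pair
aln = generate_coupled_alignment(
    CoupledAlignmentSpec(n_rows=200, n_columns=50,
                         coupled_pairs=[(10, 30, 0.9)], seed=1))
res = CoevolutionModel(aln).fit(n_permutations=200, seed=1)
print(res.summary())
```

```
Co-evolution analysis summary
================================================
rows:                 200
columns analysed:     50 (of 50, max gap fraction 0.3)
effective sequences:  200.0
pseudocount:          0.05
permutations:         200 (seed 1)
Z threshold:          6.5
significant pairs:    1

pos_i  pos_j       Z   tier
   11     31   29.49   top5
```

The planted pair (columns 10 and 30, reported 1-based) is the single
significant relationship, at Z ≈ 29 against the 6.5 threshold.

On the kinetics side, with the measured Tth UDGa efficiencies
(k2/Km, s⁻¹M⁻¹: wild type 2.4×10⁵, E41Q 2.7×10², G42D 2.7×10³,
E41Q-G42D 4.5×10⁴) at the 60 °C assay temperature:

```python
T = 333.15
d_e41q   = ddg(2.7e2, 2.4e5, T)   # 4.5 kcal/mol
d_g42d   = ddg(2.7e3, 2.4e5, T)   # 3.0 kcal/mol
d_double = ddg(4.5e4, 2.4e5, T)   # 1.1 kcal/mol
coupling_energy(d_double, d_e41q, d_g42d)   # 6.4 kcal/mol
fold_change(4.5e4, 2.7e2)                   # 166.7 — enhancement over E41Q
```

The double substitution costs far less free energy than the sum of its
parts: the 6.4 kcal/mol coupling energy quantifies the energetic
interaction between the two motif-1 sites.

A thin CLI wraps the same functions:

```bash
udgcoev simulate alignment --rows 200 --columns 50 --pair 10,30,0.9 --seed 1 --out aln.fasta
udgcoev coevolve --alignment aln.fasta --threshold 6.5 --permutations 200 --seed 1 --out-dir out/
udgcoev kinetics energy-table --input efficiencies.tsv --wild-type wild_type
```

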