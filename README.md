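# udpep

Uniform-design sampling of the tetrapeptide sequence space, physicochemical
property calculators, sequence → property machine-learning protocols, and
SHAP-based attribution of peptide aggregation behaviour.

## The problem

Short self-assembling peptides are promising building blocks for drug
delivery, tissue engineering and antimicrobials, but their key
physicochemical properties — aggregation propensity (AP), hydrophobicity
(logP) and isoelectric point (pI) — vary across a combinatorial sequence
space (20⁴ = 160 000 tetrapeptides) far too large to simulate or measure
exhaustively. Which subset of sequences should be labelled so that a model
trained on it generalises to the whole space?

`udpep` answers this with **uniform experimental design (UD)**: a training
sample is a U-type design, an *n* × *s* matrix of residue levels in which
every amino acid occupies every sequence position exactly *n*/20 times, and
among all such balanced designs the sample is chosen to minimise the
**mixture L2-discrepancy**

```
MD2(P) = (19/12)^s
         − (2/n) Σᵢ Πⱼ (5/3 − ¼|xᵢⱼ−½| − ¼|xᵢⱼ−½|²)
         + (1/n²) ΣᵢΣₖ Πⱼ (15/8 − ¼|xᵢⱼ−½| − ¼|xₖⱼ−½| − ¾|xᵢⱼ−xₖⱼ| + ½|xᵢⱼ−xₖⱼ|²)
```

where the design points `x = (u − ½)/q` are the centred unit-cube image of
the levels. Minimisation uses a stochastic-optimisation adaptive
threshold-acceptance (SOAT) search whose move — swapping two entries within
one column — preserves balance by construction, and which accepts mildly
worsening moves below a decaying threshold to escape local optima.

Around the design live the rest of the pipeline stages:

* **properties** — logP as the sum of Wimley–White whole-residue
  water/octanol transfer energies (bundled hydrophobic-positive scale),
  a Henderson–Hasselbalch net-charge and bisection-pI calculator with an
  EMBOSS-style pKa set, AP = SASA_initial/SASA_final post-processing with
  the three-class binning [1,1.5)/[1.5,2)/[2,2.5], and a curated
  11-descriptor panel;
* **modeling** — one-hot (4×20 = 80-dimensional) encodings, random
  hyperparameter search under 5-fold CV, MAE/MSE/RMSE/R² on a fixed
  10 000-sequence test draw and on the full complement, learning curves
  over the 31-design series (n = 1000…16000 step 500) with
  second-difference inflection detection;
* **attribution** — three GBDT classifiers (xgboost, lightgbm, sklearn
  gradient boosting) on the descriptor panel, mean+1SD multi-model voting
  feature selection, and **exact tree-SHAP main and pairwise interaction
  values** (implemented natively, verified against a brute-force Shapley
  oracle) with Mann–Whitney aromaticity-threshold statistics under
  Bonferroni-corrected tiers;
* **synthetic_data** — a seeded generator that plants an aromaticity
  threshold, a logP window and a charge term into AP labels with the
  realistic distribution shape (mean ≈ 1.86 on [1, 2.5]), storing the
  noiseless ground truth so estimator bias and variance are measurable.

## Worked example

```python
import numpy as np
from udpep import SoatConfig, soat_optimize, occupancy_table
from udpep.uniform_design import design_to_peptides, md2_of_design, random_balanced_design

cfg = SoatConfig(outer_loops=10, inner_loops=800, seed=7)
design = soat_optimize(1000, 4, 20, cfg)          # 1000-run uniform design
print(round(md2_of_design(random_balanced_design(1000, 4, 20, seed=7)), 6))
print(round(design.md2_value, 6))
print(np.unique(occupancy_table(design)))
print(design_to_peptides(design)[:3])
```

prints

```
0.005366
0.00504
[0.05]
['RRMH', 'AKND', 'AELE']
```

— the SOAT search lowered the discrepancy of the random balanced start from
0.005366 to 0.005040, every residue occupies every position with frequency
exactly 0.05 (the design guarantee), and each run is a concrete
tetrapeptide. Properties for any peptide:

```python
from udpep import descriptor_vector
descriptor_vector("WKDF")
# {'aromatic_count': 2.0, 'net_charge': -0.023, 'logp': -2.64, 'pi': 6.337, ...}
```

From the shell, the same stages are available as `udpep design`, `udpep
series`, `udpep properties`, `udpep simulate`, `udpep train`, `udpep
curves`, `udpep attribute` and `udpep run --config cfg.yaml` (an
end-to-end pipeline with a checksummed manifest).

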