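# targetkl

Quantitative **one-to-group comparison of a query compound with drug-target
classes** from chemical-similarity matrices.

In ligand-based target prediction ("target fishing"), the usual evidence is
the similarity of a query compound to individual annotated ligands.  That
one-to-one view is noisy: for 3D (shape + pharmacophore-color) Tanimoto
scores the similarity distributions of different target classes overlap
heavily, and the single most-similar ligand says little about a whole
class.  `targetkl` instead compares *distributions*:

* each **target class** is summarized by the distribution of its
  intra-class ligand-pair similarities, fitted as a K-component Gaussian
  mixture (the class's *Q-distribution*) by expectation–maximization:
  Ξ(x) = Σₖ ωₖ g(x; mₖ, σₖ);
* each **query** is summarized, per class, by a maximum-likelihood
  Gaussian g(x; μ, σ) fitted to its vector of similarities against that
  class's ligands;
* query–class relevance is the **Kullback–Leibler divergence**
  D(query ‖ class), in closed form for single-Gaussian class models,

  D = ln(σⱼ/σᵢ) + (σᵢ² + (mᵢ − mⱼ)²)/(2σⱼ²) − ½,

  and by deterministic quadrature for mixtures;
* each query is assigned the class ν with minimal divergence; aggregating
  over annotated queries gives the assignment probability matrix
  P(ν = i | class m), per-class **necessary-condition** flags
  (P(m,m) ≥ maxᵢ≠ₘ P(m,i)) and the **feasibility index**
  F = √(P/(1−P)) quantifying how cleanly each class is discriminated.

The package consumes delimited similarity matrices (it does not compute 3D
overlays), ships a synthetic-matrix generator with exact ground truth for
validation, and exposes both a Python API and a `targetkl` command line.

## Worked example

Generate a well-separated four-class matrix (100 ligands per class, class
similarity means 0.30/0.45/0.60/0.75 on the combined [0, 2] score) and run
the full pipeline with single-Gaussian class models:

```python
from targetkl import separated_spec, recovery_experiment

result = recovery_experiment(separated_spec(n_ligands=100, seed=0), K=1)
report = result.report

for lab, m in result.class_models.items():
    print(f"Q({lab}): mean={m.means[0]:.4f} sd={m.sds[0]:.4f}")
print(report.prob_matrix.round(3))
print(report.necessary_ok.tolist())
print(report.feasibility.round(3).tolist())
```

Output:

```
Q(C1): mean=0.3042 sd=0.0693
Q(C2): mean=0.4487 sd=0.0775
Q(C3): mean=0.6028 sd=0.0683
Q(C4): mean=0.7482 sd=0.0704
[[1.   0.   0.   0.  ]
 [0.01 0.99 0.   0.  ]
 [0.02 0.03 0.95 0.  ]
 [0.03 0.02 0.01 0.94]]
[True, True, True, True]
[inf, 9.95, 4.359, 3.958]
```

Each fitted Q-distribution recovers its generating class mean to well
under 0.01.  The probability matrix is read row-wise: 94–100 % of each
class's queries are assigned back to their own class, every class
satisfies the necessary condition, and all feasibility indices exceed 1
(F = ∞ for C1 means not a single C1 query was misassigned; F = 3.96 for
C4 corresponds to P = 0.94).  On four *identical* classes
(`null_spec()`), the same pipeline returns rows near 0.25 everywhere —
no spurious discrimination.

The same pipeline from the shell:

```sh
targetkl simulate --preset separated --n-ligands 100 --seed 0 --out sim/
targetkl run --matrix sim/matrix.csv --annotations sim/annotations.tsv \
             --k 1,3,7 --seed 0 --out results/
```

which writes fitted class models (`models/q_<class>_K<k>.json`), per-query
fits, divergence tables, cumulative-divergence curves and `report.json`.
Real matrices in delimited text (IDs in the first row/column, plus a
two-column ligand→class annotation table) run through the identical
commands.

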