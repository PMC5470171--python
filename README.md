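# leafpheno

Cell-resolution phenotyping of leaf growth, for plant developmental
biologists who want the standard quantitative toolchain of a leaf-growth
study — kinematic rates, pavement-cell shape, endoreduplication, and
two-group RNA-seq statistics — as a tested, scriptable Python library
with a synthetic-data module that generates every input with known
ground truth.

## What it computes

**Kinematic growth analysis.** From daily leaf blade areas A(t) (mm²)
and mean epidermal cell areas ā(t) (µm²) of replicate leaves, the
average cell number is N(t) = A(t)·10⁶/ā(t), the relative leaf
expansion rate is RLER(t) = d ln A/dt (day⁻¹) and the average cell
division rate is D(t) = d ln N/dt (cells·cell⁻¹·day⁻¹), with
cell-cycle duration T_c = ln 2/D while proliferation lasts.
Derivatives of the noisy log series are taken by local quadratic
regression over a centred 5-day window; the proliferation-exit day
t_exit is the interpolated day where the smoothed D(t) falls to half
its proliferative plateau and stays down.

**Pavement-cell morphometrics.** Convexity (solidity) of a traced cell
outline is its shoelace area divided by the area of its convex hull
(Andrew's monotone chain), 1 for convex cells and lower for jigsaw
shapes; the area–convexity relationship is summarised in log-spaced
area bins per genotype. The stomatal index is guard cells as a percent
of all epidermal cells.

**Endoreduplication index.** From flow-cytometry nuclei counts over the
2C/4C/8C/16C classes, EI = 0·f₂C + 1·f₄C + 2·f₈C + 3·f₁₆C — the mean
number of endocycles per nucleus — with a multinomial-bootstrap
confidence interval.

**Expression statistics.** RPKM, per-sample scaling of counts to a
common depth of 10⁷ reads, a beta-binomial weighted two-group
proportion test on per-sample gene proportions (sample weights
w_i = n_i/(1+φ(n_i−1)), overdispersion φ estimated by a cross-gene
moderated moment estimator), Benjamini–Hochberg FDR, the significance
filter FDR < 0.05 and |log₂FC| > 0.75, and quality-threshold (QT)
clustering of significant-gene profiles under a 1 − Pearson-r diameter
of 0.8 with minimum cluster size 15.

**Synthetic data.** Piecewise-exponential leaf growth (exponential
proliferation to an arrest day, then exponential cell expansion to
maturity) with lognormal measurement noise; lobed cell outlines
r(θ) = R(1 + a·sin kθ); multinomial ploidy counts; negative-binomial
count matrices with planted fold changes. All generators are pure
functions of parameters and seed.

## Worked example

Run the numbered analysis scripts from the repository root (each reads
the previous one's outputs under `results/`):

```bash
python analysis/01_simulate_study.py
python analysis/02_kinematic_analysis.py
```

The first simulates three genotypes that differ only in their
proliferation-arrest day (15, 12 and 10 days after stratification);
the second recovers the contrast from the noisy replicate series:

```
WT-like: proliferation exit 14.8 DAS, mean division rate 0.407/day (Tc >= 1.60 d), final cell number 167,282
OE-mild: proliferation exit 12.1 DAS, mean division rate 0.395/day (Tc >= 1.72 d), final cell number 47,901
OE-like: proliferation exit 10.0 DAS, mean division rate 0.392/day (Tc >= 1.73 d), final cell number 22,120
final blade area WT-like 295.2 vs OE-like 225.1 mm^2 (24% reduction), Welch t=11.4, p=1.51e-06
```

Stopping division five days earlier at an unchanged division rate
(~0.4/day, i.e. a ~1.7-day cell cycle) costs the arrested genotype
roughly 7-fold in final cell number, only partly compensated at the
blade-area level by cell expansion — the classic kinematic signature
of a shortened proliferation phase. Scripts 03–05 continue with cell
shape (median convexity per genotype and the area–convexity curve),
endoreduplication (EI with bootstrap CI per genotype) and differential
expression:

```
90 genes significant (FDR<0.05, |log2FC|>0.75); recovered 90/100 planted, 0 false calls
QT clusters: sizes [48, 42], diameters [0.607, 0.559], 0 unclustered
```

The same stages are available as subcommands of a single CLI
(`leafpheno demo --seed 0 --out demo_out` runs everything and writes a
plain-text report).

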