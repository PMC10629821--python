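# centrotrace

Centrosome-birthdating analysis for human cortical organoid units, built
around recombination-induced tag exchange (RITE): before Cre recombination
every copy of the centrosomal protein Centriolin is tdTomato-tagged; after
recombination all new protein is NeonGreen-tagged, so a centrosome's
red-to-green balance reports the age of its mother centriole. In the
ventricular zone (VZ) of a cortical unit, neural progenitor cells (NPCs)
divide asymmetrically — one daughter self-renews in place, the other
migrates out — and the package asks, end to end on synthetic data, whether
the self-renewing daughter preferentially retains the **older** centrosome,
and whether randomising that inheritance (as Ninein knockdown does) is
detectable.

It is aimed at quantitative biologists who want a reproducible, fully
synthetic testbed for this class of two-channel puncta analyses: every stage
from the generative model to the significance tests is importable, seeded and
unit-tested, with ground truth available at each step.

## What it computes

- **Lineage simulation.** Semi-conservative centrosome duplication with slow
  Centriolin turnover (fraction `τ` per division, total load conserved) and a
  tunable probability `p_asym` that the VZ daughter inherits the older
  centrosome (0.9 wild-type-like, 0.5 knockdown-like).
- **Scene rendering.** Cortical units as rosettes: a dense apical ring of VZ
  centrosomes around the lumen plus radially migrated progeny, rendered as
  two-channel 16-bit TIFFs with Poisson and read noise.
- **Quantification.** Laplacian-of-Gaussian puncta detection on the
  channel-sum image, aperture photometry with annulus-median background
  subtraction, and the age statistic `r = N / (T + N)`.
- **Region analysis.** The ventricle-centred analysis circle, the 45° wedge
  over a recombined cluster, vent/nonvent assignment, manual and
  ratio-tertile colour classes (orange = oldest, green = youngest), per-unit
  proportions and unpaired Student *t*-tests, and recovery of `p_asym` by
  minimum-distance matching against the generative model with a bootstrap
  confidence interval over cortical units.

## Worked example

```python
import centrotrace as ct

wt = ct.run_study(ct.StudyConfig(sim=ct.SimConfig(p_asym=0.9, seed=1)))
for colour, t in wt.tests.items():
    print(colour, f"t={t.t:.2f} p={t.p:.2g} {t.stars}")
```

prints (22 simulated cortical units, tertile classification):

```
ORANGE t=4.68 p=3e-05 ***
YELLOW t=-2.92 p=0.0057 **
GREEN t=-3.58 p=0.00089 ***
```

i.e. old (orange) centrosomes are significantly enriched on the ventricular
wall (mean vent proportion 0.54 vs 0.29 outside) and young (green)
centrosomes significantly depleted there (0.23 vs 0.36) — the wild-type
signature of asymmetric inheritance. Recovering the inheritance parameter
from the same kind of classified table:

```python
est = ct.recover_asymmetry(ct.run_study(
    ct.StudyConfig(sim=ct.SimConfig(p_asym=0.9, n_units=50, seed=91))))
print(est.p_hat, (est.ci_low, est.ci_high))   # 0.9 (0.88, 0.92)
```

A command-line interface mirrors the library:
`centrotrace simulate|render|roi|quantify|classify|stats|recover|run|compare`.

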