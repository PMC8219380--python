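# tcrpower

Quantifying the discriminatory power of the T cell receptor (TCR).

T cells distinguish self from non-self by the affinity of their TCR for
peptide–MHC (pMHC) ligands. `tcrpower` implements the quantitative
machinery needed to measure how sharply that discrimination operates:

- **Constrained-Bmax SPR affinity fitting.** Steady-state surface plasmon
  resonance titrations are fitted with the Langmuir isotherm
  `B = Bmax·[TCR]/(KD + [TCR])`. For low-affinity interactions the curve
  cannot be saturated and the free two-parameter fit is ridge-degenerate
  (many Bmax/KD combinations fit equally well). The constrained method
  fixes Bmax from an empirical standard curve built on the plateau binding
  of the conformation-sensitive W6/32 antibody (a proxy for correctly
  folded pMHC density), leaving KD as the only free parameter and making
  KD measurable into the millimolar range.
- **Potency extraction.** Dose–response curves are fitted with a
  four-parameter sigmoid and inverted analytically at a fixed activation
  threshold (PX, e.g. P15 for CD69); potencies beyond the tested dose
  range are excluded, never extrapolated.
- **The discrimination power α.** Potency and affinity obey the power law
  `PX = 10^C · KD^α`, fitted by OLS in log–log space. α is the slope: the
  factor by which affinity changes are amplified into potency changes.
  α = 1 is the receptor-occupancy baseline; a 5-fold affinity loss then
  needs a 5-fold dose increase, while α = 2 needs 25-fold and a
  near-perfect α = 9 would need ~2-million-fold.
- **Kinetic proofreading (KP) inference.** A bound TCR must traverse N
  sequential steps at rate k_p before signalling (delay τ_KP = N/k_p).
  The closed-form KP potency is fitted hierarchically to multi-experiment
  potency tables (global N, γ, δ̂; per-experiment k_p, λ̂) with an
  annealed Metropolis–Hastings ensemble.
- **Sensitivity–discrimination phase maps.** Deterministic constraints and
  exact Gillespie simulation classify (N, τ) parameter space by whether a
  single agonist can trigger signalling (sensitivity) and whether a
  10⁴-fold excess of a Δ-fold weaker ligand stays silent (discrimination).
- **Synthetic data generators** with known ground truth for every stage,
  so each fitter is validated by parameter recovery.

## Worked example

Run the full synthetic chain — generate data, fit affinities, extract
potencies, estimate the discrimination power:

```python
import json
from pathlib import Path
from tcrpower.config import PipelineConfig
from tcrpower.pipeline import run_pipeline

cfg = PipelineConfig(seed=11)
out = Path("demo")
for stage in ("synth", "spr-fit", "potency", "powerlaw"):
    run_pipeline(cfg, stage, out_dir=out)

agg = json.load(open(out / "aggregate.json"))
std = json.load(open(out / "standard_curve.json"))
print(f"standard curve: slope={std['slope']:.2f}, intercept={std['intercept']:.1f} RU "
      f"({std['n_points']} saturating fits)")
print(f"discrimination power: alpha = {agg['alpha_mean']:.2f} "
      f"(95% CI {agg['alpha_ci95'][0]:.2f}-{agg['alpha_ci95'][1]:.2f}, "
      f"n = {agg['n_included']} experiments)")
print(f"test vs alpha=1: p = {agg['p_vs_one']:.2e}")
```

prints

```
standard curve: slope=1.96, intercept=14.2 RU (9 saturating fits)
discrimination power: alpha = 1.71 (95% CI 1.59-1.84, n = 12 experiments)
test vs alpha=1: p = 9.66e-09
```

The standard-curve slope recovers the generator's W6/32-to-Bmax
conversion (truth 2.0). The fitted α ≈ 1.7 is the effective log–log slope
the KP generator (N = 2.67, k_p ≈ 1 s⁻¹) produces over the 3–1500 μM
panel: enhanced above the occupancy baseline (p ≪ 0.001 against α = 1)
but far from near-perfect discrimination.

The same stages are available from the shell:

```bash
tcrpower synth --seed 11 --out-dir demo
tcrpower spr-fit --out-dir demo
tcrpower potency --out-dir demo
tcrpower powerlaw --out-dir demo
tcrpower kp-fit --out-dir demo     # annealed MH ensemble (ensemble.csv, summary.json)
tcrpower kp-map --out-dir demo     # phase maps (phase_map.csv)
```

Fixed seeds give byte-identical outputs; every run writes a
`run_metadata.json` with the seed, config hash and package version.

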