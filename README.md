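# fluxnode

Proteomics-constrained metabolic flux analysis of drug response in cancer
cell lines.

Breast cancer cell lines respond very differently to drugs that target
metabolism (the biguanide metformin, the mTOR inhibitor rapamycin).  This
package re-implements, as a tested and fully synthetic-testable pipeline, a
workflow that connects label-free shotgun proteomics of treated vs. control
cells to predictions about growth and pathway fluxes:

1. **Proteomics preprocessing** — MaxQuant-style protein-group tables are
   filtered for quantifiability (≥ 2 unique peptides, detected in ≥ 75% of
   samples), arcsinh-transformed, zero-imputed (iterative random-forest,
   k-NN fallback), median-scaled per sample and expressed in log2 units;
   per-protein deltas are treated − control, and |Δ| > 1.5 defines
   differential expression.
2. **Functional network** — a maximum-|Pearson ρ| spanning forest over
   proteins (the treewidth-1 decomposable graphical model), split into
   branches by cutting the weakest edges; branches are labeled by
   hypergeometric over-representation of annotation terms, and a labeled
   branch's *node activity* is the mean delta of its label-carrying
   proteins.
3. **E-flux integration** — each reaction's gene–protein–reaction (GPR)
   rule is evaluated against protein abundance (OR = sum of isozymes,
   AND = min over complex subunits), scores are min–max normalized to
   [0, 1] per sample, and the normalized score a′ⱼ replaces the flux
   bounds: [0, a′ⱼ] if irreversible, [−a′ⱼ, a′ⱼ] if reversible.
4. **Flux analysis** — FBA maximizes biomass flux μ subject to S·v = 0 and
   bounds; FVA gives per-reaction flux ranges at the optimum; the
   maximum-Σ|v| solution represents "every measured enzyme is used"; a
   Monte-Carlo sampler draws vertices of the optimal face under random
   objectives.  Reactions whose control→treated flux change exceeds 95% of
   the union FVA range are flagged, with Monte-Carlo support reported.
   *Flux activity* summarizes a pathway as Σ|v| over its reactions.
5. **Dynamic FBA** — quasi-steady-state batch growth: per step the glucose
   uptake bound follows the medium, X ← X·e^{μ dt}, and substrate is
   depleted by the integrated biomass.
6. **Dose–response** — the median-effect model fa/(1 − fa) = (D/Dm)^m is
   fit by least squares on log(fa/(1−fa)) vs log D, giving the IC50 (Dm)
   and slope m; IC_x doses follow from D = Dm·(fa/(1−fa))^{1/m}.

Every stage runs on synthetic data with known ground truth: toy metabolic
models (uptake → chain → parallel block → biomass, with GPR rules and
subsystem labels) and simulated perturbation proteomics with planted
log2 effects on co-regulated modules.

## Worked example

Fit the printed metformin viability table and report IC50s:

```bash
fluxnode ic50 --viability src/fluxnode/data/viability_mtf.tsv
```

```
                 m         Dm        r2  n_points_used  n_excluded
MCF7      2.111441  33.069695  0.926333            5.0         2.0
T47D      1.428743  20.449207  0.906713            5.0         2.0
CAMA1     1.400194  47.413181  0.640887            4.0         3.0
MDAMB231  1.284198  14.244552  0.840017            6.0         1.0
MDAMB468  1.707356   6.318497  0.796664            5.0         2.0
HCC1143   1.474352  36.590074  0.973878            4.0         3.0
```

Reading the output: T47D's median-effect dose is Dm ≈ 20.4 mM (the
metformin IC50) with slope m ≈ 1.43; CAMA1, the most resistant line, needs
≈ 47 mM, while MDAMB468, the most sensitive, is at ≈ 6.3 mM.
`n_excluded` counts dose points outside the model's dynamic range —
dose 0 plus viability ≥ 100% (growth stimulation, e.g. MCF7 at 5 mM or
CAMA1 at 10 and 40 mM) or complete kill — whose log-odds are undefined.

The full synthetic pipeline, from simulated proteomics to flux-change
detection and response regression, runs off one YAML config:

```bash
fluxnode run --config configs/demo.yaml --outdir demo_out
```

and the numbered drivers under `analysis/` execute the same stages
step by step, writing their tables under `results/` (e.g.
`analysis/03_functional_network.py` reports the planted −1.0 module
recovered as a labeled branch with node activity ≈ −0.96 on the demo
study, and a 98/100 recovery rate across seeded replicate studies).

## Layout

- `src/fluxnode/` — library: `prep`, `network`, `gpr`/`eflux`/`model`,
  `fba`, `dfba`, `fluxchange`, `dose`, `synth`, `experiments`,
  `pipeline`, `cli`, `sbml`.
- `analysis/` — numbered narrative drivers over the library.
- `configs/demo.yaml` — the synthetic demo study.
- `tests/` — pytest suite with independent brute-force oracles
  (`tests/oracles.py`).
- `docs/methods.md` — modeling assumptions, parameter choices and
  limitations.
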