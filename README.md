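# riboquant

Quantitative analysis of the biochemical assays used to characterize
ligand-sensing riboswitches — in particular Na⁺-sensing riboswitches and
their tandem arrangements with c-di-AMP riboswitches.

Riboswitches are structured mRNA segments that bind a small ligand and
regulate the downstream gene, here through an intrinsic transcription
terminator. Two assays dominate their biochemical characterization, and
both end in densitometry of radiolabelled gel bands:

* **In-line probing** reads ligand-induced structure change through the
  rate of spontaneous RNA strand scission at individual sites. `riboquant`
  normalizes per-lane band volumes to a reference band, rescales modulated
  sites to fraction bound *f* anchored at the no-ligand and saturating
  lanes, and fits the sigmoidal dose-response

  $$f(L) = \mathrm{bottom} + \mathrm{top}\cdot\frac{L^{h}}{L^{h}+K_D^{h}}$$

  against log₁₀ ligand concentration (h pinned at 1 for one-to-one
  binding; variance-weighted for multiplicative band noise) to estimate
  the apparent dissociation constant $K_D$.

* **Single-round transcription termination** counts how many polymerases
  stop at a terminator (T) versus reading through to full length (FL).
  Because initiation and elongation use UTP pools with different
  radiolabel fractions, band volumes are corrected by each species'
  relative radioactivity $R = u_\mathrm{init} f_\mathrm{init} +
  u_\mathrm{elong} f_\mathrm{elong}$ before comparison:
  percent termination $= 100\,T/(T + \mathrm{FL}\cdot X)$ with
  $X = R_T/R_{FL}$, and the analogous three-species formulas for tandem
  (T1/T2/FL) constructs — equivalent to normalizing corrected counts
  $I_s/R_s$.

* A **two-input Boolean logic-gate model** composes two independent
  switches in series: an upstream ligand-activated ON switch (read-through
  probability $p_1$) and a downstream ligand-repressed OFF switch
  ($p_2$), each a floor/ceiling-bounded Hill dose-response. The transcript
  partition is $f_{T1} = 1-p_1$, $f_{T2} = p_1(1-p_2)$,
  $f_{FL} = p_1 p_2$, predicting "A and Not B" (material nonimplication)
  behaviour: gene ON only at high Na⁺ and low c-di-AMP.

No public archive deposits the underlying gel densitometry, so the package
ships seeded generators (`riboquant.synthetic`) that emulate both assay
types with the statistical structure the analyses assume, and
parameter-recovery round trips (`riboquant.recovery`) that validate every
equation against generated truth.

## Worked example

```python
from riboquant import (NoiseModel, default_probing_sites, fit_kd,
                       simulate_titration, titration_concentrations)

series = simulate_titration(
    true_kd=2.2,                                # mM
    sites=default_probing_sites(),
    concentrations=titration_concentrations(),  # 0 + 12 points, 0.01-100 mM
    noise=NoiseModel(cv=0.10, seed=7),
)
fit = fit_kd(series)
print(f"fitted K_D: {fit.kd_mM:.2f} mM (hill = {fit.hill:.1f})")
```

prints

```
fitted K_D: 2.50 mM (hill = 1.0)
```

a single noisy titration recovering the generating 2.2 mM dissociation
constant to within ~14%; the median over many replicate titrations lands
within a few percent. The scripts in `examples/` walk through each
capability (`01_binding_kd.py`, `02_termination_readthrough.py`,
`03_tandem_logic_gate.py`) and print annotated output.

A thin CLI mirrors the library
(`riboquant simulate-probing | fit-kd | simulate-transcription |
quantify-termination | simulate-gate | gate-evaluate | demo`); lane tables
travel as TSV and results as JSON with the run-configuration hash embedded.

## Layout

```
src/riboquant/
  constructs.py    transcript templates, halt site, U-residue accounting
  synthetic.py     seeded probing/transcription generators + noise model
  probing.py       normalization, fraction bound, K_D fitting, ion panels
  termination.py   radiolabel correction and termination fractions
  gate.py          tandem logic-gate model and truth tables
  recovery.py      generator -> quantification round-trip experiments
  io.py, cli.py    TSV/JSON formats, run configs, thin CLI
docs/methods.md    models, assumptions, parameter choices, limitations
```
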