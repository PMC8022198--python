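# pcfba — proteome-constrained flux balance analysis

`pcfba` is a Python library and command-line tool for **proteome-constrained
(metabolism-and-expression) modeling** of fermentative bacteria. It is aimed
at systems biologists who want to ask not just *which fluxes are
stoichiometrically possible* but *which fluxes the cell can afford to
catalyze*: every metabolic flux v is tied to the concentration of its
catalyst through v ≤ k_cat·[E], every catalyst must be transcribed,
translated, assembled, degraded and diluted by growth, and the whole modeled
proteome must fit a fixed budget.

## The model

At a fixed specific growth rate μ the model is a linear program over
reaction fluxes. Catalyst concentrations are eliminated through the
steady-state relation (synthesis = degradation + dilution to daughter
cells):

```
[X] = v_dilution(X) / μ,        v_synthesis(X) = (μ + k_deg)·[X]
```

which makes all coupling constraints linear in the fluxes:

* enzyme capacity v ≤ k_cat·[E], with k_cat·σ for the glucose transporter,
  where σ = S/(K_M + S) is its Michaelis–Menten saturation at extracellular
  glucose concentration S;
* ribosome, RNA-polymerase, mRNA and tRNA capacities (events per machine
  per hour, weighted by protein/transcript length);
* a total modeled-proteome budget Σ mass(X)·[X] + inactive = P_modeled,
  whose slack is reported as **inactive enzyme** — spare proteome of
  average amino-acid composition; it is zero exactly when the proteome
  constraint is active;
* a hard cap on the glucose-transporter abundance, calibrated as the
  minimal transporter level that still supports the maximal growth rate.

Glucose-limited chemostat conditions are found by **binary search over S**:
the smallest concentration at which the LP (objective: dummy-protein
production) is feasible for the requested μ. Three local sensitivity tools
sit on top: scaled reduced costs R = (Δμ/Δq)(q/μ) for amino-acid uptake
bounds, sensitivity scores S = (Δμ/Δc)(c/μ) for the transporter cap and
proteome budget, and a twofold one-at-a-time robustness scan over all
parameters.

The package also contains the **three-pathway small model**: maximize
J_ATP = Σ Y_i·J_i over glycolysis + mixed-acid fermentation, glycolysis +
lactate, and arginine catabolism, subject to J_1 + J_2 = J_glc, a proteome
cap Σ p_i·J_i ≤ P, and an arginine bound J_3 ≤ α·J_glc + β. Its exact
piecewise solution is implemented independently of the LP and explains the
two metabolic switches from protein efficiency (e_i = Y_i/p_i) alone.

Everything is exercised on a bundled synthetic toy network — a lumped
lactic-acid-bacterium fermenter with PTS glucose uptake, mixed-acid and
lactate branches, the arginine deiminase pathway (net consumer of two
cytosolic protons per arginine) and an ATP synthase translocating three
protons per ATP. All toy reactions balance C, H, N, O, P, S and charge
exactly. No external data are required.

## Worked example

```python
from pcfba import make_toy_network
from pcfba.small_model import estimate_pathway_params

params = estimate_pathway_params(make_toy_network())
print(params.atp_yield)      # (3.0, 2.0, 1.6667)
print(params.efficiency)     # (85.7, 172.6, 39.1)
```

Running `python examples/01_pathway_yields.py` prints:

```
pathway       Y (ATP/substrate)   p (g.h/mmol)   e (mmol ATP/g/h)
mixed_acid                 3.00         0.0350               85.7
lactate                    2.00         0.0116              172.6
arginine                   1.67         0.0426               39.1

arginine substrate-level ATP (carbamate kinase only): 1.00
ATP-equivalent of the 2 avoided proton exports:       0.67
```

Mixed-acid fermentation yields 3 ATP per glucose, lactate 2. Arginine
catabolism yields 1.67 ATP per arginine: one from carbamate kinase plus
2/3 because the pathway consumes two cytosolic protons the cell would
otherwise have to export through the ATP synthase at 3 H⁺ per ATP. Because
protein efficiency orders lactate > mixed acid > arginine, a rising glucose
supply under a fixed proteome first squeezes out arginine catabolism and
then trades mixed acid for lactate — `examples/04_small_model_phases.py`
shows the three phases, and `examples/03_growth_simulation.py` shows the
same switches emerging from the full proteome-constrained model along a
simulated chemostat curve.

The CLI mirrors the library:

```bash
pcfba simulate --model toy --mu 0.5 --out fluxes.tsv
pcfba mumax --model toy
pcfba smallmodel --out phases.tsv
pcfba reducedcost --model toy --mu 0.3
pcfba run sweep.ini          # config-driven mu-grid sweep with manifest
```

## Layout

```
src/pcfba/
  core.py        domain types: metabolites, reactions, proteins, enzymes,
                 machineries, proteome budget, models
  build.py       reversible/isozyme splitting, dummy catalyst, expression layer
  simulation.py  coupling-constraint LP, feasibility, binary searches
  analyses.py    reduced costs, sensitivity scores, robustness scan
  small_model.py three-pathway LP, analytic solution, phase scan
  fixtures.py    toy network, micro-model, chemostat data generator
  io.py          JSON schema, TSV tables, SBML import (via cobrapy)
  cli.py         command-line interface;  config.py: config-driven sweeps
examples/        one short narrative script per capability
docs/methods.md  modeling assumptions, parameters, numerical choices
```
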