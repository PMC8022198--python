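# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind `pcfba`, in the spirit of a model-description appendix.

## The two-layer model

A conventional stoichiometric model (metabolites, reactions, bounds,
gene–protein–reaction links) is reformulated before coupling:

1. **Reversible split.** Every reversible reaction becomes a forward/reverse
   pair with nonnegative fluxes (exchanges included), so each direction
   carries its own catalyst cost. A mapping back to net fluxes is kept for
   reporting; a flux-minimizing post-solve (below) prevents simultaneous
   forward/reverse flux in returned optima.
2. **Isozyme split.** A reaction with alternative catalysts becomes one copy
   per isozyme; reported flux is the sum over copies.
3. **Dummy catalyst.** Non-spontaneous metabolic/transport reactions without
   a gene assignment are catalyzed by a shared dummy protein (300 residues
   of model-average amino-acid composition; k_cat equal to the median of
   all enzyme turnover numbers) so that no flux is free of proteome cost.
   Spontaneity is an explicit model field, never inferred.
4. **Expression layer.** Per gene: transcription (NTPs in, 2 phosphates per
   nucleotide out, RNA-polymerase-catalyzed), mRNA degradation (returns
   nucleotide monophosphates) and dilution; per protein: translation
   (charged tRNAs + 2 ATP-equivalents per residue, ribosome-catalyzed,
   mRNA-coupled), degradation (1 ATP per residue, returns amino acids) and
   dilution; per amino acid: a tRNA gene (transcription, lumped maturation,
   dilution) and a charging reaction (1 ATP); per enzyme: formation from
   subunits and dilution. rRNA/tRNA maturation chemistry is lumped into
   single machinery-catalyzed reactions. The biomass equation carries only
   non-protein, non-RNA components (protein and RNA leave through their own
   dilution reactions); an unmodeled-protein reaction produces the fixed
   extra-model protein share from free amino acids at 3 ATP-equivalents per
   residue, pinned to μ × mass/MW. All energy bookkeeping uses ATP as the
   GTP-equivalent currency; the per-step costs are config fields
   (`ExpressionConfig`) because different organisms warrant different
   accounting.

Compositions of expression-layer species are derived by closing the
elemental balance of their creating reaction, so every constructed reaction
balances C, H, N, O, P, S and charge by construction; `check_balances`
verifies this after the build. Exchange, biomass and dilution reactions are
exempt: they move mass across the system boundary (medium or daughter
cells).

## Coupling constraints and the growth LP

With μ fixed, catalyst concentrations are eliminated via [X] = v_dil(X)/μ.
The LP has one flux variable per reaction plus one slack (the inactive
enzyme) and rows for: species mass balance; degradation ties
v_deg = (k_deg/μ)·v_dil; enzyme capacities v ≤ (k_cat/μ)·v_dil(E);
machinery capacities (ribosome: Σ L_p·v_transl,p, RNA polymerase:
Σ L_nt·v_transcription, per-mRNA translation initiation, per-tRNA
charging); and the proteome budget
Σ mass(X)·[X] + inactive = total modeled fraction.

**Inactive enzyme is budget slack, not synthesized fill.** The inactive
pool absorbs unused modeled proteome at zero resource cost. The alternative
— requiring the fill protein to be synthesized — would give the proteome
budget a small *negative* shadow value in glucose-limited conditions
(synthesizing fill costs glucose), contradicting the defining property that
a slack constraint has zero sensitivity. With the slack formulation,
inactive enzyme > 0 ⟺ proteome score = 0, exactly.

**Glucose uptake** is doubly limited: kinetically, v ≤ k_cat·σ·[E] with
σ = S/(K_M + S), and by an abundance cap [E] ≤ cap. The cap is calibrated
by the model itself: find μ_max at saturating glucose with the cap
unbounded, then minimize the transporter concentration at that μ_max; the
minimum becomes the cap. After calibration the cap is, by construction,
exactly binding at μ_max.

**Objective and degeneracy.** The feasibility objective maximizes
dummy-protein production (conventional for this model class). Returned
solutions are cleaned by a second LP that fixes the attained objective and
minimizes total flux, suppressing futile cycles. These LPs are
ill-conditioned (coefficients spanning 1e−7…1e5); all coupling rows are
scaled so the dilution-flux coefficient is −1, HiGHS runs at a primal
feasibility tolerance of 1e−10, and a post-solve audit re-checks every
coupling row, concentration sign and the budget closure at 1e−6 relative.
The audit substitutes for the exact rational arithmetic sometimes used on
such problems.

**Binary searches.** Minimal glucose concentration: bisection on S over
[0, 1000 mM] to relative tolerance 1e−6 (searching S is equivalent to
searching the lowest transporter saturation σ). Maximal growth rate:
doubling bracket then bisection on μ to relative 1e−4. Feasibility is
monotone in both S and μ, so the brackets are valid and nest.

## Sensitivity machinery

Scaled reduced costs R = (Δμ/Δq)(q/μ) probe each amino-acid uptake bound
with an absolute Δq = 0.01 mmol/gCDW/h; sensitivity scores
S = (Δμ/Δc)(c/μ) probe the transporter cap and the proteome budget with a
relative 1% increase. Both recompute μ by re-solving (finite differences),
which is robust to LP degeneracy; both perturbation conventions are
config-overridable since the appropriate size is condition-dependent.

An independent **dual route** cross-checks the finite differences: μ*(q) is
the root of the value function g(μ, q) = max dummy production, so
dμ/dq = −g_q/(g_μ + a·g_q) by the implicit function theorem, where g_q is
the exact LP dual of the uptake bound, g_μ a central difference in μ at
*fixed* bounds, and a the bound's slope in μ. The q-direction never uses
finite differences, keeping the two routes independent; they agree within a
few percent on the toy model wherever the bound is active.

The robustness scan varies every turnover number, degradation constant,
machinery rate and budget term twofold up and down, re-solves μ at each
reference condition, and flags |Δμ/μ| > 1%. Solver failures are recorded
per row and do not stop the scan.

## The three-pathway small model

Pathway parameters are estimated from the metabolic layer by three LPs with
the maintenance bound freed: mixed acid maximizes maintenance at glucose
uptake 1 mmol/gCDW/h; lactate maximizes lactate production at glucose 1 and
maintenance fixed at 2; arginine maximizes maintenance at arginine uptake 1.
Yield Y_i is maintenance flux over substrate uptake; protein cost p_i sums
(enzyme mass / k_cat) × flux over the pathway's reactions; efficiency
e_i = Y_i/p_i.

The allocation LP (maximize Σ Y_i·J_i s.t. J_1 + J_2 = J_glc,
Σ p_i·J_i ≤ P, 0 ≤ J_3 ≤ α·J_glc + β) has a closed-form greedy solution in
the fermentative regime Y_1 > Y_2, p_1 > p_2: route all glucose through
lactate first, then spend the remaining proteome budget on the two
"upgrades" — moving glucose to mixed acid at marginal gain
(Y_1−Y_2)/(p_1−p_2) per gram, and arginine at Y_3/p_3 — in order of
decreasing marginal gain. This analytic solution is implemented separately
from the LP and serves as its oracle. Phase labels come from
finite-difference slopes over the scan grid (flat below 1e−9 × max flux;
phase B requires a strictly negative arginine slope); at a tie
e_1 = e_2 the LP's flux-cost ordering prefers lactate. Sensitivities
perturb glucose supply, the cap, or the arginine bound value independently
(the bound is held at its base value when glucose is perturbed), which
makes the three scaled scores sum to 1 when β = 0, by Euler's relation for
the degree-1 homogeneous optimum.

## The toy network (study conditions)

The bundled fixture emulates a lactic acid bacterium: PTS glucose uptake
(phosphorylation at PEP expense), lumped EMP glycolysis (G6P → 2 PEP,
+1 ATP, +2 NADH), pyruvate kinase, a mixed-acid branch (pyruvate
formate-lyase, phosphotransacetylase, acetate kinase, and a two-NADH
ethanol branch), lactate dehydrogenase, and the arginine deiminase pathway
(arginine/ornithine antiport, deiminase, catabolic ornithine
transcarbamylase, carbamate kinase). Protons are explicit: phosphate is
carried as H₂PO₄⁻ and ammonium as NH₄⁺, a convention under which ADP + Pi →
ATP + H₂O is proton-neutral, fermentation acids leave as proton symports
(net zero cytosolic protons per glucose), and the arginine pathway consumes
exactly two cytosolic protons per arginine, both at the carbamate-kinase
step. The membrane ATP synthase translocates 3 H⁺ per ATP by default
(config-exposed), so those two protons are worth 2/3 ATP and the full
arginine yield is 1.67. Blocked by default, mirroring anaerobic operation:
oxygen exchange, pyruvate oxidase, one alcohol dehydrogenase isozyme, and
two alternative glucose transporters.

Numbers defining the conditions: total modeled proteome 0.276 g/gCDW with a
40% unmodeled share (total protein 0.46 g/gCDW); non-protein/RNA biomass
0.4 g/gCDW (1.54 mmol/gCDW of a G6P-like precursor at 2 ATP each);
maintenance 0.4 mmol ATP/gCDW/h; transporter k_cat 24 000/h, K_M 0.2 mM;
ribosome 45 000 aa/h, RNA polymerase 180 000 nt/h, mRNA 1 200
initiations/h with k_deg 10/h, tRNA 36 000 charging events/h; protein
k_deg 0.02/h. Enzyme turnover numbers (2 300–100 000/h) and masses
(35–500 g/mmol) are effective rates chosen once so that (i) protein
efficiencies order lactate > mixed acid > arginine, (ii) the proteome
becomes limiting around 60% of μ_max, and (iii) μ_max lands near 1.3/h —
the regime of a fast-growing fermenter. Amino-acid uptake bounds (the
alphabet is alanine/arginine/serine) are linear in μ with arginine
deliberately overconsumable (2.0·μ + 0.3), so arginine catabolism is an
active constraint at low growth rates.

The chemostat generator produces supernatant/medium concentration tables at
six dilution rates (0.1–0.6/h, anchored to the 0.5/h of a 2.25 ml/min feed
into 270 ml): linear uptake trends for most amino acids, saturating
profiles for aspartate/glutamate as non-linear negative controls, and
secreted ornithine. Gaussian noise acts on concentrations (not fluxes),
with one standard deviation per compound equal to 5% of its mean
supernatant concentration. Because q = D·ΔC/X, the implied flux noise grows
with D; the generator's provenance therefore includes the exact noise so
recovery tests can use the estimator's true sampling error.

**What the toy does and does not show.** Passing tests demonstrate that the
coupling formulation, searches and sensitivity machinery behave correctly
and that the qualitative physiology (transporter saturation rising with μ,
inactive enzyme draining to zero, arginine shutdown preceding the
mixed-acid→lactate switch) emerges from protein-efficiency orderings alone.
The toy cannot stand in for a genome-scale reconstruction: it has one
lumped glycolysis instead of ten enzymes, a three-letter amino-acid
alphabet, nucleotide salvage instead of de-novo synthesis (an NMP medium
supply), no membrane-area constraint, and effective rather than measured
turnover numbers. Quantities that depend on real parameterization (absolute
S_min values, the exact switch growth rate) are toy-specific.

## Degenerate and edge cases

μ = 0 is rejected (coupling coefficients are 1/μ). A model with zero genes
degenerates to the metabolic layer plus budget. The micro-model used to
validate the binary search has no expression layer; its transporter bound
reduces to k_cat·cap·σ and its minimal glucose concentration has the closed
form S = K_M·σ*/(1−σ*) with σ* = demand/(k_cat·cap). Uptake-bound
trendlines are clipped at zero when a fitted intercept is negative;
secreted compounds get no bound. In `phase_scan`, grids must be strictly
increasing; a glucose flux beyond P/min(p_1,p_2) is reported as infeasible
together with the maximum sustainable value.

## Known limitations

Local, one-at-a-time sensitivities only (no global methods); no dynamic
simulation, thermodynamic constraints or integer variables; kinetic
regulation (e.g. NADH/NAD⁺ control of the lactate switch) is outside the
scope of a stoichiometric model — here the fermentation switch is driven
entirely by protein costs; the SBML importer covers the metabolic layer
only, with kinetic parameters supplied through the TSV tables.
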