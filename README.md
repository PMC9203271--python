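# mpresolve

Macropinosomes (MPs) are micron-scale fluid-filled vacuoles that macrophages
and cancer cells form by plasma-membrane ruffling. Within ~10 minutes of
closure an MP shrinks to a small fraction of its initial volume by expelling
Na⁺ and Cl⁻ (water follows osmotically), while its lumen acidifies.
`mpresolve` is a Python package for studying this *resolution* process from
both ends:

* a **deterministic ODE model** of a single MP — Na⁺ efflux through two-pore
  channels (TPC), Cl⁻ efflux through the proton-activated anion channel
  ASOR/TMEM206, 2Cl⁻/H⁺ exchange by CLC antiporters, V-ATPase pumping, an
  outwardly rectifying H⁺ conductance, proton buffering, and instantaneous
  osmotic water flow — with named presets for the classic interventions
  (TMEM206 knockout, luminal ion substitution, bafilomycin, NH₄Cl,
  alkaline-shifted ASOR mutant, gating removal, copy-number scans);
* a **time-lapse quantification pipeline** for spinning-disc-style z-stack
  movies of dye-filled MPs — maximum projection, histogram truncation, cell
  masking, difference-of-Gaussians blob proposals, circular-Hough
  confirmation with a 2-of-5 concentricity rule, backward-in-time nearest-
  neighbour tracking (30 px gate), spherical volume and inner-circle
  intensity measurement, ratiometric pH with an ionophore-style sigmoid
  calibration, and a wound-healing (scratch) assay analyzer;
* a **synthetic microscopy generator** that renders ground-truthed movies
  (shrinking spheres with conserved dye, dual-excitation pH reporter
  stacks, scratch sequences), so every stage of the pipeline is testable
  without any external data.

It is aimed at cell biologists and biophysicists who want to reproduce,
probe or extend the ion-transport feedback logic of vacuole shrinkage, and
at image-analysis developers who need a fully specified, benchmarked
reference implementation of the MP quantification recipe.

## The model in brief

State: luminal amounts *n*ᵢ of Na⁺, K⁺, Cl⁻, buffered protons, and two
impermeant pools. Volume follows algebraically from the osmotic constraint
Σᵢ *n*ᵢ / *V* = Osmₑₓₜ (infinite water permeability; buffered protons are
osmotically inactive), and the membrane potential *U* (lumen − cytosol)
from the net luminal charge on the membrane capacitance,
*U* = *F*·Δ*q* / (*c*ₘ·*A*).

Fluxes (mol/s into the lumen):

* channels: *J* = −*g*·*A*·*p*ₒₚₑₙ·(*U* − *E*) / (*zF*), with Nernst
  potentials *E* = (*RT*/*zF*)·ln(*c*_cyt/*c*_lum);
* ASOR gating: *p* = [1 + 10^(*n*·(pH − pH_½))]⁻¹ · [1 + e^((U−U_½)/k)]⁻¹
  (acid- and hyperpolarization-activated, pH_½ = 5.3);
* CLC 2Cl⁻/H⁺ exchange: rate ∝ (*U*_rev − *U*) with
  *U*_rev = −(2·*E*-term(Cl) + *E*-term(H))/3 from the cycle free energy
  ΔG = 2RT·ln([Cl]_c/[Cl]_l) + RT·ln([H]_l/[H]_c) + 3FU — exactly zero flux
  at equilibrium — gated by voltage and partially inhibited by acid;
* V-ATPase: *J* = *J*_max·*A*·max(0, 1 − pmf/pmf_stall), with
  pmf = *U* + (RT/F)·ln10·(pH_cyt − pH_lum).

The wired-together system reproduces the experimental signatures: the lumen
swings from +70 mV to negative as Na⁺ leaves, acidification opens ASOR,
Cl⁻ follows, and two negative feedback loops (hyperpolarization and
alkalinization both close ASOR) make shrinkage resilient to channel copy
number. See `docs/methods.md` for every equation, parameter and assumption.

## Worked example

Simulate the wild-type preset for 10 minutes and scan ASOR density:

```text
$ mpresolve simulate --scenario WT --duration 600 --out wt.csv
WT: V(end)/V(0) = 0.190, pH(end) = 5.53 -> wt.csv

$ mpresolve scan --param g_ASOR --factors 0,1,10
 factor  V_fraction   pH_end
    0.0    0.537582 4.738519
    1.0    0.190067 5.532046
   10.0    0.173969 5.705101
```

Read: the wild-type MP keeps 19 % of its volume after 10 min with luminal
pH 5.53 (the observed values are ~20 % and ~5.5). Removing ASOR
(factor 0 = TMEM206 knockout) leaves a much larger, *more acidic* vesicle —
without the Cl⁻ conductance the lumen stays strongly negative and protons
keep flowing in. Ten-fold ASOR overexpression changes the outcome by less
than 10 %: the feedback loops, not the channel count, set the pace.

The end-to-end demo renders wild-type and knockout movies, measures them
with the full detection/tracking chain, and compares against the simulated
ground truth:

```text
$ mpresolve demo --out-dir demo_out --seed 7
WT: measured end volume fraction 0.22 (simulated 0.19), 28 tracks
TMEM206_KO: measured end volume fraction 0.51 (simulated 0.54), 28 tracks
```

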