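# Methods

## Model structure

The host cell is the coarse-grained growth model of Weiße et al. (2015,
PNAS): a fixed external substrate is imported (`v_imp = p_T·v_T·s_ext/(K_T+s_ext)`)
and catabolised (`v_cat = p_E·v_E·s_i/(K_E+s_i)`) into an abstract energy
species `e` that drives both transcription and translation. Transcription
of class *X* is `T_X(e) = ω_X·e/(o_X+e)`; housekeeping transcription is
additionally autoinhibited by `1/(1+(p_H/K_H)^h_H)`, which is what keeps
the proteome balance finite. Translation of a ribosome–mRNA complex is
`T_L(c,e) = c·γ(e)/n` with `γ(e) = γ_max·e/(K_γ+e)`; every elongation step
consumes one energy unit, so the energy balance loses `γ(e)·Σc`. Growth
dilutes every species at `λ = γ(e)·Σc/M`, where the sum runs over **all**
translating complexes — host classes, circuit genes, and every orthogonal
pool — because all of them produce proteome mass.

Ribosome biosynthesis is resolved into two components. The
ribosomal-protein transcript `m_R` is translated into the "empty ribosome"
`p_R` (one lumped species standing for both subunits' proteins and
accessory factors); the rRNA `r` is transcribed directly. The two associate
reversibly, `p_R + r ⇌ R`. An orthogonal pool *k* adds a synthetic 16S
rRNA `ρ_k` transcribed at `ω_ρ·e/(o_ρ+e)` which competes for the same
`p_R`: `p_R + ρ_k ⇌ P_k`. `P_k` binds only the mRNAs of circuit genes
allocated to pool *k*; host ribosomes never bind orthogonal-RBS mRNAs
(the reverse interference is exposed as an optional cross-binding rate
`b_cross`, default 0, which when enabled adds one extra complex species
per host-RBS circuit gene and pool).

Free-ribosome balances follow the reaction scheme exactly: binding
consumes the free ribosome (`−b·R·m`), dissociation (`+u·c`) and
completed translation (`+T_L`) release it. The same holds for each `P_k`
restricted to its own gene set, and `p_R` gains the `⇌` exchange terms of
every pool it feeds.

## Default parameters

Host defaults are the published fitted values of the source growth model:
`v_T=726`, `K_T=10³`, `v_E=5800`, `K_E=10³`, `n_s=0.5`, `ω_T=ω_E=4.14`,
`ω_H=948.93`, `ω_R=930`, `o_T=o_E=o_H=4.38`, `o_R=426.87`,
`K_H=1.52219·10⁵`, `h_H=4`, `b=u=1` for all host RBSs, `n_T=n_E=n_H=300` aa,
`n_R=7549` aa, `γ_max=1260` aa/min, `K_γ=7`, `M=10⁸` aa, `δ_m=0.1` /min,
`s_ext=10⁴` molecules. Splitting the ribosome gene into protein and rRNA
components introduces parameters the source model did not have; we give
the rRNA the ribosomal transcription parameters (`ω_r=930`, `o_r=426.87`),
assembly rates `b_r=u_r=1`, and let RNAs degrade (`δ_r=0.1`) while
proteins and assembled ribosomes only dilute (`δ_R=δ_pR=0`). At these
defaults the unburdened cell grows at λ≈0.0153 /min with ribosomal mass
fraction Φ_R≈0.33.

Orthogonal-pool defaults mirror the host rRNA (`b_ρ=u_ρ=1`, `δ_ρ=0.1`)
except the transcriptional threshold: the o-rRNA is plasmid-carried and
responds to energy like an ordinary (non-ribosomal) host gene, so
`o_ρ=4.38`. Its maximal rate `ω_ρ` is the experiment's induction dial
(figures use 500 rRNAs/min unless stated). Circuit genes default to
`o_Y=4.38`, `n_Y=300` aa, `b_Y=u_Y=1`, `δ_mY=0.1`; their transcription
rate `ω_Y` is the induction input — the mapping from inducer concentration
to ω is experimental and not modelled.

## Quantities reported

- `ribosome_mass_fraction` counts `R`, `p_R`, every mRNA-bound complex and
  every free `P_k`, each weighted by `n_R/M`. rRNA mass is excluded: `M`
  is a protein mass.
- The **isocost slope** is an ordinary least-squares line through *all*
  converged sweep points of (induced, constitutive) steady-state protein.
  Two scales are always emitted: raw molecules, and each reporter
  normalised by its maximum over the sweep. Configuration comparisons use
  the normalised slope, which is the scale on which differently sized
  pools can be compared; the per-sweep normalisation is one of two
  defensible readings (the alternative normalises across a whole set of
  ω_ρ values; raw values are retained so either can be recomputed).
- The **two-pool decoupling** objective is the magnitude of the
  constitutive reporter's percent change between the lowest and highest
  induction; the grid table of all (ω_ρ1, ω_ρ2) candidates is returned so
  the trade-off surface is inspectable.

## Steady-state solving

Cold solves integrate with BDF (rtol 1e-9, atol 1e-12) to t=10⁵ min and
polish the endpoint with one Powell-hybrid (Newton-type) root pass;
warm-started solves (sweeps, Monte Carlo, fitting) go straight to the root
pass and fall back to integration if it leaves the non-negative orthant or
fails to reach the residual tolerance. Convergence means the scaled
residual `max_i |f_i|/max(1,|y_i|)` is below 1e-6; the flag is reported
rather than raised, and non-converged sweep points are retained in tables
but excluded from line fits. Reported states are clipped at zero (solver
undershoot below −1e-9 is treated as error). The all-zero state is an
exact equilibrium, and a pool with `ω_ρ=0` and empty o-species reproduces
the base model's right-hand side bitwise — the reduction tests rely on
this.

## Pathway model

The violacein-style chain is an irreversible Michaelis–Menten cascade:
`v_i = kcat_i·p_i·S_i/(Km_i+S_i)` with `S_1` a constant external
tryptophan level and `S_i = I_{i−1}` thereafter; intermediates and the
product dilute at λ. Enzyme A has its own promoter (`ω_A=25`); B–E form a
polycistronic cassette modelled as four mRNA species sharing one
transcription rate and one RBS strength, differing only in length — vioB
defaults to 3× the others, reflecting its outsized ribosome sequestration.
Kinetic defaults are uniform (`kcat=10` /min, `Km=10³`, substrate 10⁵
molecules) and fully exposed; the chain topology and constants are a
declared reconstruction chosen as the simplest scheme consistent with an
activation-cascade analogy, so only allocation *contrasts* (host- vs
o-pool vioA), not absolute fluxes, should be interpreted.

## Controller

The repressor F is an ordinary circuit gene on the pool it controls; its
protein gates that pool's o-rRNA transcription multiplicatively by
`1/(1+(p_F/k_D)^h)` — nothing else is regulated. Defaults `h=2`
(dimerising repressor) and `k_D=500` molecules put the sensor in its
responsive range at typical repressor levels; both are design parameters.
The *open loop* comparator is the same circuit with the controller absent
(equivalently `ω_F=0`, the convention used throughout); `tune_open_loop_match`
root-solves the open loop's ω_ρ so both variants give the same
pre-induction constitutive expression within 0.1%.

Design is a deterministic log-spaced grid search over any subset of
`{ω_ρ_max, b_F, k_D, h, ω_F}` minimising `J = |slope_norm| + w·shortfall`,
where shortfall is the relative resting-expression loss against the
uncontrolled reference; the exact objective the original design study used
is not stated anywhere, so J is a declared choice and the full evaluated
frontier is returned for re-scoring. The robustness study multiplies all
twelve o-rRNA/controller parameters `{ω_ρ, o_ρ, b_ρ, u_ρ, δ_ρ, ω_F, o_F,
b_F, u_F, n_F, k_D, h}` by independent Uniform(1−f, 1+f) factors per draw
(f=0.5 by default; uniform is the minimal reading of "random values
between ±50%" and is configurable), seeded and bit-reproducible;
non-converged draws are excluded and counted.

## Synthetic growth-law data

`generate_growth_law_data` emulates the classic growth-law experiment:
conditions are a grid of nutrient qualities (`n_s`) crossed with
translation-inhibitor strengths, the latter modelled as a multiplicative
factor on `γ_max` (the standard coarse-grained reading of a
chloramphenicol titration). Observations are the model's own steady-state
(λ, Φ_R) with multiplicative Gaussian noise of relative scale σ. What the
generator deliberately does **not** emulate: biological replicate
structure, instrument calibration, growth-curve fitting error, or any
mismatch between the model family and a real cell. Passing the recovery
tests therefore shows the fitting machinery is correct and the data are
informative about `{γ_max, ω_R, …}` — not that the model would fit real
growth-law measurements without bias. Fitting is weighted least squares on
relative (λ, Φ_R) residuals, optimised in log-parameter space within
bounds, deterministic given the start.

## Problem sizes

Analyses are sized for a desk-scale study: isocost sweeps use ~6–10
log-spaced induction points; the two-pool optimisation evaluates an 8×8
pool-size grid over a 10-point sweep (≈640 steady states, a few minutes);
the robustness Monte Carlo runs 1000 draws over a 6-point sweep. Warm
starting makes each additional steady state a few milliseconds, so larger
grids scale linearly.

## Known limitations

- One fixed parameter set: the original study's supplementary parameter
  tables are not reproduced here, so defaults inherit the source growth
  model plus the declared extensions above; quantitative outputs are in
  model units, not calibrated to fluorescence.
- Within a single shared orthogonal pool, the translation budget is fixed
  (total P ≈ assembly flux/λ), so two genes on one pool split it almost
  zero-sum and their normalised coupling is slightly *stronger* than on
  the buffered host pool (≈−0.9 vs ≈−0.8 at defaults). The in vivo
  observation that an all-orthogonal circuit couples less than an all-host
  one is an instrument-scale result this model family does not reproduce;
  the mixed allocations (insulated constitutive gene mildest, o-induced
  against host-constitutive harshest) are reproduced.
- No RNA-polymerase competition, no tRNA pool, no stochasticity, no cell
  volume or SSA; tethered-subunit ribosomes are out of scope.
- The pathway and controller supplementary equations were not available;
  both are declared reconstructions with all constants exposed in the
  config schema.
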