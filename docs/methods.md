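# Methods

`semdem` simulates word acquisition and its breakdown under simulated
semantic dementia in a brain-constrained network of twelve cortical areas.
This note documents the model, its parameters and the design decisions a
user should know before interpreting results.

## Architecture

Twelve areas stand for left-hemisphere fronto-temporo-occipital cortex,
grouped in four zones of three areas (primary → secondary → higher
association): auditory A1–AB–PB and articulatory M1i–PMi–PFi (together the
**perisylvian**, word-form system), and visual V1–TO–AT and hand-motor
M1L–PML–PFL (the **extrasylvian**, semantic system). Adjacent areas of a
zone are reciprocally connected; four long-distance pairs (AT–PFi, PB–PFi,
AT–PFL, PB–PFL) stand for the arcuate/uncinate fascicles and extreme
capsule. AT is therefore the only bridge between the visual stream and the
language system, which is what makes its lesion interesting. Two further
hub–hub pairs (AT–PB, PFi–PFL) can be enabled by a configuration switch and
are off by default.

Each area is a 25 × 25 sheet of excitatory (e) graded-response cells, each
paired with one inhibitory (i) cell that pools the output of the 5 × 5 patch
of e-cells around it and subtracts from its matched e-cell. Excitatory
links — recurrent within-area and reciprocal between-area — are sparse,
patchy and topographic: a candidate link inside a 19 × 19 window is drawn
with probability `p0·exp(−d²/2σ²)` of the topographic distance d (defaults
p0 = 0.28, σ = 4.5 for both kinds; mean out-degree ≈ 25–35 per projection,
a few percent of the window). Kernels clip at sheet borders; there is no
toroidal wrap-around, since the sheets model cortical patches. Initial
efficacies are uniform on (0, 0.2·w_max]; this relatively generous floor is
what lets a stimulated area bias, through noise, which downstream cells its
assembly recruits.

## Cell dynamics

Per discrete time-step (`DynamicsParams`), an e-cell integrates

    V ← V + (1/τ_m)(−V + gain·(synaptic + stimulus) − k_loc·I − k_glob·G + η)

with membrane constant τ_m = 2.5 steps, local inhibition from the matched
i-cell (k_loc = 0.6; the i-cell is itself a leaky integrator, τ_i = 2, of
the pooled 5 × 5 output), slow area-global inhibition G (a low-pass of the
area's total output, τ_g = 8, weight k_glob = 0.15) and uniform white noise
η ∈ [−0.3, 0.3] present in every cell during every phase. The output is a
clamped-linear ("ramp") function

    O = clip(V − α·a − h·s − φ, 0, 1),       φ = 0.18

with two adaptation variables: a fast one `a` (low-pass of O, τ_a = 25,
weight α = 2.8) that terminates each assembly ignition a few steps after
stimulus offset, and a slow activity-average `s` (τ_h = 400, weight
h = 3.0) that acts as firing-rate homeostasis. Because the ramp gives exact
zeros below threshold, network activity is sparse at all times and the
simulator only propagates the out-links of currently active cells — this,
not approximation, is what makes full-size training fast. A logistic
transfer and a raw identity transfer (used by the linear-response tests)
are available via `DynamicsParams.transfer`.

The slow homeostatic term deserves justification, as it goes beyond the
textbook leaky-integrator-plus-adaptation cell. Hub areas receive no
direct sensorimotor input, so their assembly membership is decided purely
by internal competition, and cells with by-chance high in-degree win the
competition for *every* word, collapsing all word circuits onto one shared
hub assembly. A penalty proportional to a cell's slow activity average
makes promiscuous firing expensive and is the standard homeostatic
counter-force to rich-cell takeover. Without it (set `homeo_strength = 0`)
the model still learns, but word specificity in hub areas degrades.

## Hebbian learning

All e→e links are plastic (`PlasticityRule`); inhibitory wiring is fixed.
Per step and link, with pre-synaptic output O_pre and post-synaptic
potential V_post:

* O_pre ≥ θ_pre and V_post ≥ θ_post → w += δ_ltp (LTP),
* O_pre ≥ θ_pre and V_post < θ_post → w −= δ_ltd (homosynaptic LTD),
* O_pre < θ_pre and O_post ≥ θ_pre → w −= δ_ltd_het (heterosynaptic LTD),

then clip to [0, w_max]. Defaults: θ_pre = 0.25, θ_post = 0.20,
δ_ltp = 0.004, δ_ltd = 0.001, δ_ltd_het = 0.002, w_max = 1. Three choices
matter:

1. **The post side of LTP gates on membrane potential, not output.** A
   still-silent cell that is consistently depolarised by a stimulus-locked
   input can recruit that input; this bootstraps assembly growth beyond the
   clamped primary areas.
2. **Homosynaptic LTD is weaker than LTP** (ratio 1:4). Assembly members'
   potentials oscillate around θ_post during inhibition-paced bursting;
   with symmetric rates those oscillation dips erode exactly the links that
   carry the circuit, and nothing beyond the directly stimulated areas ever
   consolidates.
3. **Heterosynaptic LTD gates on the post-synaptic cell firing** (output ≥
   θ_pre), not merely being depolarised. The erosion of a cell's silent
   inputs then scales with how often the cell fires, i.e. with its
   promiscuity: a cell serving many word circuits sheds all but its
   best-supported inputs, while a weakly depolarised candidate that is
   still being recruited is spared. With the depolarisation-gated variant
   the model sits on a knife edge between circuits that never span the hub
   areas and circuits that merge there.

## Training protocol

A word is a set of concurrent 19-cell binary patterns (≈3% of a sheet):
A1 + M1i + V1 for object words, A1 + M1i + M1L for action words. A trial
clamps the word's patterns (input current 8.0) for 16 steps with plasticity
on; the non-involved primary area (M1L for object words, V1 for action
words) receives a fresh random 19-cell pattern each trial, so nothing
consistent can be learned from it. The inter-stimulus interval runs with
plasticity off and extra "environmental" noise (amplitude 0.15) in the four
primary areas, and ends when the slow inhibition of PFi and PB falls below
1.5 (at least 4, at most 50 steps) — so one trial's reverberation does not
leak into the next. Keeping plasticity off during the ISI is a deliberate
choice: learning is meant to be driven by the sensorimotor co-occurrence
structure, and with plasticity on during reverberant ISIs, consecutive
trials' circuits associate with each other. Words are trained interleaved,
one block = every word once in fresh random order.

Profiles: `full` is the original design (13 instances × 12 words × 3000
trials; tens of hours of compute per instance at the original scale) and
`scaled` keeps the architecture at full size but trains 300 trials per word
with 5 instances (~1 minute of training per instance here); the
architecture is never shrunk, so all structural invariants remain testable.

## Lesions

Both lesion types target area AT of a trained network, on independent deep
copies (one GM arm, one WM arm, per the two-copies design). Grey-matter
damage inactivates `floor(f·625)` uniformly sampled AT e-cells: they emit
zero, are frozen, and are excluded from plasticity and the assay; their
synapses remain in place. White-matter damage removes `floor(f·|L|)` links
sampled uniformly from the population L of all plastic e→e links with
either endpoint in AT (within-AT links counted once); cells stay alive.
Severities f ∈ {0, 0.3, 0.6, 0.9}; floor rounding never exceeds the stated
severity. Each severity is lesioned independently on a fresh copy of the
trained arm; a nested mode (`LesionSpec.nested`), in which the 30% damage
set is a prefix of the 60% set and so on, is available for within-instance
severity trajectories but is not the default.

## Responsiveness assay

Cell-assembly membership is identified in the intact network: present the
word's full multi-area pattern for 2 steps, record every e-cell's output
over those 2 plus the following 15 steps, and take each cell's
time-averaged output ω (the plain mean over the 17-step window). Within
each area A, the threshold is θ(w, A) = γ·max ω with γ = 0.5, and a cell is
responsive iff ω exceeds θ strictly *and* exceeds an absolute floor of
0.05. Word-processing integrity before/after lesion is the per-area count
of CA members responsive after an auditory-only cue (the A1 pattern alone,
2 steps); counts can be averaged over several cue repetitions
(`AssayConfig.cue_repetitions`, default 1, matching a single presentation). Plasticity is off and baseline noise stays on throughout; state
is reset and re-settled under baseline noise before each cue.

The absolute floor is the one departure from a purely relative criterion,
and it exists because of scale: in an area whose responses a lesion has
destroyed, max ω collapses to the noise floor, and a relative-only rule
then promotes chance noise crossings to "responsive" cells. The asymmetry
is not neutral — cells disconnected by a white-matter lesion still jitter
with noise, while grey-matter-inactivated cells are forced silent — so
without the floor, white-matter damage is systematically under-measured.

## Statistics

Counts are normalised per instance to the intact (severity-0) condition;
system-level ratios sum counts over the six areas of a system before
dividing, and decline is 100·(1 − ratio at 90%). Repeated-measures ANOVAs
(instances as subjects; ExtraPeri × Severity per lesion type, WordType and
LesionType factors on extrasylvian counts) are computed through pingouin,
with Greenhouse–Geisser-corrected p-values reported alongside uncorrected
F. Follow-up dependent-sample t-tests are Bonferroni-corrected within
their stated family. The package also carries an exact combinatorial
oracle for the expectation argument of why link removal should beat cell
removal: the expected number of assemblies hit by removing n elements
uniformly without replacement, by exhaustive enumeration of removal subsets
(or the equivalent hypergeometric closed form when enumeration is
infeasible).

## What the scaled profile does and does not show

With the scaled defaults the model reproduces, across seeds: formation of
word-specific distributed circuits (mean pairwise overlap a few percent of
circuit size; the full-scale literature value for this architecture family
is < 5%); the category double dissociation in circuit distribution (object
circuits hold visual-zone cells, action circuits hand-motor-zone cells);
and the headline lesion result — AT damage collapses extrasylvian
("semantic") responsiveness by tens of percent while perisylvian
("word-form") responsiveness declines by only a few percent, for both
lesion types and both word categories.

Three full-scale observations are *not* reproduced at 300 trials, and the
package reports them honestly rather than tuning toward them:

* **Ignition breadth.** Auditory-only cues reactivate circuit cells in
  about 5 areas beyond A1 on average (best words 9–11), not the ≥ 8
  expected at full scale. At scaled trial counts there is a sharp trade-off
  between hub-circuit consolidation (deep ignition) and hub-circuit
  word-specificity; the defaults favour specificity, because without it the
  lesion assay is meaningless. Longer training with proportionally slower
  learning rates deepens ignition, at compute budgets outside a desk run.
* **WM > GM.** At 90% severity both lesion types already floor the
  AT-mediated pathway at this scale, and the white-vs-grey difference in
  extrasylvian decline is within instance noise.
* **Object > action.** The category-specific severity gradient is small at
  full scale and is lost in instance noise here, for the same dynamic-range
  reason.

## Numerical and reproducibility notes

All randomness flows from a single master seed through named
`SeedSequence` spawns (per instance and per component: build, patterns,
training, assay, each lesion arm/severity), so any table is regenerable
from its configuration and seed, and sub-seeds stay below 2³¹. Networks
snapshot losslessly to HDF5 (schema-versioned; weights, masks, dynamic
state and the embedded architecture config), and a save/load round-trip
followed by continued training is bit-identical to an uninterrupted run.
Degenerate inputs are defined: zero-variance ANOVA tables report a
degenerate result rather than raising; an all-silent area has θ = 0 and no
responsive cells (strict inequality); γ = 1 makes every cell
non-responsive; lesion fractions are validated to [0, 1].
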