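# semdem

A brain-constrained neural network model of word acquisition, and of its
breakdown under simulated semantic dementia.

Semantic dementia (SD) progressively destroys anterior temporal cortex and,
with it, the meaning of words — while the ability to *repeat* words stays
comparatively intact. `semdem` is a research simulator for studying why.
It implements a twelve-area network of left-hemisphere fronto-temporal and
occipital cortex in which "words" are learned bottom-up, with no
pre-assigned locus for meaning: repeated co-presentation of auditory,
articulatory and visual (or hand-motor) activity patterns, under Hebbian
plasticity alone, grows distributed **cell assemblies** — sets of strongly,
reciprocally connected cells spanning word-form (perisylvian) and semantic
(extrasylvian) areas. Grey-matter damage (inactivating cells) and
white-matter damage (removing links) can then be applied at graded severity
to the anterior-temporal hub area AT, and the surviving word circuits are
measured by how many of their cells still respond when only the word's
*sound* is presented. It is written for computational neuroscientists and
psycholinguists who want a lesionable, fully unsupervised alternative to
hub-and-spokes models trained with error-driven learning.

## The model in brief

* Twelve areas in four zones (auditory A1–AB–PB, articulatory M1i–PMi–PFi,
  visual V1–TO–AT, hand-motor M1L–PML–PFL), 625 excitatory + 625 inhibitory
  graded-response cells each; sparse, patchy, topographic within- and
  between-area links initialised to weak random efficacies.
* Per-step cell dynamics: leaky integration with temporal summation, a
  clamped-linear output nonlinearity, fast spike-rate adaptation, a slow
  homeostatic activity penalty, local (5×5-pooled) and slow area-global
  inhibition, and uniform white noise in every cell at all times.
* Learning: a discrete-threshold Hebbian rule with LTP, homosynaptic and
  heterosynaptic LTD on all excitatory links — no gradients, no error
  signal, no supervision.
* Assay: a cell is *responsive* to word w in area A when its time-averaged
  output exceeds θ(w,A) = γ·max ω (γ = 0.5). The per-area count of
  responsive assembly cells after an auditory-only cue is the unit of
  word-processing integrity.

See `docs/methods.md` for the equations, parameter values and design
rationale.

## Worked example

Train two network instances on six object- and six action-related words
(scaled profile: 300 trials per word), lesion each instance's
anterior-temporal area both ways at 30/60/90% severity, re-assay every word
from its auditory pattern alone, and summarise the decline at 90% severity
relative to the intact network:

```python
import dataclasses
import semdem
from semdem.config import PROFILES

cfg = dataclasses.replace(PROFILES["scaled"](), n_instances=2)
result = semdem.run_experiment(cfg, seed=11)

declines = result.declines()
print(declines.pivot_table(index=["lesion_type", "category"],
                           columns="system", values="decline_pct").round(1))
```

```
system                extrasylvian  perisylvian
lesion_type category
GM          action            34.1          5.8
            object            15.8          2.5
WM          action            27.7          3.7
            object            24.0          2.7
```

The pattern is the model's central result: lesioning the AT hub collapses
responsiveness in the *semantic* (extrasylvian) system by tens of percent
while the *word-form* (perisylvian) system loses only a few percent — the
dissociation between impaired comprehension and spared repetition seen in
SD patients. (`result.table` holds the full long-format per-area counts;
`semdem.experiment.standard_battery` runs the repeated-measures ANOVAs and
Bonferroni-corrected t-tests on them.)

The combinatorial argument for why removing links should hurt more than
removing the same fraction of cells is available as an exact enumeration:

```bash
$ semdem oracle
remove 1 of 2 cells : expected assemblies affected = 1.0
remove 2 of 4 links : expected assemblies affected = 5/3 ~= 1.6667
```

The same CLI exposes `build`, `train`, `lesion`, `experiment` (with
`--profile {scaled,full}`, `--seed`, `--config`, `--dry-run`) and `stats`
subcommands; networks snapshot losslessly to HDF5 and configurations load
from YAML.

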