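# clutchkit

Tools for testing the **egg-arrangement hypothesis** of brood parasitism:
that host birds notice when the spatial arrangement of their clutch has
been disturbed and use that as a cue to reject a foreign egg.  The package
re-implements the measurement and analysis pipeline of a three-treatment
field experiment on European blackbirds (*Turdus merula*) — control
(clutch untouched), constant (a non-mimetic model egg added at the cup
edge), rearranged (clutch shuffled, then the egg added) — and, because the
original photographs and nest records were never deposited, ships a
synthetic-data generator that emulates the experiment so every stage is
testable end to end.

It is intended for behavioural ecologists who want to quantify clutch
arrangement from annotated nest photographs, compare before/after clutch
silhouettes, or power/validate rejection-experiment analyses by
simulation.

## What it computes

**Arrangement metrics** (per egg, from pole annotations): blunt pole
distance `d_i = ||b_i − c||`; blunt pole angle (direction of `b_i − c`,
period 360°); blunt pole orientation (long-axis angle, axial, period
180°); adjacent angles (axial angle between long axes of clockwise
neighbours, cyclic).  Nest-level change between photographs is the
per-egg two-point SD of each metric — `|Δ|/√2` for distances, Mardia's
circular SD `√(−2 ln R)` for directional angles and its doubled-angle
analogue for axial ones — averaged over host eggs.

**Mask dissimilarity**: before/after binary silhouettes are registered
(centroid translation + isotropic area-matching scale), then scored as

    dissimilarity = (# unmatched pixels of both masks) / (# pixels in union)

where a pixel is matched when the other mask's distance transform there is
≤ a tolerance (default 2 px).  0 = identical, 1 = no overlap within
tolerance.

**Statistics**: per-group desertion/ejection rates; Fisher's exact test
(full enumeration and Monte-Carlo p with 100,000 conditional draws;
conditional-MLE odds ratio with exact CI); a binomial GLM (logit) for
ejection vs acceptance; a negative-binomial GLM (log link, ML dispersion)
for latency to ejection; likelihood-ratio χ² per term, Bonferroni
family-wise Wald CIs, VIF, Nagelkerke R²; and backward elimination that
always retains the treatment term.

See `docs/methods.md` for conventions, parameter defaults and limitations.

## Worked example

```python
from clutchkit.pipeline import RunConfig, run_experiment, format_report

report = run_experiment(RunConfig(seed=1), outdir="runs/demo")
print(format_report(report))
```

prints (abridged):

```
Desertion / ejection rates
             n  n_deserted  desertion_pct  n_scored  n_ejected  ejection_pct
control     19           3           15.8        16          0           NaN
constant    30           2            6.7        28         23          82.1
rearranged  30           6           20.0        24         20          83.3

Group dissimilarity (mean +/- SD)
             mean    std  count
control    0.0211 0.0117     19
constant   0.3115 0.0463     30
rearranged 0.5112 0.0958     30

Fisher exact test (desertion, control vs parasitized): OR=1.22 CI=(0.19, 5.88) p=0.72 p_MC=0.7236
```

Reading this: 19/30/30 nests were simulated under the default (study)
conditions.  The dissimilarity means are strictly ordered control <
constant < rearranged — untouched clutches barely change between
photographs (~2% mismatch), adding an egg changes the silhouette
substantially (~31%), shuffling most of all (~51%) — confirming the
manipulation produces three distinct disruption levels.  Desertion is
unrelated to treatment (Fisher p = 0.72), so the response model compares
ejection only among non-deserted parasitized nests.  The run directory
receives the annotation/outcome/change-score CSVs, mask PNGs, model
tables and this report.

The same stages are available from the shell:

```sh
clutchkit simulate --n-control 19 --n-constant 30 --n-rearranged 30 --seed 1 --outdir runs/demo
clutchkit measure --annotations runs/demo/annotations.csv --out runs/demo/scores.csv
clutchkit dissim --before runs/demo/masks/K001_before.png --after runs/demo/masks/K001_after.png
clutchkit analyze --outcomes runs/demo/outcomes.csv
clutchkit reproduce
```

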