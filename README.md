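# milgrade

Weakly-supervised grading of breast-cancer whole-slide histopathology
images, with survival analysis of the predicted grade groups.

Tumor grade (the Nottingham system: nuclear pleomorphism + tubule
formation + mitotic count, summed to grade 1–3) is one of the strongest
prognostic factors in invasive breast cancer, but pathologist grading
shows substantial inter-observer variation, and most automated graders
need tumor annotations. `milgrade` implements an annotation-free
alternative: **multiple-instance learning (MIL)** over whole-slide
images. A slide is a *bag* of 224×224 tissue tiles at 10× magnification
carrying one binary label (high grade vs low/intermediate); a bag is
positive iff it contains at least one positive instance. Training
iterates two steps — score up to 512 random tiles per slide, select the
top 5 by high-grade probability, then train on those 5 with the slide's
label by SGD (lr 0.007, momentum 0.9, batch 256, weight decay 0.01,
heavy augmentation) — with multi-task heads (component grades, HR/HER2
status) sharing all layers but the final dense layer, trained on the
unweighted sum of binary cross-entropies. Slide-level prediction is the
majority vote of the top-5 tiles; model selection maximizes validation
Cohen's κ; tile-probability heatmaps show where the model looks.
Predicted grade groups feed Kaplan–Meier / log-rank comparisons and
univariate or subtype-stratified multivariate Cox models for three
endpoints (overall, distant-recurrence-free and recurrence-free
survival).

Real graded WSI cohorts are private, so the package includes a
**synthetic slide generator** with the exact statistical structure MIL
assumes — positive slides carry a minority of discriminative "motif"
tiles, calibrated so mean color carries no signal — plus correlated
auxiliary labels and grade-dependent exponential survival. Every part
of the pipeline is testable end to end with no data download. See
`docs/methods.md` for the model details and design choices.

## Worked example

```
python examples/synthetic_mil_training.py
```

trains the MIL loop on 32 synthetic slides (24 train / 8 validation,
30% motif prevalence) for 25 iterations and prints:

```
best validation kappa: 1.000
per-iteration kappa: [0.0, 0.0, 0.0, 0.0, 0.0, 0.75, 1.0, 1.0, ...]
motif fraction among top-5 tiles of positive validation bags: 1.00
```

Validation κ = 1.0 means the recovered slide labels agree perfectly
with the generating labels; the motif fraction of 1.00 (against a 0.3
prevalence baseline) means the top-5 selections are exactly the
discriminative tiles — the loop found the *instances*, not just the bag
labels. `examples/survival_analysis.py` runs the survival side on a
600-patient generated cohort (true hazard ratio 2.0):

```
8-year OS, low/intermediate grade: 77.3% (95% CI 72.2-81.7)
8-year OS, high grade: 63.7% (95% CI 57.9-68.8)
log-rank: chi2=13.9, p=0.00019
Cox hazard ratio (high vs low/intermediate): 1.77 (95% CI 1.30-2.39)
```

`examples/grade_mapping.py` and `examples/heatmap_demo.py` cover the
grading arithmetic and the interpretability overlay.

## Command line

Each stage is also a `milgrade` subcommand, composable end to end and
writing a `manifest.json` (config, seeds, input digests, timings) per
run:

```
milgrade synth    --config cohort.yaml --out data/ --seed 1
milgrade tile     --slides data/slides --labels data/labels.csv --out bags/
milgrade train    --bags bags/ --labels data/labels.csv --config train.yaml --out run/
milgrade predict  --model run/model.npz --bags bags/ --labels data/labels.csv --out preds.csv
milgrade evaluate --preds preds.csv --labels data/labels.csv --out report/ --seed 1
milgrade heatmap  --model run/model.npz --slide data/slides/slide_0000.tiff --out hm/
milgrade survival --outcomes data/labels.csv --groups preds.csv --endpoint os --out surv/
```

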