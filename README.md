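# conemosaic

Agreement analysis for cone photoreceptor identifications in adaptive-optics
retinal images.

Quantifying the cone mosaic from AOSLO (adaptive optics scanning laser
ophthalmoscopy) images usually starts with an annotator — a human grader or
an automated detector — clicking the center of every cone in a small region
of interest (ROI). Before cone density can be tracked through a disease or a
treatment, one has to know how repeatable and reliable those annotations
are. `conemosaic` implements the full agreement pipeline for that question:
point-set correspondence between annotators, Voronoi-based bound cone
density, and the inter-rater statistics built on both, together with a
synthetic mosaic/annotator generator so the whole closed loop is testable
without any image data.

## Method

**Adaptive matching threshold.** For one ROI, the selections of all
annotators are pooled into a master coordinate list. With dᵢ the distance
from point i to its nearest other point in the master list, the matching
threshold is

    t = mean(dᵢ) + 2 · SD(dᵢ)          (sample SD, n−1)

**One-to-one matching.** All cross-annotator pairs with distance ≤ t are
candidate matches; they are accepted greedily in ascending distance order,
skipping pairs with an already-matched endpoint — the "closer cone wins"
rule made deterministic and symmetric. For more than two annotators the
same greedy pass agglomerates selections into clusters holding at most one
selection per annotator. With a ground-truth and a comparison annotator,
N_TP (matched), N_FN (ground truth only) and N_FP (comparison only) satisfy
N_comparison = N_TP + N_FP and N_ground_truth = N_TP + N_FN exactly, and

    TPR  = N_TP / N_ground_truth
    FPR  = N_FP / N_comparison
    Dice = 2·N_TP / (N_ground_truth + N_comparison)

**Bound cone density.** Each annotation set is Voronoi-tessellated; cones
whose cell is not a closed polygon lying entirely inside the ROI are
excluded, and density = n_bound / Σ(bound cell areas), in cones/mm².

**Reliability statistics.** Bland–Altman bias and 95 % limits of agreement
between paired densities (log₁₀-transformed automatically when the raw
differences fail Shapiro–Wilk normality), ICC(2,1) (two-way random effects,
absolute agreement, single measure) with an F-based 95 % CI and Cicchetti's
qualitative bands, repeated-measures one-way ANOVA with Bonferroni-corrected
post hoc paired t-tests, and the per-ROI coefficient of variation of
density.

## Worked example

```python
import numpy as np
from conemosaic import (ROIMeta, ConePoints, match_threshold,
                        match_pairwise, confusion_from_match, agreement_rates)

roi = ROIMeta("S01", "R01", 100, 100, 0.45, 24.0, 500)
master = [(0, 0), (10, 0), (1, 0), (15, 0)]       # pooled selections
ts = match_threshold(master)
# nearest-neighbour distances [1, 5, 1, 5] -> mean 3.0, SD 2.3094
print(ts.threshold_um)                            # 7.618802153517006

gt   = ConePoints(roi, "gradingA", np.array([(0, 0), (10, 0)]))
comp = ConePoints(roi, "gradingB", np.array([(1, 0), (15, 0)]))
m = match_pairwise(gt, comp, ts)
print(m.matched_pairs)                            # [(0, 0, 1.0), (1, 1, 5.0)]
print(agreement_rates(confusion_from_match(m)))
# AgreementRates(tpr=1.0, fpr=0.0, dice=1.0)
```

Both of grading B's selections fall within the 7.62 µm adaptive threshold
of their grading-A counterparts, so the two gradings agree perfectly
(Dice 1.0) despite the coordinate offsets.

## Analysis scripts

The `analysis/` drivers run a complete synthetic study (17 subjects,
~200 ROIs, three simulated graders) and write their tables to `results/`:

```bash
python analysis/01_simulate_study.py --seed 1   # study files -> scratch/study/
python analysis/02_grader_agreement.py          # TPR/FPR/Dice per ordered pair
python analysis/03_bound_density.py             # bound density per annotator
python analysis/04_reliability_stats.py         # Bland-Altman, ICC, RM-ANOVA
```

With seed 1 the last step prints, among other lines:

```
density ICC(2,1) across annotators: 0.954 (95% CI 0.87–0.98), excellent
mean per-ROI density CoV: 0.084
Bland–Altman truth vs grader1B: transform=log10, bias=0.0612, LoA=[0.009812, 0.1126]
```

i.e. the three simulated graders' densities agree in the "excellent" ICC
band, and the grader with extra spurious marks shows a positive log-scale
density bias against the truth — the qualitative behavior expected of
annotators who over-mark.

The same pipeline is available as a CLI (`conemosaic simulate|density|agree|full`)
driven by flags or a YAML config.

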