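# punctatrack

Quantification tools for live-cell imaging studies of clathrin-mediated
endocytosis and cell migration: scoring of fluorescent puncta (endocytic
vesicles) in cytosolic regions, Pearson colocalization, TIRF co-recruitment
fold changes with inclusion gating, focal-adhesion enrichment, migration
statistics from cell tracks, and the rank-based group comparisons used to
report such measurements — together with a synthetic-data generator that
provides ground truth for every stage, so the whole pipeline can be
validated by parameter recovery.

The package is aimed at cell biologists analysing spinning-disk / TIRF
movies of fluorescently tagged proteins (e.g. the PI3K regulatory-subunit
fragment iSH2 and clathrin adaptor AP2) and TrackMate-exported migration
tracks of fibroblasts.

## Quantities implemented

**Puncta (endocytosis) index.** The raw image *I* is divided pixelwise by
its median-filtered version (square window *w*, default 5×5), and the index
is the dispersion of the ratio over a hand-drawn cytosolic ROI *C*:

- `sd` variant: sample standard deviation of `I / med_w(I)` over *C*
- `skewness` variant (10×10 window, laser-scanning data): moment skewness
  g₁ = m₃ / m₂^{3/2} of the same ratio values

A flat cytosol gives a ratio of exactly 1 everywhere (index 0); bright
diffraction-limited puncta survive the division as local excursions and
inflate the index. The statistic is exactly invariant to intensity
rescaling, because the median filter is scale-equivariant.

**Colocalization.** Pearson product-moment correlation of two channels over
the masked pixels only.

**Co-recruitment index (CI).** In a chemically inducible dimerization TIRF
assay, per-channel fold change = mean(response window) / mean(baseline
window) after background subtraction; baseline is every frame strictly
before the dimerizer-addition frame. CI is the prey fold change; a cell is
*included* only if its bait fold change is ≥ 1.30 (the "at least 30 %
increase" rule).

**Migration metrics.** From tracks sampled every Δt (default 10 min over
16 h, i.e. 97 frames): mean speed D/T (path length over elapsed time, in
µm/min); time- then ensemble-averaged mean square displacement MSD(k);
persistence ratio d/D (net displacement over path length, in [0, 1]);
forward migration index FMI = y/D (net displacement projected on the
gradient axis, over path length). Doubling time from exponential growth:
T_d = t·ln2 / ln(N_f/N_0).

**Group statistics.** Two-sided Wilcoxon rank-sum (exact enumeration for
small untied samples, tie-corrected normal approximation otherwise) for two
groups; the Steel–Dwass–Critchlow–Fligner asymptotic all-pairs test for
three or more, with two-sided p-values from the studentized range
distribution (k groups, ∞ df) at √2·|Z|. Summaries follow the mean ± 2×SEM
and median/quartile/1.5×IQR box-whisker conventions, with significance
stars at 0.05 / 0.01 / 0.001 / 0.0001.

## Worked example

Simulate two "genotypes" that differ only in vesicle abundance, score every
cell's puncta index, and compare the groups:

```python
from punctatrack.pipeline import run_pipeline

cfg = {
    "experiment": "puncta",
    "seed": 7,
    "puncta": {"window": 5, "variant": "sd", "groups": [
        {"label": "wt", "n_cells": 10,
         "image": {"n_puncta": 60, "shape": [128, 128], "radius": 50}},
        {"label": "motif_mut", "n_cells": 10,
         "image": {"n_puncta": 5, "shape": [128, 128], "radius": 50}},
    ]},
}
res = run_pipeline(cfg)
print(res.summaries[["label", "n", "mean", "two_sem", "median"]].to_string(index=False))
print(res.pairwise.to_string(index=False))
```

which prints

```
    label  n     mean  two_sem   median
motif_mut 10 0.108964 0.001698 0.108770
       wt 10 0.171738 0.002226 0.171751

  group_a group_b  statistic  p_value         method stars
motif_mut      wt        0.0 0.000011 wilcoxon-exact  ****
```

The 60-puncta cells score a clearly higher endocytosis index
(0.172 ± 0.002, mean ± 2×SEM) than the 5-puncta cells (0.109 ± 0.002), and
the exact two-sided rank-sum test separates the groups at p ≈ 1.1×10⁻⁵ —
the smallest p attainable at n = 10 per group (complete separation). The
same experiment is available from the shell:

```bash
punctatrack run --config demo.yaml --out-dir out/
```

which writes `per_cell.csv`, `group_summary.csv`, `pairwise_stats.csv`, the
resolved config and a JSON manifest; identical config + seed reproduces
every output byte for byte. Individual stages are exposed as the
subcommands `simulate`, `puncta`, `coloc`, `corecruit`, `translocate`,
`fa-enrich`, `uptake`, `tracks` and `stats`.

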