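# cordpolar

Quantitative histology of the spinal cord gray matter: detect
immunolabelled cells in four-channel confocal cross-sections (ChAT, GAD-67,
Parvalbumin, Calbindin), classify and colocalise them, map every cell into
polar coordinates referenced to the central canal, and compare counts,
normalised radial distances and angular distributions across genotype
groups with linear and circular statistics.

The package is aimed at groups doing marker-based interneuron/motor-neuron
surveys on cord cross-sections who want the whole chain — segmentation,
canal-referenced geometry and the statistics layer — as tested, scriptable
code rather than a pile of macros.  Because raw imaging studies are rarely
shareable, it ships a synthetic-section generator with complete ground
truth, so every stage of the pipeline is verifiable end to end.

## The method

Per section and channel, the imaging chain is

1. maximum-intensity projection of the z-stack;
2. masking to a hand-drawn gray-matter ROI;
3. rolling-ball background subtraction (disk radius 20 px);
4. maximum-entropy thresholding: the cut *t* maximising
   H_bg(t) + H_fg(t), the summed Shannon entropies of the histogram
   partitions (Kapur–Sahoo–Wong), computed on in-mask pixels only;
5. despeckle (3×3 median) and one 3×3 morphological closing;
6. particle analysis with inclusive marker-specific area windows derived
   from somal diameters via A = π(d/2)²: ChAT 10–40 µm (78.5–1256.6 µm²),
   Parvalbumin 10–20 µm (78.5–314 µm²), GAD-67 8–20 µm (50–314 µm²),
   Calbindin 10–25 µm (78.5–490.9 µm²).  ChAT⁺ cells split at 491 µm²
   (25 µm) into presumed interneurons and motor neurons.

A cell of marker A is double positive for marker B when ≥ 20% of its
pixels fall on B's thresholded mask.  Each cell is then mapped to polar
coordinates about the central-canal centroid (0° right, 90° dorsal, 270°
ventral); because anatomical left/right is unidentifiable in free-floating
sections, left-side angles are mirrored, θ′ = 180° − θ, which preserves the
dorsoventral component.  Radial position is normalised to gray-matter size
(default: distance to the canal over the canal-to-boundary distance along
the same ray, so 0 is at the canal and 1 at the tissue edge; two
alternative variants are selectable).

Statistics: cell counts (per-animal sums over eight sections) by one-way
ANOVA across genotypes; per-cell normalised distances by nested one-way
ANOVA (animals within genotype, F = MS_genotype / MS_animal(genotype));
pooled mirrored angles by Fisher's common-median test (the circular
analogue of Kruskal–Wallis), with pairwise two-sample Kuiper tests
(permutation p-values) and Benjamini–Hochberg FDR adjustment as post hocs
after a significant omnibus.

## Worked example

```python
from cordpolar.pipeline import StudyConfig, run_synthetic_study
from cordpolar.synthdata import SectionConfig

config = StudyConfig(
    genotypes=("+/+", "-/+"), animals_per_genotype=2, sections_per_animal=2,
    section=SectionConfig(enforce_separation=True), seed=7, n_perm=300,
)
bundle = run_synthetic_study(config)
print(bundle.count_table.query("cell_class == 'GAD67'"))
print(bundle.circular_tests[["cell_class", "statistic", "p"]].head(4))
```

prints the per-animal GAD-67⁺ counts (sums over each animal's sections)

```
   genotype  animal cell_class  count
3       +/+  +/+_m1      GAD67    184
12      +/+  +/+_m2      GAD67    174
21      -/+  -/+_m1      GAD67    168
30      -/+  -/+_m2      GAD67    177
```

and the omnibus circular common-median tests per cell class

```
          cell_class  statistic         p
0               ChAT   0.832204  0.361636
1   ChAT_interneuron   0.720627  0.395938
2  ChAT_motor_neuron   0.312446  0.576183
3              GAD67   0.001476  0.969353
```

— no genotype effect was injected, so the statistics are null, and the
detected counts equal the generator's ground truth exactly
(`pipeline.evaluate_recovery(bundle.cells, bundle.truth)`).

A CLI wraps the same functionality: `cordpolar simulate`, `cordpolar
segment`, `cordpolar analyze`, `cordpolar stats` (see `cordpolar --help`).

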