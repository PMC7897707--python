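# scaffoldcount

Direct, non-destructive quantitation of cells encapsulated in 3D hydrogel
scaffolds from wide-field fluorescence z-stacks.

Cells cultured inside a thick, often opaque scaffold cannot be counted by
ordinary light microscopy, and indirect assays (metabolic readouts, counts
after scaffold digestion) carry large errors. A practical alternative is to
stain the nuclei in situ (e.g. Hoechst 33342), image each field of view as a
z-stack through the scaffold depth, fuse each stack into a single fully
focused image, and count the bright nuclear cores. `scaffoldcount`
implements that pipeline end to end:

- **z-fusion** — extended-depth-of-field synthesis: for every pixel, keep
  the value from the plane where the local neighbourhood is sharpest
  (selection, not blending, so peak intensities survive).
- **detection** — nuclei are the connected components of pixels strictly
  above an intensity threshold (default 7000 a.u. on a 16-bit scale), which
  both removes out-of-focus residue and splits touching nuclei via their
  brighter centers; components at or above a core-area limit (default
  30 µm²) are rejected as debris or unsplit clusters. A QC "mask" overlay
  records exactly what was counted and why the rest was not.
- **quantitation** — per-field counts become a density

  K = N / (B · C · D · 10⁻⁹)   [cells/mm³]

  where N is the mean nucleus count per field, B and C the lateral field
  size (µm), D the analyzed depth (µm, ≤ 530 recommended) and 10⁻⁹ converts
  µm³ to mm³. Dispersion across fields is reported as the sample standard
  deviation σ (n−1) and the standard error of the mean m = σ/√n.
- **viability** — a second, membrane-impermeant nuclear stain (TO-PRO-3)
  marks dead cells only; the same pipeline on the paired channel gives the
  dead density and percent dead per mm³.
- **proliferation** — densities at successive culture days are compared
  with two-sided Wilcoxon rank-sum tests (exact enumeration for combined
  n ≤ 12, tie-corrected normal approximation otherwise) plus fold changes
  versus seeding or an earlier day.
- **synthetic** — a ground-truthed generator of realistic two-channel
  z-stacks (defocus-blurred Gaussian nuclear cores on a noisy background),
  so every stage is testable without instrument data.

## Worked example

```python
from scaffoldcount import (generate_scene, render_stack, fuse_zstack,
                           segment_nuclei, count_field, density,
                           summarize_densities)
from scaffoldcount.datasets import VAR1_DENSITIES

# Summary statistics of the bundled per-field densities (ten fields of a
# scaffold seeded at 90 cells/mm^3, counted after three days of culture):
mean, sigma, sem = summarize_densities(VAR1_DENSITIES)
print(f"variant 1: mean {mean:.2f} cells/mm^3, sigma {sigma:.2f}, SEM {sem:.2f}")

# Full pipeline on ten synthetic fields with known ground truth:
counts = []
for seed in range(10):
    scene = generate_scene(50, seed=seed)          # 50 nuclei, ground truth known
    stack, _ = render_stack(scene)                 # 6 planes over 530 um
    fused = fuse_zstack(stack)                     # extended depth of field
    objects, _ = segment_nuclei(fused)             # threshold 7000, area < 30 um^2
    counts.append(count_field(objects, stack.geometry(), field_id=f"f{seed}"))
result = density(counts)
print(f"synthetic study: K = {result.K:.2f} cells/mm^3 "
      f"(N = {result.N:.1f} nuclei/field over {result.n_fields} fields, "
      f"sigma {result.sigma:.2f}, SEM {result.sem:.2f})")
```

Output:

```
variant 1: mean 268.70 cells/mm^3, sigma 40.89, SEM 12.93
synthetic study: K = 94.46 cells/mm^3 (N = 50.0 nuclei/field over 10 fields, sigma 0.00, SEM 0.00)
```

The first line reproduces the published two-scaffold validation table: a
three-fold rise from the 90 cells/mm³ seeding, with σ ≈ 15% and SEM ≈ 5% of
the mean. The second line shows exact recovery of the planted ground truth
(50 nuclei per field; every field recovered perfectly, hence zero
dispersion): 50 nuclei in the 999.375 × 999.375 × 530 µm sampled volume is
94.46 cells/mm³.

A command-line interface wraps the same pipeline:

```bash
scaffoldcount synth --out-dir stacks --n-fields 10 --n-nuclei 50 --seed 0
scaffoldcount count --input-dir stacks --out-dir results
scaffoldcount viability --input-dir stacks --out-dir results-viability
scaffoldcount proliferation --table densities.csv --initial-density 90 --out-dir results-prolif
```

## Layout

- `src/scaffoldcount/io_formats.py` — TIFF stack reading, YAML calibration, CSV tables
- `src/scaffoldcount/zfusion.py` — focus-selection fusion and max projection
- `src/scaffoldcount/detection.py` — threshold/area segmentation and QC masks
- `src/scaffoldcount/quantitation.py` — densities, summary statistics, viability
- `src/scaffoldcount/proliferation.py` — time courses, fold changes, rank tests
- `src/scaffoldcount/synthetic.py` — ground-truthed stack generator
- `src/scaffoldcount/cli.py` — `scaffoldcount` command
- `docs/methods.md` — models, parameters, numerical choices, limitations
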