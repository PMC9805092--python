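# surfquant

Quantification toolkit for **yeast surface-displayed enzymes**: how much of a
GFP-tagged enzyme chimera a cell makes, what fraction of it actually reaches
the cell wall, and how fast the resulting whole-cell biocatalyst turns over
its substrate.

Surface display anchors an enzyme to the yeast cell wall by fusing it to a
wall protein (Aga2, Sed1, Tip1, ...). Bulk fluorescence tells you *total*
expression, but much of a secreted chimera can remain stuck inside the cell,
so the catalytically relevant quantity — enzyme concentration at the cell
surface — needs a microscopy-based correction. This package implements that
chain and a synthetic-data generator with known ground truth so every stage
is testable without any external data.

## The method

**Display efficiency from micrographs.** Cells are segmented on a
wall-stain channel (concanavalin A conjugate) and each mask is peeled into
signed one-pixel concentric rings: coordinate 0 is the outermost ring inside
the border, −1 … −9 go deeper, the residual interior is the CORE, and
+1 … +4 lie outside. Wall signal lives in rings 0 … −9. Because the
microscope's point-spread function bleeds intracellular GFP into those wall
rings, intracellular-control strains are used to estimate per-ring bleed
factors

&nbsp;&nbsp;&nbsp;&nbsp;FB_i = ⟨(median_i − bg) / (median_CORE − bg)⟩ over control cells,

and each cell's displayed fraction is computed with a two-stage correction:

&nbsp;&nbsp;&nbsp;&nbsp;GFPint_corr1,i = GFPint_i − bg · P_i
&nbsp;&nbsp;&nbsp;&nbsp;GFPint_corr2,i = GFPint_corr1,i − GFPmed_inner · FB_i · P_i
&nbsp;&nbsp;&nbsp;&nbsp;displayed fraction = Σ_{i∈wall} GFPint_corr2,i / GFPint_corr1,total

where P_i is the ring's pixel count and GFPmed_inner the background-corrected
CORE median.

**Molecules per cell from plate readings.** GFP intensity / OD600
(GFP_corr), expressed relative to a non-fluorescent control (GFP_norm), is
regressed in log10–log10 space against reference strains of known abundance
(2.3 × 10³ – 7.5 × 10⁵ molecules/cell); inverting the line converts readings
to molecules/cell, and a stated cell density converts that to nanomolar
enzyme.

**Whole-cell kinetics.** Endpoint A405 of released *p*-nitrophenol (minus a
paired substrate-autohydrolysis control) becomes product via Beer–Lambert
with a pH-dependent extinction coefficient ε(pH) = ε_max / (1 + 10^(pKa−pH));
initial rates v(S) are fitted with v = V_max·S/(K_m+S), and
k_cat = V_max/[E] uses the displayed-enzyme concentration
(molecules/cell × displayed fraction × cell density).

## Worked example

```python
import surfquant as sq
from surfquant.synthetic import SceneSpec, generate_micrograph

# 1. calibrate bleed-through on synthetic intracellular-control cells
controls = []
for seed in (1, 2):
    mg, _ = generate_micrograph(SceneSpec(n_cells=50, image_shape=(700, 700),
                                          surface_fraction_true=0.0, seed=seed))
    cells = sq.segment_cells(mg.cona)
    rings = sq.peel_rings(cells)
    bg = sq.estimate_background(mg.gfp, rings)
    controls.append(sq.ring_profile(mg.gfp, rings, bg))
fb = sq.BleedthroughEstimator().fit(controls)
print(fb.fb_[-4], fb.fb_[-5])          # 0.552, 0.880 (n = 100 cells)

# 2. displayed fraction of a strain whose true fraction is 0.18
mg, _ = generate_micrograph(SceneSpec(n_cells=50, image_shape=(700, 700),
                                      surface_fraction_true=0.18, seed=3))
cells = sq.segment_cells(mg.cona)
rings = sq.peel_rings(cells)
bg = sq.estimate_background(mg.gfp, rings)
records = sq.quantify_display(mg.gfp, rings, fb, bg)
valid = records[records.valid]
print(valid.displayed_fraction.mean())  # 0.184 (sd 0.009, n = 50 cells)

# 3. surface abundance and whole-cell kinetics
disp, disp_nM = sq.displayed_abundance(1.2e5, valid.displayed_fraction.mean(), 1e8)
print(disp, disp_nM)                    # 2.2e4 molecules/cell, 3.66 nM

from surfquant.synthetic import AssaySpec, generate_kinetics_dataset
spec = AssaySpec(vmax_true=0.6, km_true=25.0, seed=4)
fit = sq.fit_assay(generate_kinetics_dataset(spec), spec.epsilon,
                   spec.pathlength, spec.duration_min, enzyme_nM=disp_nM)
print(fit.vmax_uM_min, fit.km_uM, fit.kcat_per_s, fit.efficiency_per_M_s)
# 0.602 uM/min, 25.6 uM, 2.74 /s, 1.07e5 /(M s)
```

Reading the numbers: the bleed factors say that roughly half and ~90% of
intracellular signal leaks into rings −4 and −5, so an uncorrected wall-ring
integral would badly overstate display; after correction the recovered mean
fraction (0.184) matches the generator's truth (0.18). The kinetic fit
recovers the generating V_max and K_m, and k_cat follows from the displayed
enzyme concentration.

A `surfquant` CLI mirrors the library (`surfquant simulate scene`,
`segment`, `profile`, `calibrate-bleed`, `quantify-display`, `calibrate`,
`abundance`, `kinetics fit`, `fitness`, `run --config run.yaml`); every run
writes its resolved config, seed, config hash and version beside the
outputs.

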