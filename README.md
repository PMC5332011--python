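# woundscreen

Analysis pipeline for high-throughput RNAi scratch-wound migration screens
in endothelial cells — from raw fluorescence images to validated,
cross-cell-type hit lists and morphometric signatures.

In a scratch-wound (wound-healing) assay a confluent monolayer is wounded
mechanically and the cell-free gap is imaged at 0 h and 24 h.  The area
migrated over is

    Am = A0 − A24

where `A0` and `A24` are the cell-free areas at scratch time and endpoint.
In a genome-wide siRNA screen each well's `Am` is normalised to the median
of mock-transfected (lipid-only) wells on the same plate, technical
replicates are averaged, and hits are called with robust z-scores

    z_i = (x_i − median(x)) / (1.4826 · MAD(x))

binned *Inhibited* (z < −2) or *Accelerated* (z > 2).  A nuclei-count
viability gate (*Low Cell Count*: fewer than 3,300 valid nuclei per well,
i.e. <110 cells/field over 30 fields) takes precedence over any migration
bin.  Plate quality is controlled by the strictly standardised mean
difference between the mock and positive-control (siCDC42 / siCDH5) wells,

    SSMD = (mean(neg) − mean(pos)) / sqrt(var(neg) + var(pos)),

with plates passing at SSMD ≥ 1, and by the Pearson correlation of replicate
plates.  Candidate pools are validated by deconvolution into their four
duplexes (*Impaired* < 0.6, *Accelerated* > 1.3 on the normalised scale),
with confidence classes from the number of duplexes reproducing the original
phenotype, and finally re-screened in lymphatic (LEC) vs blood (BEC)
endothelial cells to partition genes into common / BEC-dominant /
LEC-dominant migration regulators.  Eleven morphometric parameters per cell
(area, perimeter, breadth, length, shape factor 4πA/P², elliptical form
factor L/B, two co-occurrence texture moments, and three F-actin intensity
statistics) are aggregated to z-scored signatures and clustered with
correlation distance (1 − Pearson), complete linkage and a fixed cut height
of 1.5.

Every stage runs against synthetic images and plates with exact embedded
ground truth, so the whole pipeline is testable without any external data.

## Layout

- `src/woundscreen/` — the library: `synthetic` (image and plate
  generators), `wound` (wound-area segmentation), `nuclei` (counting and the
  viability gate), `morphology` (segmentation + 11-feature signatures),
  `screen_stats` (normalisation, robust z, SSMD, binning, confidence,
  tertiary classes), `clustering` (correlation-distance clustering),
  `layout` / `workflow` (plate configuration and tier orchestration).
- `analysis/01…06` — numbered drivers reproducing each stage of the screen
  on simulated data; tables are written to `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers (below).

## Worked example

```python
from woundscreen.layout import default_layout
from woundscreen.synthetic import EffectModel, generate_screen_dataset
from woundscreen.workflow import run_primary

effects = EffectModel(inhibitor_effect=0.5, accelerator_effect=1.5,
                      well_noise_sd=0.1, replicate_noise_sd=0.05, seed=17)
table, truth = generate_screen_dataset(10, default_layout(), effects)
res = run_primary(table, truth)
print(res["recovery"])
```

prints the truth-recovery cross-tabulation of the simulated 10-plate screen
(800 library siRNAs):

```
primary_bin  Accelerated  Inhibited  LowCellCount  none
true_class
accelerator           35          0             0     0
inhibitor              0         29             0     0
lethal                 0          0            16     0
neutral                9          1             0   710
```

Every simulated inhibitor (migration ×0.5) is recovered as *Inhibited*,
every lethal siRNA is captured by the viability gate (which suppresses its
migration bin), and 1.4% of neutral siRNAs are false positives at the
|z| > 2 cut.  `analysis/03_primary_screen.py` additionally reports the QC:
all 20 physical plates pass SSMD ≥ 1 (mean siCDC42 SSMD 4.69) and the
median replicate Pearson r is 0.94 under the default replicate noise.

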