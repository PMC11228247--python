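# isletnet

Spatial proximity-network analysis of endocrine–immune cell interactions
during insulitis, the islet inflammation of type 1 diabetes.

Insulitis is transient and strikingly heterogeneous: in the same pancreas,
one islet can be untouched while its neighbour is already destroyed, and
peri-insulitis lesions often form on one *side* of an islet.  Donor-averaged
leucocyte densities hide all of this.  `isletnet` works at the level of
single islets and single cells: given each islet's rim polygon and the typed
nucleus positions of its α-, β-, T-, macrophage and myeloid cells (in μm),
it quantifies which cell types interact, where in the islet, and whether
those interactions could have arisen by chance.  It is written for
quantitative biologists analysing multiplexed immunofluorescence of
NOD-mouse (or similar) pancreas sections, and ships a synthetic-tissue
generator so every statistical property of the pipeline can be validated
against a known ground truth.

## The method

**Staging.**  Each islet is placed on a disease pseudotime by its insulitis
degree, the ratio of T-cells to β-cells counted inside the islet plus a
60 μm margin around the rim:

    degree = n_T / n_β

Islets are sorted by degree and classified early ([0, 0.51)), intermediate
([0.51, 1.25]) or late (> 1.25); they are independently stratified by
cross-sectional area (small < 7,000 μm², medium ≤ 20,000 μm², large above).

**Proximity networks.**  Cells are nodes; a link joins two cells of
*different* types whose centre-to-centre distance is at most a threshold
(15, 20 or 25 μm — one to two cell diameters).  Endocrine cells must lie
inside the rim; immune cells within 20 μm of it.  Interaction strength
between types is the average heterotypic degree

    K_avg(type 1) = (# links of cells of type 1) / (# cells of type 1),

which obeys K_avg(A)·n_A = K_avg(B)·n_B = |E| in any two-type network.

**Randomization null.**  To ask whether immune cells *prefer* particular
islet regions, immune cells are repositioned while endocrine cells stay
fixed: cells are split into inside/outside groups by the sign of their rim
distance, a 1,000-draw normal pool is fitted to each group's distances,
every cell gets a pool distance and a uniform position on the corresponding
offset curve of the rim, and the network is rebuilt.  Over 100 seeds this
preserves the distance-to-rim statistics but erases any angular preference,
so experimental K_avg above the seed distribution indicates genuine
attraction.  A supplementary variant instead shuffles α/β labels in place.

**Architecture-aware analyses.**  Within a ±20 μm outer ring (which
equalizes exposure to peri-islet immune cells), β-cells are split into
α-linked (≥1 α neighbour within the threshold) and non-α-linked, and their
immune K_avg compared pairwise per islet.  Separately, each islet is cut in
half through its rim centroid and the per-half proportions of α-cells and
immune cells are regressed against each other — a positive slope means
immune infiltration is polarized toward α-rich sectors.

**Colocalization preprocessing.**  For the imaging stage, insulin-channel
bleed-through is subtracted from immune-marker channels, images are
median-filtered (disc radius 2 px at 0.5 μm/px), and channel overlap is
quantified with Manders coefficients M1/M2 under an automatic threshold:
channel 2 is regressed on channel 1 (P2 ≈ a·P1 + b) and the threshold T is
stepped down from max(P1) until the sub-threshold pixels are uncorrelated.

## Worked example

Simulate 40 early-stage islets whose immune cells are attracted to
α-cell-rich sectors (ground-truth bias λ = 10), run the full analysis, and
read the three headline results from the report:

```python
from isletnet import CohortSpec, IsletSimParams, PipelineConfig, run_pipeline

cfg = PipelineConfig(
    cohort=CohortSpec(
        n_islets={"early": 40, "intermediate": 0, "late": 0},
        base_params=IsletSimParams(alpha_attraction=10.0),
    ),
    n_seeds=50,
    master_seed=7,
    outdir="example_out",
)
report = run_pipeline(cfg)

t = report["null_model_paired_t"]["alpha-T:early"]
print("alpha-T early: exp-vs-random mean diff = %.3f, t(%d) = %.2f, p = %.4f"
      % (t["mean_diff"], t["df"], t["t"], t["p"]))
w = report["outer_ring_wilcoxon"]["T:early"]
print("outer ring (T): median K_avg difference = %.3f, Wilcoxon p = %.4f"
      % (w["median_diff"], w["p"]))
h = report["half_islet_regressions"]["alpha-vs-T:vertical"]
print("half-islet polarity: slope = %.3f, R2 = %.3f, p = %.6f"
      % (h["slope"], h["r2"], h["p"]))
```

Output:

```
alpha-T early: exp-vs-random mean diff = 0.075, t(39) = 3.74, p = 0.0006
outer ring (T): median K_avg difference = 0.120, Wilcoxon p = 0.0005
half-islet polarity: slope = 0.655, R2 = 0.168, p = 0.009555
```

Read: experimental α–T networks carry ~0.08 more links per α-cell than
their randomized counterparts (paired t across 40 islets, p < 10⁻³);
α-linked β-cells in the outer ring out-link non-α-linked β-cells to
T-cells; and islet halves richer in α-cells hold proportionally more
T-cells.  Re-running with `alpha_attraction=0.0` makes all three signals
vanish, which is the package's type-I calibration.

A `simulate`d cohort is plain CSV (cells + WKT rim polygons), so the same
pipeline runs unchanged on real segmented data via
`PipelineConfig(cells_path=..., rims_path=...)` or the CLI:

```bash
isletnet simulate --seed 1 --outdir data/
isletnet all --seed 1 --outdir results/
isletnet coloc ch1.tif ch2.tif --out coloc.json
```

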