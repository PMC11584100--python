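# Methods

This package quantifies two spatial biomarkers from digital-image-analysis
(DIA) output of breast-cancer immunohistochemistry slides — the intratumoral
heterogeneity (ITH) of Ki67 positivity and the CD8+ immunogradient across the
tumor–stroma interface — and carries them into survival modeling. Because no
patient-level data are distributed, every stage is exercised on synthetic
slides and cohorts with known ground truth.

## Hexagonal subsampling

Both biomarker families rest on a randomized hexagonal tessellation of the
slide. We use pointy-top hexagons with axial (q, r) coordinates; the origin
offset is drawn uniformly over one lattice period from an explicit seed, so
repeated analyses probe different grid phases. A point is assigned to exactly
one hexagon by fractional axial conversion followed by cube rounding, which
partitions the plane deterministically (no boundary double-counting); raster
pixels are assigned by the same rule applied to their centers (a fused
numba kernel, since whole-slide rasters run to tens of megapixels).

Grid scales. The Ki67 grid uses hexagons of side 262.5 μm and the CD8 grid
hexagons of side 65 μm. The source method states these as pixel "side
lengths" of 1050 px and "diameter" 260 px at 0.5 μm/px; the two statements
are mutually consistent only if both pixel figures are circumcircle
*diameters* (2 × side). We adopt that reading — side 525 px = 262.5 μm and
side 130 px = 65 μm — and flag the ambiguity here rather than silently
choosing. The physical hexagon area is (3√3/2)·s² (≈ 0.0110 mm² for the CD8
grid), and all densities are consistent with it.

Per-hexagon aggregates are cell counts by marker/positivity and tissue-class
area fractions (tumor/stroma/background) by pixel counting; no sub-pixel
polygon clipping is attempted, so fraction tests carry a pixelation tolerance
(±0.02 on a boundary-straddling hexagon).

## Ki67 heterogeneity (co-occurrence entropy)

Hexagons with fewer than 50 tumor cells are discarded as insufficiently
sampled. Per-hexagon Ki67 positivity percent is discretized into 10 ranks —
interval 1 is [0, 10] %, interval k ≥ 2 is (10(k−1), 10k] % — and a 10×10
co-occurrence matrix is accumulated over all unordered pairs of included
hexagons at hexagonal distance 1 (the 6-neighbor adjacency; the distance is a
config knob), symmetrized and normalized. Haralick indicators follow:
entropy −Σ p ln p (natural log; the choice of base is exposed nowhere else,
so entropy is reported in nats), contrast Σ(i−j)²p, dissimilarity Σ|i−j|p,
homogeneity (inverse difference moment) Σ p/(1+(i−j)²), and energy Σp².
Entropy is the headline biomarker; the others are computed and exported.
The pairing rule (distance-1, each unordered pair counted once then
symmetrized) is our fixed choice; it is oracle-tested against brute-force
pair enumeration.

## CD8 immunogradient

Tumor-edge detection operates on hexagon-level tissue fractions: a hexagon is
flagged when, along at least one of the three lattice axes, the tumor-area
fraction of its two opposite neighbors differs by more than τ (default 0.5;
the source describes the concept but no threshold). Flagged transitions whose
low-tumor side is background-like are discarded (section borders are not a
tumor–stroma interface). Of a sharp transition's two sides only the
tumor-dominant one is kept as edge, which keeps the central edge one rank
wide as in the reference visualization; the stroma-side partner becomes
rank −1.

Ranks: |rank| is the BFS distance over the 6-neighbor adjacency to the
nearest edge hexagon (rank 0), signed by the hexagon's dominant tissue class
(tumor +, stroma −; argmax of area fractions). Background-dominant hexagons
(background fraction > 0.5) and hexagons unreachable from the edge are
excluded. With several disjoint tumor nests, ranks are measured against the
union of all edge hexagons. The interface zone (IZ) keeps ranks −4…+4 —
nine rank classes around a one-rank-wide edge.

Densities are CD8+ count per mm² of *analyzed tissue* (tumor+stroma area of
the hexagon), so background-heavy hexagons at section borders are not
artificially diluted — an interpretation we document rather than inherit.
Eight indicators summarize the profile: mean/SD of per-hexagon density in
the stroma aspect (ranks −4…−1), edge (0) and tumor aspect (1…4); the
Immunodrop ID = mean density at rank −1 / mean density at rank +1 (zero
denominator with positive numerator reports a configurable cap, default 100,
with a flag; 0/0 reports 1 with a flag); and the center of mass
CM = Σ r·D̄(r) / Σ D̄(r) over per-rank *mean* densities including rank 0,
with empty rank classes omitted from both sums. The one-sentence upstream
definition of CM does not fix whether per-rank totals or means are weighted;
we weight means (hexagon-count invariance) and isolate the choice in a
single function.

## Synthetic data

The generator produces the three inputs the pipeline needs, with the
statistical structure the indicators are designed to detect. All generators
are pure functions of (scenario, seed).

* **Tissue maps** — half-plane, disk, or blob-union tumor geometries in a
  stroma canvas with a background margin; 0.5 μm/px by default.
* **Cells** — homogeneous Poisson tumor cells on tumor pixels (default
  2000/mm²); CD8 cells as an inhomogeneous Poisson process via thinning:
  intensity λ_S on stroma (default 300/mm², matching reported cohort-scale
  stromal densities) and λ_S/κ·exp(−depth/decay) on tumor, where depth is
  Euclidean distance to the tumor boundary (KD-tree over boundary-pixel
  centers, equivalent to a distance transform at the sample points). κ ≥ 1
  is the ground-truth drop factor the Immunodrop should recover. The default
  decay length is 2000 μm — the *shallow-decay* regime (decay ≫ IZ width ≈
  1 mm) in which the rank ±1 density ratio identifies κ itself; short decay
  lengths deliberately confound κ with decay, and indicator values then
  reflect both.
* **Ki67 patchiness** — a Voronoi mosaic of patches (Poisson seeds, mean
  patch area π(d/2)², default diameter 500 μm ≈ one Ki67 hexagon) whose
  per-patch positivity probability is Beta-distributed with mean equal to
  the global base rate and standard deviation equal to the patchiness knob.
  The mosaic preserves the expected global positivity while adding spatial
  contrast, which is the structure the co-occurrence entropy responds to.
  It is a stand-in for real proliferation hotspots, not a fitted model: real
  Ki67 fields have autocorrelation and anisotropy the mosaic lacks, so a
  passing monotonicity test shows the estimator responds to spatial
  contrast, not that it is calibrated on tissue.
* **Cohorts** — exponential proportional-hazards event times with per-SD
  log-hazard coefficients (defaults: node positivity +0.95, Ki67 entropy
  +0.70, intratumoral CD8 density −0.70, Immunodrop +0.60 — directions and
  rough magnitudes mirroring the reported prognostic tables), covariate
  marginals moment-matched to the reported ER+HER2− indicator summaries,
  administrative censoring at 120 months, and a baseline rate calibrated by
  root-finding so the expected event fraction is 13% (the reported 33/252).

## Survival layer

Continuous indicators are dichotomized at the cutoff minimizing the log-rank
p over all midpoints between consecutive distinct values whose split leaves
at least 10% of the cohort on each side (ties: larger χ², then lower
cutoff). The log-rank statistic is a vectorized in-repo Mantel–Haenszel
implementation, cross-checked against lifelines. **No multiple-testing
correction is applied across candidate cutoffs or indicators** — mirroring
common optimal-cutpoint practice — so the univariate screen's type-I error
is badly inflated (a null covariate is retained far more often than 5%); the
test suite asserts this inflation rather than hiding it, and downstream
hazard ratios for optimally-dichotomized variables are optimistic.

Indicators passing the screen (p < 0.05) enter a multivariable Cox
proportional-hazards model (lifelines, Efron tie handling), reported with
per-covariate HR/CI/Wald χ², the likelihood-ratio statistic, and Harrell's C
computed in-repo on the fitted linear predictor (ties in risk count ½;
event/event ties in time are not comparable). Componentwise-boosting model
selection and cross-validated train/test evaluation are out of scope; a
seeded random split utility is provided.

The combined prognostic score (CPBS) sums oriented binary indicators
(1 = poor prognosis: node-positive; entropy above cutoff; CD8 density below
cutoff; Immunodrop above cutoff; pT2). ER+HER2− model: 4 indicators, risk
groups 0 / 1 / 2–4 → low / intermediate / high. TNBC model: 3 indicators,
groups 0–1 / 2 / 3. The TNBC grouping follows the results-text convention;
the alternative figure-caption convention (0 / 1 / 2) conflicts with it and
is not implemented.

Slide-level QC excludes slides with less than 6 mm² of tumor by pixel area
before any indicator computation.

## Validation problem sizes and numerical choices

The validation experiments are sized to run in minutes on one CPU:
κ-recovery and grid-stability slides are 1.2 × 3.6 mm half-planes (≈ 32 CD8
hexagons per IZ rank class; 20 seeds per condition), entropy-vs-patchiness
uses 2.9-mm-radius tumor disks (≈ 35 Ki67 hexagons; 20 seeds per level), and
Cox recovery uses 100 cohorts of n = 250. Degenerate inputs fail loudly:
no hexagon passing the 50-cell filter, no adjacent hexagon pair, no
tumor–stroma transition, all-censored cohorts and infeasible cutoff
constraints each raise a specific error rather than returning silent NaNs.
Known limitations: single-slide indicator estimates on small (≈ 1 mm²)
synthetic slides are dominated by counting noise (the demo panel in
`analysis/` shows this); the mosaic and half-plane geometries are idealized;
and optimal-cutoff p-values are anti-conservative by construction.
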