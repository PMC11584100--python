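# immunohex

Spatial analysis of breast-cancer immunohistochemistry (IHC) slides on a
hexagonal grid: **Ki67 intratumoral heterogeneity** measured as co-occurrence
(Haralick) entropy, and the **CD8+ immunogradient** — density profile
indicators across an automatically extracted tumor–stroma interface zone —
followed by optimal-cutoff survival stratification, multivariable Cox
modeling, and a combined prognostic score for breast-cancer-specific
survival (BCSS).

It is written for computational-pathology researchers who have per-slide DIA
output (a cell coordinate table and a tumor/stroma/background label raster)
and a clinical follow-up table, and for anyone who wants to study the
statistical behavior of these indicators on synthetic tissue, which the
package generates with controllable ground truth.

## The indicators

A randomized hexagonal grid (side 262.5 μm for Ki67, 65 μm for CD8 at
0.5 μm/px) subsamples each slide.

* **Ki67 entropy.** Per-hexagon Ki67 positivity (hexagons with < 50 cells
  excluded) is ranked into 10 intervals (0–10 %, >10–20 %, …); a normalized
  co-occurrence matrix P over adjacent hexagon pairs yields
  `entropy = −Σᵢⱼ pᵢⱼ ln pᵢⱼ`, plus homogeneity, contrast, dissimilarity and
  energy. High entropy = spatially heterogeneous proliferation.
* **CD8 immunogradient.** Hexagons with abrupt tumor-fraction changes along
  the lattice axes (tumor–stroma transitions only) form the tumor edge
  (rank 0); other hexagons get signed ranks by hexagonal distance (tumor
  side +, stroma side −), and the interface zone keeps ranks −4…+4. From
  per-hexagon CD8+ densities (cells/mm² of analyzed tissue):
  `CD8_m_S, CD8_sd_S` (stroma aspect), `CD8_m_TE, CD8_sd_TE` (edge),
  `CD8_m_T, CD8_sd_T` (tumor aspect), the Immunodrop
  `CD8_ID = D̄(−1)/D̄(+1)` and the center of mass
  `CD8_CM = Σ r·D̄(r) / Σ D̄(r)`. Stroma-trapped infiltrates give high ID
  and negative CM.
* **Survival layer.** Indicators are dichotomized at the log-rank-optimal
  cutoff (both groups ≥ 10% of the cohort), screened univariately
  (p < 0.05), and fitted in a multivariable Cox model (Efron ties) with
  Harrell's C. The combined prognostic score (CPBS) sums binary
  poor-prognosis indicators: ER+HER2− model (pN, Ki67 entropy, CD8_m_T,
  CD8_ID) → risk groups 0 / 1 / 2–4; TNBC model (pT, Ki67 entropy, CD8_m_S)
  → 0–1 / 2 / 3.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Generate a panel of synthetic slides (half-plane tumor, CD8 drop factor
κ ∈ {1, 2, 4} crossed with uniform vs. patchy Ki67), extract indicators, and
run the cohort analysis:

```sh
python analysis/01_simulate_slides.py
python analysis/02_extract_indicators.py
python analysis/03_survival_models.py
```

`02_extract_indicators.py` prints one row per slide
(`results/slide_indicators.csv`), e.g.:

```
     slide_id  ki67_entropy    CD8_m_S    CD8_m_T    CD8_CM   CD8_ID
s1_k1_uniform      1.631345 247.901096 265.739753  0.087957 0.775234
s3_k2_uniform      1.271370 313.567337 155.389863 -0.728028 1.995018
s5_k4_uniform      1.263654 279.750734  54.700680 -1.515622 5.489666
```

Reading the numbers: with no gradient (κ=1) the CD8 density is flat across
the interface (ID ≈ 0.8, CM ≈ 0); as κ grows, tumor-aspect density
`CD8_m_T` collapses (266 → 54 cells/mm²), the Immunodrop rises and the
center of mass moves to the stroma side — single small slides are noisy
(these are 1.2 × 1.2 mm), which is why validation averages over seeds.

`03_survival_models.py` simulates an ER+HER2−-like cohort (n = 250, 40
BCSS events within 120 months) and prints the screen, the Cox model and the
CPBS stratification:

```
retained (p < 0.05): ['Ki67_entropy', 'CD8_m_T', 'CD8_ID']
LR = 27.35 (p = 4.96e-06), Harrell's C = 0.7111
CPBS risk groups: {'high': 208, 'intermediate': 39, 'low': 3}
10-year survival, low-risk: 100.0%  intermediate: 94.9%  high: 81.7%
```

The same pipeline is scriptable per slide and per cohort through the CLI:

```sh
immunohex simulate --scenario scenario.yaml --seed 5 --out sim/
immunohex slide --cells-ki67 sim/cells_ki67.csv --cells-cd8 sim/cells_cd8.csv \
    --tissue sim/tissue.png --config cfg.yaml --out out/
immunohex cohort --indicators indicators.csv --clinical clinical.csv --out out/
```

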