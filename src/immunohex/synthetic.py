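"""Synthetic tissue, cell and cohort generators.

The analysis operates on three inputs that, for real slides, come from
digital image analysis of immunohistochemistry whole-slide images: a tissue
label raster (tumor / stroma / background), a per-cell coordinate table, and
a clinical follow-up table.  This module generates all three with the
statistical structure the downstream indicators are designed to detect:

* tumor nests embedded in stroma (half-plane, disk, or blob-union geometry);
* tumor cells with spatially patchy Ki67 positivity — a Voronoi mosaic of
  per-patch positivity probabilities whose spread is the heterogeneity knob
  the co-occurrence entropy should respond to;
* CD8+ cells as an inhomogeneous Poisson process with stromal intensity
  ``λ_S`` and intratumoral intensity ``λ_S/κ · exp(−depth/decay)``, so the
  drop factor ``κ ≥ 1`` is the ground truth the Immunodrop indicator should
  recover;
* survival cohorts drawn from a proportional-hazards model with known
  log-hazard coefficients and administrative censoring.

All generators are pure functions of (scenario, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree

BACKGROUND, STROMA, TUMOR = 0, 1, 2

__all__ = [
    "BACKGROUND", "STROMA", "TUMOR",
    "TissueMap", "HalfPlane", "Disk", "BlobUnion",
    "TissueScenario", "CellScenario", "CohortScenario",
    "generate_tissue_map", "generate_cells", "generate_cohort",
    "default_cohort_scenario", "train_test_split_cohort",
]


@dataclass
class TissueMap:
    """Label raster over {background, stroma, tumor} with physical resolution."""

    labels: np.ndarray  # (H, W) uint8
    resolution_um_per_px: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def area_mm2(self, label: int) -> float:
        px = (self.resolution_um_per_px / 1000.0) ** 2
        return float(np.count_nonzero(self.labels == label)) * px

    @property
    def tumor_area_mm2(self) -> float:
        return self.area_mm2(TUMOR)


# -- geometries -------------------------------------------------------------

@dataclass(frozen=True)
class HalfPlane:
    """Tumor occupies x ≥ boundary_x_px (within the tissue region)."""
    boundary_x_px: float

@dataclass(frozen=True)
class Disk:
    center_px: tuple[float, float]
    radius_px: float

@dataclass(frozen=True)
class BlobUnion:
    """Union of k random disks (tumor nests); centers/radii drawn from seed."""
    n_blobs: int
    radius_min_px: float
    radius_max_px: float


@dataclass(frozen=True)
class TissueScenario:
    width_px: int
    height_px: int
    geometry: HalfPlane | Disk | BlobUnion
    resolution_um_per_px: float = 0.5
    margin_px: int = 0  # background border width
    seed: int = 0


def generate_tissue_map(scenario: TissueScenario) -> TissueMap:
    """Rasterize a tissue scenario into a label map.

    Pixels outside the background margin are stroma, overwritten with tumor
    where the geometry applies.  Deterministic for fixed scenario (the seed
    only matters for ``BlobUnion``).
    """
    w, h, m = scenario.width_px, scenario.height_px, scenario.margin_px
    if w <= 0 or h <= 0:
        raise ValueError("canvas must be non-degenerate")
    if m < 0 or 2 * m >= min(w, h):
        raise ValueError("background margin leaves no tissue")
    labels = np.full((h, w), BACKGROUND, dtype=np.uint8)
    labels[m:h - m, m:w - m] = STROMA

    xx = np.arange(w, dtype=float) + 0.5
    yy = np.arange(h, dtype=float) + 0.5
    geom = scenario.geometry
    if isinstance(geom, HalfPlane):
        if not (m < geom.boundary_x_px < w - m):
            raise ValueError("half-plane boundary outside the tissue region")
        tumor = xx[None, :] >= geom.boundary_x_px
    elif isinstance(geom, Disk):
        cx, cy = geom.center_px
        rad = geom.radius_px
        if rad <= 0:
            raise ValueError("disk radius must be positive")
        if (cx - rad < m or cx + rad > w - m or cy - rad < m or cy + rad > h - m):
            raise ValueError("disk does not fit inside the canvas tissue region")
        tumor = ((xx[None, :] - cx) ** 2 + (yy[:, None] - cy) ** 2) <= rad ** 2
    elif isinstance(geom, BlobUnion):
        if geom.n_blobs < 1:
            raise ValueError("blob union needs at least one blob")
        rng = np.random.default_rng(scenario.seed)
        tumor = np.zeros((h, w), dtype=bool)
        for _ in range(geom.n_blobs):
            rad = rng.uniform(geom.radius_min_px, geom.radius_max_px)
            if 2 * rad >= min(w, h) - 2 * m:
                raise ValueError("blob radius exceeds canvas tissue region")
            cx = rng.uniform(m + rad, w - m - rad)
            cy = rng.uniform(m + rad, h - m - rad)
            tumor |= ((xx[None, :] - cx) ** 2 + (yy[:, None] - cy) ** 2) <= rad ** 2
    else:  # pragma: no cover
        raise TypeError(f"unknown geometry {type(geom)!r}")

    labels[tumor & (labels == STROMA)] = TUMOR
    return TissueMap(labels=labels, resolution_um_per_px=scenario.resolution_um_per_px)


# -- cells ------------------------------------------------------------------

@dataclass(frozen=True)
class CellScenario:
    """Parameters of the per-slide point processes.

    Intensities are in cells/mm²; lengths in μm.  ``ki67_patch_spread`` is
    the standard deviation of the per-patch positivity probability (Beta
    mosaic with mean ``ki67_base``); 0 means spatially uniform positivity.
    ``cd8_kappa`` ≥ 1 is the stroma-to-tumor CD8 intensity ratio at the
    tumor boundary and ``cd8_decay_um`` the intratumoral exponential decay
    length of CD8 intensity with depth.
    """

    tumor_density: float = 2000.0
    ki67_base: float = 0.16
    ki67_patch_diameter_um: float = 500.0
    ki67_patch_spread: float = 0.0
    cd8_stroma_density: float = 300.0
    cd8_kappa: float = 3.0
    cd8_decay_um: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tumor_density, self.cd8_stroma_density) < 0:
            raise ValueError("cell intensities must be nonnegative")
        if not 0.0 <= self.ki67_base <= 1.0:
            raise ValueError("ki67_base must be a fraction in [0, 1]")
        if self.cd8_kappa < 1.0:
            raise ValueError("cd8_kappa must be ≥ 1 (stromal density dominates)")
        if self.ki67_patch_spread < 0:
            raise ValueError("ki67_patch_spread must be ≥ 0")
        mx = self.ki67_base * (1.0 - self.ki67_base)
        if self.ki67_patch_spread > 0 and self.ki67_patch_spread ** 2 >= mx:
            raise ValueError(
                f"ki67_patch_spread² must be < base·(1−base) = {mx:.4f}")


def _sample_points_in_mask(mask: np.ndarray, n: int, rng: np.random.Generator):
    """Uniform points inside True pixels (pixel choice + sub-pixel jitter)."""
    idx = np.flatnonzero(mask.ravel())
    if len(idx) == 0 or n == 0:
        return np.empty(0), np.empty(0)
    pick = rng.choice(idx, size=n, replace=True)
    h, w = mask.shape
    iy, ix = np.divmod(pick, w)
    x = ix + rng.random(n)
    y = iy + rng.random(n)
    return x, y


def generate_cells(tissue: TissueMap, scenario: CellScenario) -> pd.DataFrame:
    """Sample the tumor-cell and CD8 point processes on a tissue map.

    Tumor cells (marker ``tumor_ki67``) form a homogeneous Poisson process
    on tumor pixels; each carries a Ki67 positivity flag drawn from its
    patch's probability.  CD8 cells (marker ``cd8``, positive = 1) form an
    inhomogeneous Poisson process with intensity ``λ_S`` on stroma and
    ``λ_S/κ · exp(−depth/decay)`` on tumor, sampled by thinning a
    homogeneous process at rate ``λ_S``.

    Returns the cell table ``cell_id, x_px, y_px, marker, positive``.
    """
    rng = np.random.default_rng(scenario.seed)
    res = tissue.resolution_um_per_px
    px_area_mm2 = (res / 1000.0) ** 2
    tumor_mask = tissue.labels == TUMOR
    tissue_mask = tissue.labels != BACKGROUND

    frames = []

    # tumor cells with patchy Ki67 positivity
    tumor_area = np.count_nonzero(tumor_mask) * px_area_mm2
    n_tumor = rng.poisson(scenario.tumor_density * tumor_area)
    if n_tumor > 0:
        x, y = _sample_points_in_mask(tumor_mask, n_tumor, rng)
        if scenario.ki67_patch_spread == 0:
            p_cell = np.full(n_tumor, scenario.ki67_base)
        else:
            p_cell = _patch_probabilities(x, y, tissue, scenario, rng)
        pos = rng.random(n_tumor) < p_cell
        frames.append(pd.DataFrame({
            "x_px": x, "y_px": y,
            "marker": "tumor_ki67", "positive": pos.astype(int)}))

    # CD8 cells by thinning
    lam = scenario.cd8_stroma_density
    if lam > 0:
        area = np.count_nonzero(tissue_mask) * px_area_mm2
        n_prop = rng.poisson(lam * area)
        if n_prop > 0:
            x, y = _sample_points_in_mask(tissue_mask, n_prop, rng)
            in_tumor = tumor_mask[
                np.clip(y.astype(int), 0, tissue.shape[0] - 1),
                np.clip(x.astype(int), 0, tissue.shape[1] - 1)]
            keep_p = np.ones(n_prop)
            if in_tumor.any():
                d_um = _depth_to_boundary_um(
                    tumor_mask, x[in_tumor], y[in_tumor], res)
                keep_p[in_tumor] = (np.exp(-d_um / scenario.cd8_decay_um)
                                    / scenario.cd8_kappa)
            keep = rng.random(n_prop) < keep_p
            frames.append(pd.DataFrame({
                "x_px": x[keep], "y_px": y[keep],
                "marker": "cd8", "positive": 1}))

    if frames:
        cells = pd.concat(frames, ignore_index=True)
    else:
        cells = pd.DataFrame(columns=["x_px", "y_px", "marker", "positive"])
    cells.insert(0, "cell_id", np.arange(len(cells)))
    return cells


def _depth_to_boundary_um(tumor_mask: np.ndarray, x, y, res: float) -> np.ndarray:
    """Euclidean distance (μm) from points inside the tumor to the tumor
    boundary (tumor pixels adjacent to non-tumor), via a KD-tree on the
    boundary pixel centers."""
    interior = ndimage.binary_erosion(tumor_mask, border_value=0)
    by, bx = np.nonzero(tumor_mask & ~interior)
    if len(bx) == 0:
        return np.zeros(len(np.atleast_1d(x)))
    tree = cKDTree(np.column_stack([bx + 0.5, by + 0.5]))
    d, _ = tree.query(np.column_stack([x, y]), k=1)
    return d * res


def _patch_probabilities(x, y, tissue, scenario, rng):
    """Voronoi patch mosaic of Ki67 positivity probabilities.

    Patch seeds form a Poisson process with mean patch area π(d/2)²; each
    patch draws its positivity probability from a Beta distribution with
    mean ``ki67_base`` and sd ``ki67_patch_spread`` (mean positivity is thus
    preserved while spatial contrast grows with the spread).
    """
    res = tissue.resolution_um_per_px
    h, w = tissue.shape
    area_mm2 = h * w * (res / 1000.0) ** 2
    patch_area_mm2 = np.pi * (scenario.ki67_patch_diameter_um / 2000.0) ** 2
    n_patches = max(1, rng.poisson(area_mm2 / patch_area_mm2))
    seeds = np.column_stack([rng.uniform(0, w, n_patches),
                             rng.uniform(0, h, n_patches)])
    mu, sd = scenario.ki67_base, scenario.ki67_patch_spread
    nu = mu * (1 - mu) / sd ** 2 - 1.0  # Beta precision from mean/sd
    p_patch = rng.beta(mu * nu, (1 - mu) * nu, size=n_patches)
    _, nearest = cKDTree(seeds).query(np.column_stack([x, y]), k=1)
    return p_patch[nearest]


# -- cohorts ----------------------------------------------------------------

@dataclass(frozen=True)
class CohortScenario:
    """Proportional-hazards cohort simulator.

    ``covariates`` maps a name to a marginal distribution spec:
    ``("normal", mean, sd)``, ``("lognormal", mean_log, sd_log)`` or
    ``("bernoulli", p)``.  ``log_hr_per_sd`` are log-hazard ratios applied to
    the standardized covariate (binary covariates enter as-is, so their
    coefficient is per category).  Event times are exponential with rate
    ``baseline_rate · exp(η)``; if ``baseline_rate`` is None it is calibrated
    so the expected event fraction under administrative censoring equals
    ``target_event_fraction``.
    """

    n: int = 250
    covariates: dict = field(default_factory=dict)
    log_hr_per_sd: dict = field(default_factory=dict)
    baseline_rate: float | None = None
    censoring_months: float = 120.0
    target_event_fraction: float = 0.13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be ≥ 1")
        if not self.censoring_months > 0:
            raise ValueError("censoring time must be positive")
        unknown = set(self.log_hr_per_sd) - set(self.covariates)
        if unknown:
            raise ValueError(f"coefficients for unknown covariates: {sorted(unknown)}")
        for name, beta in self.log_hr_per_sd.items():
            if not np.isfinite(beta):
                raise ValueError(f"non-finite coefficient for {name!r}")

    def true_log_hr_per_unit(self) -> dict:
        """Per-raw-unit log-hazard ratios implied by the per-SD coefficients."""
        out = {}
        for name, beta in self.log_hr_per_sd.items():
            _, sd = _dist_moments(self.covariates[name])
            kind = self.covariates[name][0]
            out[name] = beta if kind == "bernoulli" else beta / sd
        return out


def _dist_moments(spec):
    kind = spec[0]
    if kind == "normal":
        return float(spec[1]), float(spec[2])
    if kind == "lognormal":
        m = np.exp(spec[1] + spec[2] ** 2 / 2.0)
        sd = m * np.sqrt(np.exp(spec[2] ** 2) - 1.0)
        return float(m), float(sd)
    if kind == "bernoulli":
        p = float(spec[1])
        return p, float(np.sqrt(p * (1 - p)))
    raise ValueError(f"unknown distribution kind {kind!r}")


def _draw_covariate(spec, n, rng):
    kind = spec[0]
    if kind == "normal":
        return rng.normal(spec[1], spec[2], n)
    if kind == "lognormal":
        return rng.lognormal(spec[1], spec[2], n)
    if kind == "bernoulli":
        return (rng.random(n) < spec[1]).astype(float)
    raise ValueError(f"unknown distribution kind {kind!r}")


def _linear_predictor(scenario, cov: dict) -> np.ndarray:
    eta = np.zeros(len(next(iter(cov.values()))) if cov else scenario.n)
    for name, beta in scenario.log_hr_per_sd.items():
        spec = scenario.covariates[name]
        x = cov[name]
        if spec[0] == "bernoulli":
            eta = eta + beta * x
        else:
            m, sd = _dist_moments(spec)
            eta = eta + beta * (x - m) / sd
    return eta


def _calibrate_baseline_rate(scenario: CohortScenario) -> float:
    """Rate such that E[P(event before censoring)] hits the target fraction."""
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 0x5EED]))
    n_mc = 20000
    cov = {name: _draw_covariate(spec, n_mc, rng)
           for name, spec in scenario.covariates.items()}
    eta = _linear_predictor(scenario, cov)
    c = scenario.censoring_months
    target = scenario.target_event_fraction

    def event_frac(log_rate):
        return np.mean(1.0 - np.exp(-np.exp(log_rate) * np.exp(eta) * c)) - target

    sol = optimize.brentq(event_frac, np.log(1e-8), np.log(10.0))
    return float(np.exp(sol))


def generate_cohort(scenario: CohortScenario) -> pd.DataFrame:
    """Simulate one cohort; returns covariates plus ``time_months, event``."""
    rate = (scenario.baseline_rate if scenario.baseline_rate is not None
            else _calibrate_baseline_rate(scenario))
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n
    cov = {name: _draw_covariate(spec, n, rng)
           for name, spec in scenario.covariates.items()}
    eta = _linear_predictor(scenario, cov)
    t_event = rng.exponential(1.0, n) / (rate * np.exp(eta))
    event = t_event <= scenario.censoring_months
    time = np.minimum(t_event, scenario.censoring_months)
    out = pd.DataFrame({"patient_id": np.arange(n)})
    for name, x in cov.items():
        out[name] = x
    out["time_months"] = time
    out["event"] = event.astype(int)
    return out


def default_cohort_scenario(n: int = 250, seed: int = 0) -> CohortScenario:
    """Cohort emulating an ER+HER2− breast-cancer study population.

    Covariate marginals are moment-matched to typical DIA indicator summaries
    (entropy ≈ 2.2 ± 1.4; interface-zone tumor-aspect CD8 density and
    Immunodrop right-skewed, hence lognormal); node positivity ~41%; event
    fraction 13% under 120-month administrative censoring.  Effect directions:
    node positivity, entropy and Immunodrop increase hazard; intratumoral CD8
    density decreases it.
    """
    return CohortScenario(
        n=n,
        covariates={
            "pN_positive": ("bernoulli", 0.413),
            "Ki67_entropy": ("normal", 2.22, 1.40),
            "CD8_m_T": ("lognormal", 4.110, 1.221),
            "CD8_ID": ("lognormal", 1.010, 0.911),
        },
        log_hr_per_sd={
            "pN_positive": 0.95,
            "Ki67_entropy": 0.70,
            "CD8_m_T": -0.70,
            "CD8_ID": 0.60,
        },
        censoring_months=120.0,
        target_event_fraction=0.13,
        seed=seed,
    )


def train_test_split_cohort(cohort: pd.DataFrame, test_fraction: float = 0.25,
                            seed: int = 0):
    """Seeded random train/test split (returns two row subsets)."""
    rng = np.random.default_rng(seed)
    n = len(cohort)
    n_test = int(round(test_fraction * n))
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return cohort.iloc[train_idx].reset_index(drop=True), \
        cohort.iloc[test_idx].reset_index(drop=True)
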