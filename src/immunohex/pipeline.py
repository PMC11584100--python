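"""Per-slide and per-cohort orchestration with QC.

``run_slide`` composes the grid, Ki67-heterogeneity and CD8-immunogradient
stages into one indicator record per slide; ``run_cohort`` joins indicator
and clinical tables, screens univariately, fits multivariable Cox models and
derives the combined prognostic score.  Every report embeds the analysis
configuration so results are reproducible from (inputs, config, seeds).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from lifelines import KaplanMeierFitter

from . import __version__
from . import hexgrid, immunogradient, ki67, survival
from .synthetic import TUMOR, TissueMap

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of the per-slide and per-cohort analysis.

    Lengths in μm, areas in mm².  Defaults reproduce the reference setting:
    0.5 μm/px 20× scans, Ki67 hexagons of side 262.5 μm, CD8 hexagons of
    side 65 μm, 50-cell Ki67 hexagon filter, τ = 0.5 edge threshold, a
    9-rank interface zone (half-width 4), and a 6 mm² minimum tumor area.
    """

    resolution_um_per_px: float = 0.5
    ki67_hex_side_um: float = 262.5
    cd8_hex_side_um: float = 65.0
    min_cells_per_hexagon: int = 50
    cooccurrence_distance: int = 1
    edge_tau: float = 0.5
    iz_half_width: int = 4
    min_tumor_area_mm2: float = 6.0
    min_group_fraction: float = 0.1
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("resolution_um_per_px", "ki67_hex_side_um",
                     "cd8_hex_side_um", "min_tumor_area_mm2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def ki67_grid(self, seed: int | None = None) -> hexgrid.GridConfig:
        return hexgrid.GridConfig(
            side_px=self.ki67_hex_side_um / self.resolution_um_per_px,
            resolution_um_per_px=self.resolution_um_per_px,
            seed=self.seed if seed is None else seed)

    def cd8_grid(self, seed: int | None = None) -> hexgrid.GridConfig:
        return hexgrid.GridConfig(
            side_px=self.cd8_hex_side_um / self.resolution_um_per_px,
            resolution_um_per_px=self.resolution_um_per_px,
            seed=self.seed if seed is None else seed)

    def edge_config(self) -> immunogradient.EdgeDetectionConfig:
        return immunogradient.EdgeDetectionConfig(
            tau=self.edge_tau, iz_half_width=self.iz_half_width)


def qc_slide(tissue: TissueMap, config: AnalysisConfig) -> tuple[bool, float]:
    """Tumor-content QC: fail slides with tumor area below the threshold."""
    if tissue.resolution_um_per_px is None or not tissue.resolution_um_per_px > 0:
        raise ValueError("tissue map resolution missing")
    area = tissue.tumor_area_mm2
    return area >= config.min_tumor_area_mm2, area


def run_slide(cells_ki67: pd.DataFrame, cells_cd8: pd.DataFrame,
              tissue: TissueMap, config: AnalysisConfig,
              slide_id: str = "slide",
              export_dir: str | Path | None = None) -> dict:
    """Compute one slide's full indicator set.

    Stages: QC → Ki67 grid + positivity + co-occurrence texture → CD8 grid +
    tissue fractions + tumor edge + interface zone + gradient indicators.
    Raises with the stage name attached if a stage fails.  When
    ``export_dir`` is given, intermediate per-hexagon aggregates and the
    interface zone are written there as CSV.
    """
    t0 = time.perf_counter()
    passed, tumor_area = qc_slide(tissue, config)
    report: dict = {
        "slide_id": slide_id,
        "qc": {"passed": bool(passed), "tumor_area_mm2": tumor_area},
        "config": config.to_dict(),
        "version": __version__,
    }
    if not passed:
        raise ValueError(
            f"[{slide_id}/qc] tumor content {tumor_area:.2f} mm² below "
            f"{config.min_tumor_area_mm2} mm² threshold")
    h, w = tissue.shape
    bounds = (0.0, 0.0, float(w), float(h))

    export_dir = Path(export_dir) if export_dir is not None else None
    if export_dir is not None:
        export_dir.mkdir(parents=True, exist_ok=True)

    try:  # Ki67 branch
        grid_k = hexgrid.make_grid(bounds, config.ki67_grid())
        counts_k = hexgrid.assign_cells(
            cells_ki67[cells_ki67["marker"] == "tumor_ki67"], grid_k)
        report.update(ki67.ki67_indicators(
            counts_k, min_cells=config.min_cells_per_hexagon,
            distance=config.cooccurrence_distance))
        if export_dir is not None:
            hexgrid.hex_aggregate_table(grid_k, counts_k).to_csv(
                export_dir / f"{slide_id}.ki67_hexagons.csv", index=False)
    except ValueError as exc:
        raise ValueError(f"[{slide_id}/ki67] {exc}") from exc

    try:  # CD8 branch
        grid_c = hexgrid.make_grid(bounds, config.cd8_grid(seed=config.seed + 1))
        fracs = hexgrid.tissue_fractions(
            tissue.labels, tissue.resolution_um_per_px, grid_c)
        counts_c = hexgrid.assign_cells(
            cells_cd8[cells_cd8["marker"] == "cd8"], grid_c)
        econf = config.edge_config()
        edge = immunogradient.detect_tumor_edge(fracs, econf)
        ranks = immunogradient.assign_ranks(edge, fracs, econf)
        iz = immunogradient.extract_interface_zone(
            ranks, fracs, counts_c, half_width=config.iz_half_width)
        report.update(immunogradient.immunogradient_indicators(iz, econf))
        report["n_edge_hexagons"] = int(len(edge))
        if export_dir is not None:
            hexgrid.hex_aggregate_table(grid_c, counts_c, fracs).to_csv(
                export_dir / f"{slide_id}.cd8_hexagons.csv", index=False)
            iz.to_frame().to_csv(
                export_dir / f"{slide_id}.interface_zone.csv", index=False)
    except ValueError as exc:
        raise ValueError(f"[{slide_id}/cd8] {exc}") from exc

    report["runtime_s"] = round(time.perf_counter() - t0, 3)
    log.info("slide %s done in %.2fs (tumor %.2f mm²)",
             slide_id, report["runtime_s"], tumor_area)
    return report


#: indicator → orientation of the poor-prognosis category used by the CPBS
CPBS_VARIABLES = {
    "ER+HER2-": ["pN_positive", "Ki67_entropy", "CD8_m_T", "CD8_ID"],
    "TNBC": ["pT2", "Ki67_entropy", "CD8_m_S"],
}
#: clinical binaries are already 0 = good / 1 = poor
CPBS_CLINICAL = {"pN_positive", "pT2"}


def run_cohort(indicators: pd.DataFrame, clinical: pd.DataFrame,
               config: AnalysisConfig, model: str = "ER+HER2-",
               screen_variables: list[str] | None = None) -> dict:
    """Cohort-level modeling: screen → multivariable Cox → CPBS → KM curves.

    ``indicators`` and ``clinical`` join 1:1 on ``patient_id``; duplicated or
    unmatched ids are rejected.  Returns a JSON-serializable report.
    """
    for name, tab in (("indicators", indicators), ("clinical", clinical)):
        if "patient_id" not in tab.columns:
            raise ValueError(f"{name} table lacks patient_id")
        if tab["patient_id"].duplicated().any():
            dup = tab.loc[tab["patient_id"].duplicated(), "patient_id"].tolist()
            raise ValueError(f"duplicated patient ids in {name}: {dup[:5]}")
    unmatched = set(indicators["patient_id"]) ^ set(clinical["patient_id"])
    if unmatched:
        raise ValueError(f"unmatched patient ids: {sorted(unmatched)[:10]}")
    cohort = clinical.merge(indicators, on="patient_id", validate="1:1")
    if len(cohort) < 10:
        raise ValueError(f"cohort of {len(cohort)} patients is too small to model")

    if screen_variables is None:
        screen_variables = [c for c in cohort.columns
                            if c not in ("patient_id", "time_months", "event")]
    retained, cutoffs = survival.univariate_screen(
        cohort, screen_variables, alpha=config.alpha,
        min_group_fraction=config.min_group_fraction)

    report: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "model": model,
        "n_patients": int(len(cohort)),
        "n_events": int(cohort["event"].sum()),
        "univariate": {v: r.to_dict() for v, r in cutoffs.items()},
        "retained": retained,
    }

    # multivariable model on dichotomized retained variables
    if retained:
        dich = pd.DataFrame({"time_months": cohort["time_months"],
                             "event": cohort["event"]})
        for v in retained:
            dich[v] = survival.orient_binary(cohort[v], cutoffs[v])
        try:
            cox = survival.fit_multivariable_cox(dich, retained)
            report["multivariable"] = cox.to_dict()
        except ValueError as exc:
            report["multivariable"] = {"error": str(exc)}

    # CPBS from the subtype model's variable set (where available)
    cpbs_vars = CPBS_VARIABLES.get(model, [])
    if cpbs_vars and all(v in cohort.columns for v in cpbs_vars):
        scores = np.zeros((len(cohort), len(cpbs_vars)), dtype=int)
        usable = True
        for k, v in enumerate(cpbs_vars):
            if v in CPBS_CLINICAL:
                scores[:, k] = cohort[v].astype(int)
            elif v in cutoffs:
                scores[:, k] = survival.orient_binary(cohort[v], cutoffs[v])
            else:
                usable = False
        if usable:
            results = [survival.cpbs_score(tuple(row), model) for row in scores]
            cohort_cpbs = pd.DataFrame({
                "patient_id": cohort["patient_id"],
                "cpbs_total": [r.total for r in results],
                "risk_group": [r.risk_group for r in results],
            })
            report["cpbs"] = {
                "per_patient": cohort_cpbs.to_dict(orient="records"),
                "group_counts": cohort_cpbs["risk_group"].value_counts().to_dict(),
            }

    report["km_curves"] = _km_curves(cohort, report)
    return report


def _km_curves(cohort: pd.DataFrame, report: dict) -> dict:
    """Kaplan–Meier coordinates for each CPBS risk group (for CSV export)."""
    out = {}
    if "cpbs" not in report:
        return out
    groups = pd.DataFrame(report["cpbs"]["per_patient"]).set_index("patient_id")
    merged = cohort.set_index("patient_id").join(groups)
    for grp, sub in merged.groupby("risk_group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], sub["event"])
        sf = kmf.survival_function_
        out[str(grp)] = {
            "time_months": [float(x) for x in sf.index],
            "survival": [float(x) for x in sf.iloc[:, 0]],
        }
    return out
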