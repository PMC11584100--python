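#!/usr/bin/env python
"""Generate a demonstration panel of synthetic IHC slides.

Six half-plane slides (stroma left, tumor right) crossing the CD8 drop
factor κ ∈ {1, 2, 4} with Ki67 patchiness (spatially uniform vs. strongly
patchy at fixed global positivity).  Slides are 1.2 × 1.2 mm — a scaled-down
stand-in for a whole-slide image that still contains a full 9-rank interface
zone and a few dozen Ki67 hexagons.

Writes tissue PNGs and cell CSVs under scratch/slides/ (regenerated on
demand; large binary intermediates are kept out of results/).
"""

from pathlib import Path

import yaml

from immunohex import io as ihio
from immunohex.pipeline import AnalysisConfig
from immunohex.synthetic import (CellScenario, HalfPlane, TissueScenario,
                                 generate_cells, generate_tissue_map)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "slides"
RESULTS = Path(__file__).resolve().parent.parent / "results"

PANEL = [
    # slide_id, kappa, ki67 patch spread
    ("s1_k1_uniform", 1.0, 0.0),
    ("s2_k1_patchy", 1.0, 0.30),
    ("s3_k2_uniform", 2.0, 0.0),
    ("s4_k2_patchy", 2.0, 0.30),
    ("s5_k4_uniform", 4.0, 0.0),
    ("s6_k4_patchy", 4.0, 0.30),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    tissue = generate_tissue_map(TissueScenario(
        width_px=2400, height_px=2400, geometry=HalfPlane(1200), margin_px=10))
    for i, (slide_id, kappa, spread) in enumerate(PANEL):
        cells = generate_cells(tissue, CellScenario(
            tumor_density=3000.0, ki67_base=0.4, ki67_patch_spread=spread,
            ki67_patch_diameter_um=400.0, cd8_stroma_density=300.0,
            cd8_kappa=kappa, cd8_decay_um=2000.0, seed=1000 + i))
        d = OUT / slide_id
        d.mkdir(exist_ok=True)
        ihio.write_tissue_map(tissue, d / "tissue.png")
        ihio.write_cells(cells[cells.marker == "tumor_ki67"],
                         d / "cells_ki67.csv")
        ihio.write_cells(cells[cells.marker == "cd8"], d / "cells_cd8.csv")
        print(f"{slide_id}: κ={kappa}, spread={spread}, "
              f"{len(cells)} cells → {d}")

    # demo config: scaled-down slides, so lower the tumor-area QC threshold
    cfg = AnalysisConfig(min_tumor_area_mm2=0.5, seed=7)
    (RESULTS / "demo_config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    print(f"wrote {RESULTS / 'demo_config.yaml'}")


if __name__ == "__main__":
    main()
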