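#!/usr/bin/env python
"""Quantify gap connectedness and proximity of the two designs.

The 'open' fractal should present one interconnected gap network while
the 'closed' grid fragments its gap into 43 x 43 = 1849 isolated
chambers.  Connectivity is evaluated at 1 um/px; corridor widths (twice
the medial-axis clearance) at 2 um/px.

Writes results/gap_topology.json.
"""

import dataclasses
import json
from pathlib import Path

from fractalmea.geometry import (
    PAPER_GRID,
    PAPER_HTREE,
    build_grid,
    build_htree,
    gap_metrics,
)

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    out = {}
    for name, layout in (
        ("fractal", build_htree(PAPER_HTREE)),
        ("grid", build_grid(PAPER_GRID)),
    ):
        topo = gap_metrics(layout, resolution=1.0, compute_corridors=False)
        corridors = gap_metrics(layout, resolution=2.0, compute_corridors=True)
        out[name] = {
            "n_gap_components": topo.n_gap_components,
            "largest_gap_fraction": topo.largest_gap_fraction,
            "mean_gap_distance_um": topo.mean_gap_distance,
            "W_Si_min_measured_um": corridors.W_Si_min_measured,
            "W_Si_max_measured_um": corridors.W_Si_max_measured,
        }
        print(
            f"{name}: {topo.n_gap_components} gap component(s); largest holds "
            f"{topo.largest_gap_fraction * 100:.1f}% of the gap; mean distance to "
            f"electrode {topo.mean_gap_distance:.1f} um; corridors "
            f"{corridors.W_Si_min_measured:.0f}-{corridors.W_Si_max_measured:.0f} um"
        )
    (OUT / "gap_topology.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
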