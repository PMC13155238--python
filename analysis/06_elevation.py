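#!/usr/bin/env python
"""Effort-adjusted elevational profiles and modal elevations.

Bins records with midpoint elevations into 60 equal-width bins, fits
per-species Poisson natural-cubic-spline profiles with log country x bin
exposure offsets, and reports modal elevations with parametric-bootstrap
95% intervals and boundary flags for the best-recorded species.  The
generator's planted elevational modes are attached for comparison.
"""

import json
from pathlib import Path

from myxindic import archive
from myxindic import elevation as el

OUT = Path("results")
records = archive.read_archive(OUT / "archive_flagged.csv")
records = records.dropna(subset=["elevationMid", "species"])
truth = json.loads((OUT / "ground_truth.json").read_text())

grid = el.build_bins(records, n_bins=60)
top = records["species"].value_counts().head(25).index.tolist()
table = el.profile_table(grid, top, df=4, B=500, seed=1)
table["true_mode"] = table["species"].map(
    {sp: round(m, 0) for sp, (m, _) in truth["elevation_modes"].items()}
)
table.to_csv(OUT / "elevation_modes.csv", index=False)

ok = table[table["skipped"].isna()]
covered = ((ok["ci_lower"] <= ok["true_mode"]) & (ok["true_mode"] <= ok["ci_upper"])).mean()
print(ok[["species", "n", "mode_elevation", "ci_lower", "ci_upper",
          "boundary", "true_mode"]].round(0).to_string(index=False))
print(f"\n{len(ok)}/{len(table)} species profiled; "
      f"CI covers the planted mode for {covered:.0%} of them")
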