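#!/usr/bin/env python
"""Quality control, substrate harmonisation and aggregation.

Profiles per-field completeness, re-harmonises verbatim microhabitat
descriptors through the controlled vocabulary, derives midpoint elevations,
and aggregates the archive to the country x substrate x species count frame
with leave-one-out effort offsets — the frame every downstream stage uses.
"""

from pathlib import Path

from myxindic import archive

OUT = Path("results")
records = archive.read_archive(OUT / "archive.csv")
records = archive.harmonise_table(records)
records = archive.add_elevation_mid(records)
flagged, summary = archive.quality_flags(records)
summary.to_frame().to_csv(OUT / "completeness.csv", index=False)
flagged.to_csv(OUT / "archive_flagged.csv", index=False)

frame = archive.aggregate_counts(flagged)
frame.to_csv(OUT / "count_frame.csv", index=False)

print(f"{summary.n_records} records, {summary.n_species} species")
for f, pct in summary.missing_percent.items():
    print(f"  {f}: {summary.missing_counts[f]} missing ({pct}%)")
print(f"count frame: {len(frame)} positive cells, "
      f"{int(frame['low_exposure'].sum())} low-exposure rows, "
      f"rare substrates: {sorted(frame.loc[frame['rare_substrate'], 'substrateCategory'].unique())}")
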