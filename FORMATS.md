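# Table formats

All pipeline outputs are plain CSV with a JSON provenance stanza
(`<name>.provenance.json`: config hash, seed, row count) written next to
each file by the pipeline runner.

## Occurrence archive (`archive.csv`)

One row per occurrence record, Darwin-Core-style columns:
`country, year, species, genus, family, order, microhabitat,
substrateCategory, decimalLatitude, decimalLongitude,
minimumElevationInMeters, maximumElevationInMeters, pH`.
`microhabitat` is the verbatim descriptor; `substrateCategory` is one of
COR, LIG, RAM, FOL, BRY, HER, TER, SAX, XYL, MSC or empty.

## Count frame (`count_frame.csv`)

One row per observed country x substrate x taxon combination:
`country, substrateCategory, species, y, cell_total, exposure, log_offset,
low_exposure, rare_substrate` with y >= 1, `exposure = cell_total - y`
(leave-one-out effort) and `log_offset = log(exposure + 1)`.

## Completeness (`completeness.csv`)

`field, missing, missing_percent, range_violations` per optional field;
percentages are half-up rounded to 2 dp.

## Diversity (`diversity.csv`)

Per substrate: `records, species, singletons, goods_coverage`, rarefied
Hill numbers `q{0,1,2}_m27` with `pielou_J`, and coverage-standardised
columns `q{q}_C{target}` with `_lo`/`_hi` bootstrap bounds.

## Model outputs

* `rate_ratios.csv`: `substrateCategory, rate_ratio, ci_lower, ci_upper,
  log_ratio, se`; the reference row has ratio 1.0 and no interval.
* `emm_pairwise.csv`: `contrast ("A / B"), ratio, se_log, z, p_value,
  p_adjusted, ci_lower, ci_upper`.
* `rank_summary.csv`: `substrateCategory, median_rank, rank_25, rank_75,
  rank_2.5, rank_97.5, info_weighted_median, n_boot, n_failed`.
* `order_deviations.csv`: `order, substrateCategory, deviation, ci_lower,
  ci_upper, excludes_zero` (log scale; 0 = population contrast).

## Indicator tables

* `indicator_table.csv`: `taxon, group, A, B, stat, p_value, p_adjusted,
  ci_lower, ci_upper, held_out_A, held_out_B, n_folds_used`.
* `presence_scores_<rank>.csv`: `taxon, group, n_focal, n_total, n_sites,
  A, B, score` plus `_display` columns rounded half-up to 2 dp.
* `ph_stratum_summary.csv`: `substrateCategory, ph_band, records, species,
  singletons, coverage` (bands `<=5.00`, `5.01-7.00`, `>=7.01`).
* `ph_indval_<rank>.csv`: indicator-table columns plus `rank` and
  `label = "screening"`.

## Elevation (`elevation_modes.csv`)

`species, n, mode_elevation, ci_lower, ci_upper, boundary, n_boot_used,
n_boot_failed, skipped` (skipped holds the reason for species with too few
occupied bins).

## Validation

* `loco_folds.csv`: `fold, n_held_out, rmse, poisson_deviance` per country.
* `loco_deciles.csv`: `decile, mean_predicted, mean_observed, n`.
* `residual_diagnostics.json` / `.csv`: KS statistic and p, dispersion
  ratio and p, number of simulations.
* `sensitivity_variants.csv`: `variant (V2-V4), substrateCategory,
  delta_log_ratio, multiplicative_change` (vs the V1 baseline), optional
  `ci_lower`/`ci_upper`.
* `ph_mode_concordance.csv`: `species, n, sparse, mode_0.01, mode_0.1,
  boundary_*` flags.

## Run manifest (`manifest.json`)

Config (with hash), seed, per-stage status/timing, and every output with
its sha256 — deterministic stages reproduce identical hashes across reruns.
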