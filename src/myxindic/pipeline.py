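"""End-to-end orchestration: simulate/ingest -> harmonise -> aggregate ->
diversity -> effort model -> indicators -> elevation -> validation.

A run is driven by a single YAML config and a seed; every stage writes plain
CSV plus a JSON provenance stanza, and the run manifest lists every output
with a content hash so deterministic stages can be verified bit-for-bit
across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import archive, diversity, glmm, indicators, simulate, validation
from . import elevation as elev_mod
from .vocab import SubstrateVocabulary

log = logging.getLogger("myxindic.pipeline")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "results"
    input_path: str | None = None  # occurrence CSV; None -> simulate
    vocab_path: str | None = None
    simulate: dict = field(default_factory=dict)  # GeneratorConfig overrides
    reference: str = "LIG"
    rarity_threshold: int = 100
    m: int = 27
    coverage_target: float = 0.90
    coverage_sensitivity: float = 0.85
    k_substrate: int = 5
    k_ph: int = 3
    n_boot_diversity: int = 200
    n_boot_ranks: int = 200
    n_perm: int = 999
    n_boot_indval: int = 500
    elevation_bins: int = 60
    elevation_df: int = 4
    elevation_boot: int = 200
    loco: bool = True
    seed: int = 0
    stages: tuple[str, ...] = (
        "ingest",
        "qc",
        "aggregate",
        "diversity",
        "model",
        "indicators",
        "elevation",
        "validate",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls(**payload)
        if cfg.vocab_path and not Path(cfg.vocab_path).exists():
            raise FileNotFoundError(f"vocabulary file not found: {cfg.vocab_path}")
        if cfg.input_path and not Path(cfg.input_path).exists():
            raise FileNotFoundError(f"input archive not found: {cfg.input_path}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _Writer:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.out_dir = out_dir
        self.meta = {"config_hash": _config_hash(config), "seed": config.seed}
        self.outputs: list[dict] = []

    def write(self, name: str, df: pd.DataFrame) -> None:
        path = self.out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        prov = dict(self.meta, output=name, rows=int(len(df)))
        (self.out_dir / f"{name}.provenance.json").write_text(json.dumps(prov, indent=1))
        self.outputs.append({"name": name, "path": str(path), "sha256": _sha256(path)})


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest.

    A stage failure halts its downstream dependents but independent stages
    continue; the manifest records per-stage status and timing.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    writer = _Writer(out_dir, config)
    vocab = (
        SubstrateVocabulary.from_yaml(config.vocab_path)
        if config.vocab_path
        else SubstrateVocabulary()
    )
    status: dict[str, dict] = {}
    state: dict = {}

    def run_stage(name, deps, fn):
        if name not in config.stages and name != "ingest":
            status[name] = {"status": "skipped"}
            return
        for dep in deps:
            if status.get(dep, {}).get("status") != "ok":
                status[name] = {"status": "blocked", "blocked_on": dep}
                return
        t0 = time.time()
        try:
            fn()
            status[name] = {"status": "ok", "seconds": round(time.time() - t0, 2)}
            log.info("stage %s completed in %.2fs", name, time.time() - t0)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            status[name] = {"status": "failed", "error": str(exc)}

    def ingest():
        if config.input_path:
            state["records"] = archive.read_archive(config.input_path)
        else:
            gen = simulate.GeneratorConfig(**dict(config.simulate, seed=config.seed))
            records, truth = simulate.generate_archive(gen)
            state["records"] = records
            truth.to_json(out_dir / "ground_truth.json")
        state["records"] = archive.harmonise_table(state["records"], vocab)
        state["records"] = archive.add_elevation_mid(state["records"])

    def qc():
        flagged, summary = archive.quality_flags(state["records"])
        state["records"] = flagged
        writer.write("completeness", summary.to_frame())

    def aggregate():
        frame = archive.aggregate_counts(
            state["records"], rare_substrate_threshold=config.rarity_threshold
        )
        state["frame"] = frame
        writer.write("count_frame", frame)

    def diversity_stage():
        frame = state["frame"]
        rng = np.random.default_rng(config.seed)
        rows = []
        for sub, part in frame.groupby("substrateCategory", observed=True):
            counts = part.groupby(frame.columns[2], observed=True)["y"].sum().to_numpy()
            n = int(counts.sum())
            f1 = int((counts == 1).sum())
            row = {
                "substrateCategory": sub,
                "records": n,
                "species": int((counts > 0).sum()),
                "singletons": f1,
                "goods_coverage": diversity.goods_coverage(n, f1),
            }
            if n >= config.m:
                for q in (0, 1, 2):
                    row[f"q{q}_m{config.m}"] = diversity.rarefy_hill(counts, config.m, q)
                row["pielou_J"] = row[f"q1_m{config.m}"] / row[f"q0_m{config.m}"]
            for q in (0, 1, 2):
                est = diversity.standardise_by_coverage(
                    counts, config.coverage_target, q,
                    n_boot=config.n_boot_diversity, rng=rng,
                )
                row[f"q{q}_C{config.coverage_target}"] = est.point
                row[f"q{q}_C{config.coverage_target}_lo"] = est.lower
                row[f"q{q}_C{config.coverage_target}_hi"] = est.upper
            rows.append(row)
        writer.write("diversity", pd.DataFrame(rows))

    def model():
        spec = glmm.ModelSpec(
            reference=config.reference, rarity_threshold=config.rarity_threshold
        )
        fr = glmm.fit(state["frame"], spec)
        state["fit"] = fr
        writer.write("rate_ratios", glmm.rate_ratios(fr))
        writer.write("emm_pairwise", glmm.emm_pairwise(fr, seed=config.seed))
        try:
            ranks = glmm.bootstrap_ranks(
                fr, B=config.n_boot_ranks, seed=config.seed
            )
            writer.write("rank_summary", ranks)
        except ValueError as exc:
            log.warning("rank summary skipped: %s", exc)

    def indicators_stage():
        M = indicators.build_sites(state["frame"])
        tab = indicators.indval_table(M)
        perm = indicators.blocked_permutation_test(M, n_perm=config.n_perm, seed=config.seed)
        ci = indicators.bootstrap_ci(M, B=config.n_boot_indval, seed=config.seed + 1)
        n_blocks = M.sites["block"].nunique()
        cv = indicators.blocked_kfold(
            M, K=min(config.k_substrate, n_blocks), seed=config.seed + 2
        )
        table = (
            tab.join(perm[["p_value", "p_adjusted"]])
            .join(ci[["ci_lower", "ci_upper"]])
            .join(cv)
            .sort_values("stat", ascending=False)
            .reset_index()
        )
        writer.write("indicator_table", table)
        for rank in ("genus", "family", "order"):
            if rank not in state["records"].columns:
                continue
            frame_r = archive.aggregate_counts(state["records"], taxon_col=rank)
            if frame_r.empty:
                continue
            Mr = indicators.build_sites(frame_r, taxon_col=rank)
            if Mr.X.shape[1]:
                writer.write(
                    f"presence_scores_{rank}",
                    indicators.presence_score(Mr).reset_index(),
                )
        screening = indicators.ph_screening(
            state["records"], K=config.k_ph, n_perm=config.n_perm,
            n_boot=config.n_boot_indval, seed=config.seed,
        )
        if len(screening["stratum_summary"]):
            writer.write("ph_stratum_summary", screening["stratum_summary"])
        for rank, tbl in screening["tables"].items():
            writer.write(f"ph_indval_{rank}", tbl.reset_index())

    def elevation_stage():
        recs = state["records"].dropna(subset=["elevationMid"])
        if recs.empty:
            raise ValueError("no records with elevation")
        grid = elev_mod.build_bins(recs, n_bins=config.elevation_bins)
        counts = recs["species"].value_counts()
        top = counts.head(20).index.tolist()
        table = elev_mod.profile_table(
            grid, top, df=config.elevation_df, B=config.elevation_boot, seed=config.seed
        )
        writer.write("elevation_modes", table)

    def validate():
        fr = state["fit"]
        diag = validation.quantile_residuals(fr, S=250, seed=config.seed)
        writer.write(
            "residual_diagnostics",
            pd.DataFrame(
                [
                    {
                        "ks_statistic": diag["ks_statistic"],
                        "ks_p": diag["ks_p"],
                        "dispersion_ratio": diag["dispersion_ratio"],
                        "dispersion_p": diag["dispersion_p"],
                        "n_simulations": diag["n_simulations"],
                    }
                ]
            ),
        )
        if config.loco:
            cv = validation.loco_cv(state["frame"], fr.spec)
            writer.write("loco_folds", cv["folds"])
            writer.write("loco_deciles", cv["decile_table"])
            writer.write(
                "loco_summary",
                pd.DataFrame(
                    [
                        {
                            "mean_rmse": cv["mean_rmse"],
                            "mean_poisson_deviance": cv["mean_poisson_deviance"],
                            "calibration_slope": cv["calibration_slope"],
                            "calibration_ci_lower": cv["calibration_ci"][0],
                            "calibration_ci_upper": cv["calibration_ci"][1],
                        }
                    ]
                ),
            )

    run_stage("ingest", [], ingest)
    run_stage("qc", ["ingest"], qc)
    run_stage("aggregate", ["ingest"], aggregate)
    run_stage("diversity", ["aggregate"], diversity_stage)
    run_stage("model", ["aggregate"], model)
    run_stage("indicators", ["aggregate"], indicators_stage)
    run_stage("elevation", ["ingest"], elevation_stage)
    run_stage("validate", ["model"], validate)

    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": status,
        "outputs": writer.outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    failed = [s for s, st in status.items() if st.get("status") == "failed"]
    manifest["ok"] = not failed
    return manifest
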