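"""Effort-weighted indicator-value analysis over blocked site x taxon matrices.

Sites are country x substrate (substrate indicators) or country x pH band
(screening).  The effort-weighted IndVal E statistic combines a
group-equalised specificity A with a weighted within-group occupancy B:

    m_g  = sum_{j in g} w_j x_j / sum_{j in g} w_j      (weighted mean presence)
    A    = m_focal / sum_g m_g                           (specificity)
    B    = m_focal                                       (fidelity)
    E    = sqrt(A * B)

with w_j the site effort (total records).  Inference respects the country
blocking: permutation tests shuffle group labels only within countries, the
bootstrap resamples sites stratified by group, and K-fold validation holds
out entire countries.  The presence-based A x B score is the descriptive
higher-taxon summary (A = focal presences / total presences, B = focal
presences / number of focal-group sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .archive import PH_BAND_DISPLAY, band_ph, round_half_up
from .diversity import goods_coverage

__all__ = [
    "SiteTaxonMatrix",
    "build_sites",
    "indval_E",
    "indval_table",
    "blocked_permutation_test",
    "bootstrap_ci",
    "blocked_kfold",
    "presence_score",
    "ph_screening",
]

MIN_SITES_DEFAULT = 3


@dataclass
class SiteTaxonMatrix:
    """A site x taxon matrix with block labels, group labels and efforts."""

    sites: pd.DataFrame  # columns: block, group, effort
    X: pd.DataFrame  # site x taxon presence (0/1), index aligned with sites
    min_sites: int = MIN_SITES_DEFAULT
    weighted: bool = True

    @property
    def taxa(self) -> pd.Index:
        return self.X.columns

    @property
    def groups(self) -> list:
        return sorted(self.sites["group"].unique())

    def with_groups(self, groups: pd.Series) -> "SiteTaxonMatrix":
        sites = self.sites.copy()
        sites["group"] = groups.to_numpy()
        return SiteTaxonMatrix(sites, self.X, self.min_sites, self.weighted)

    def subset_sites(self, mask_or_idx) -> "SiteTaxonMatrix":
        sites = self.sites.loc[mask_or_idx].reset_index(drop=True)
        X = self.X.loc[mask_or_idx].reset_index(drop=True)
        return SiteTaxonMatrix(sites, X, self.min_sites, self.weighted)


def build_sites(
    frame: pd.DataFrame,
    taxon_col: str = "species",
    group_col: str = "substrateCategory",
    block_col: str = "country",
    min_sites: int = MIN_SITES_DEFAULT,
    weighted: bool = True,
) -> SiteTaxonMatrix:
    """Build the site x taxon presence matrix from a count frame.

    One site per observed (block, group) combination; presence is y > 0; the
    site effort is its total record count.  Taxa occurring in fewer than
    ``min_sites`` sites are dropped.
    """
    if frame.empty:
        raise ValueError("empty frame")
    pivot = frame.pivot_table(
        index=[block_col, group_col],
        columns=taxon_col,
        values="y",
        aggfunc="sum",
        fill_value=0,
        observed=True,
    )
    effort = pivot.sum(axis=1)
    X = (pivot > 0).astype(np.int8)
    keep = X.sum(axis=0) >= min_sites
    X = X.loc[:, keep]
    sites = pd.DataFrame(
        {
            "block": pivot.index.get_level_values(0),
            "group": pivot.index.get_level_values(1),
            "effort": effort.to_numpy(dtype=float),
        }
    ).reset_index(drop=True)
    X = X.reset_index(drop=True)
    return SiteTaxonMatrix(sites=sites, X=X, min_sites=min_sites, weighted=weighted)


def _group_means(M: SiteTaxonMatrix, groups=None) -> pd.DataFrame:
    """Weighted (or unweighted) mean presence of every taxon per group."""
    w = M.sites["effort"].to_numpy() if M.weighted else np.ones(len(M.sites))
    g = M.sites["group"].to_numpy()
    out = {}
    for grp in groups if groups is not None else np.unique(g):
        mask = g == grp
        wsum = w[mask].sum()
        out[grp] = (M.X.to_numpy()[mask] * w[mask, None]).sum(axis=0) / wsum
    return pd.DataFrame(out, index=M.X.columns)  # taxa x groups


def indval_E(M: SiteTaxonMatrix, taxon=None, focal_group=None):
    """Effort-weighted IndVal E.

    With a taxon and focal group: returns (A, B, statistic).  Without:
    returns a taxa x groups DataFrame of statistics (see indval_table for the
    tidy per-taxon best-group summary).
    """
    means = _group_means(M)  # taxa x groups
    denom = means.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = means.div(denom, axis=0)
    B = means
    stat = np.sqrt(A * B)
    if taxon is None:
        return stat
    a = float(A.loc[taxon, focal_group])
    b = float(B.loc[taxon, focal_group])
    return a, b, float(np.sqrt(a * b))


def indval_table(M: SiteTaxonMatrix) -> pd.DataFrame:
    """Per-taxon best group with A, B and the IndVal E statistic.

    Ties on the statistic break toward the larger B, then the lexicographically
    smaller group code (deterministic reproducibility).
    """
    means = _group_means(M)
    A = means.div(means.sum(axis=1), axis=0)
    B = means
    stat = np.sqrt(A * B)
    rows = []
    for taxon in stat.index:
        s = stat.loc[taxon]
        best = sorted(
            s.index, key=lambda g: (-s[g], -B.loc[taxon, g], str(g))
        )[0]
        rows.append(
            {
                "taxon": taxon,
                "group": best,
                "A": float(A.loc[taxon, best]),
                "B": float(B.loc[taxon, best]),
                "stat": float(s[best]),
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def _max_stat(M: SiteTaxonMatrix) -> pd.Series:
    """Max-over-groups IndVal E per taxon (the permutation test statistic)."""
    return indval_E(M).max(axis=1)


def blocked_permutation_test(
    M: SiteTaxonMatrix,
    n_perm: int = 999,
    seed: int = 0,
    statistic=_max_stat,
) -> pd.DataFrame:
    """Country-blocked permutation test with BH step-up adjustment.

    Group labels are permuted among sites within each block; the per-taxon
    statistic is the max-over-groups IndVal E.  p = (1 + #{perm >= obs}) /
    (1 + n_perm); single-site blocks contribute no permutation variability.
    """
    obs = statistic(M)
    rng = np.random.default_rng(seed)
    blocks = M.sites["block"].to_numpy()
    groups = M.sites["group"].to_numpy()
    block_idx = {b: np.where(blocks == b)[0] for b in np.unique(blocks)}
    exceed = np.zeros(len(obs))
    for _ in range(n_perm):
        perm = groups.copy()
        for idx in block_idx.values():
            if len(idx) > 1:
                perm[idx] = groups[rng.permutation(idx)]
        stat_p = statistic(M.with_groups(pd.Series(perm)))
        exceed += (stat_p.to_numpy() >= obs.to_numpy() - 1e-12).astype(float)
    p_raw = (1.0 + exceed) / (1.0 + n_perm)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    return pd.DataFrame(
        {"taxon": obs.index, "stat": obs.to_numpy(), "p_value": p_raw, "p_adjusted": p_adj}
    ).set_index("taxon")


def bootstrap_ci(
    M: SiteTaxonMatrix,
    B: int = 1000,
    seed: int = 0,
    max_undefined: float = 0.025,
) -> pd.DataFrame:
    """Percentile 95% bootstrap intervals for each taxon's best-group IndVal E.

    Sites are resampled with replacement stratified by group.  Replicates in
    which a taxon vanishes entirely leave its statistic undefined; if more
    than ``max_undefined`` of replicates are undefined the corresponding
    bound is reported as unavailable (NaN) — more than half undefined voids
    both bounds.
    """
    base = indval_table(M)
    rng = np.random.default_rng(seed)
    groups = M.sites["group"].to_numpy()
    by_group = {g: np.where(groups == g)[0] for g in np.unique(groups)}
    taxa = M.X.columns
    reps = np.full((B, len(taxa)), np.nan)
    for b in range(B):
        take = np.concatenate(
            [rng.choice(idx, size=len(idx), replace=True) for idx in by_group.values()]
        )
        Mb = M.subset_sites(take)
        present = Mb.X.sum(axis=0) > 0
        stat_b = indval_E(Mb)
        for t_i, taxon in enumerate(taxa):
            if present[taxon]:
                reps[b, t_i] = stat_b.loc[taxon, base.loc[taxon, "group"]]
    rows = []
    for t_i, taxon in enumerate(taxa):
        vals = reps[:, t_i]
        ok = np.isfinite(vals)
        frac_undef = 1.0 - ok.mean()
        if frac_undef > 0.5:
            lo = hi = np.nan
        else:
            lo, hi = np.percentile(vals[ok], [2.5, 97.5])
            if frac_undef > max_undefined:
                lo = np.nan
        rows.append(
            {
                "taxon": taxon,
                "stat": base.loc[taxon, "stat"],
                "group": base.loc[taxon, "group"],
                "ci_lower": lo,
                "ci_upper": hi,
                "frac_undefined": frac_undef,
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def blocked_kfold(M: SiteTaxonMatrix, K: int = 5, seed: int = 0) -> pd.DataFrame:
    """Country-blocked K-fold held-out specificity (A) and fidelity (B).

    Blocks (countries) are partitioned into K folds.  Per fold, the best
    group per taxon is chosen on the training sites (training statistic, ties
    to larger training B then lexicographic group code) and A, B are
    recomputed on the held-out sites for that group; fold values are averaged.
    Taxa absent from training or held-out sites in a fold contribute nothing
    for that fold; taxa with no usable fold are reported unavailable.
    """
    blocks = np.array(sorted(M.sites["block"].unique()))
    if K > len(blocks):
        raise ValueError(f"K = {K} exceeds the number of blocks ({len(blocks)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    folds = [blocks[order[i::K]] for i in range(K)]

    sums_A = pd.Series(0.0, index=M.X.columns)
    sums_B = pd.Series(0.0, index=M.X.columns)
    n_folds = pd.Series(0, index=M.X.columns)
    for held in folds:
        test_mask = M.sites["block"].isin(held).to_numpy()
        train = M.subset_sites(~test_mask)
        test = M.subset_sites(test_mask)
        if train.sites.empty or test.sites.empty:
            continue
        train_tab = indval_table(train)
        test_means = _group_means(test)
        test_A = test_means.div(test_means.sum(axis=1), axis=0)
        for taxon in M.X.columns:
            if train.X[taxon].sum() == 0 or test.X[taxon].sum() == 0:
                continue
            best = train_tab.loc[taxon, "group"]
            if best not in test_means.columns or not np.isfinite(test_A.loc[taxon, best]):
                continue
            sums_A[taxon] += float(test_A.loc[taxon, best])
            sums_B[taxon] += float(test_means.loc[taxon, best])
            n_folds[taxon] += 1
    out = pd.DataFrame(
        {
            "held_out_A": sums_A / n_folds.replace(0, np.nan),
            "held_out_B": sums_B / n_folds.replace(0, np.nan),
            "n_folds_used": n_folds,
        }
    )
    return out


def presence_score(M: SiteTaxonMatrix, taxon=None) -> pd.DataFrame | dict:
    """Presence-based A x B indicator score for (higher) taxa.

    A = presences in the focal group / total presences across groups;
    B = presences in the focal group / number of sites in the focal group;
    score = A x B; the maximising group is reported (ties to larger B then
    lexicographic group code).  Full precision is retained alongside 2-dp
    half-up display columns.
    """
    g = M.sites["group"].to_numpy()
    pres = M.X.to_numpy()
    group_list = sorted(np.unique(g))
    n_sites = {grp: int((g == grp).sum()) for grp in group_list}
    focal = {grp: pres[g == grp].sum(axis=0) for grp in group_list}
    total = pres.sum(axis=0)
    rows = []
    for t_i, tx in enumerate(M.X.columns):
        per_group = []
        for grp in group_list:
            nf = int(focal[grp][t_i])
            A = nf / total[t_i] if total[t_i] else np.nan
            B = nf / n_sites[grp]
            per_group.append((grp, nf, A, B, A * B))
        best = sorted(per_group, key=lambda r: (-r[4], -r[3], str(r[0])))[0]
        grp, nf, A, B, score = best
        rows.append(
            {
                "taxon": tx,
                "group": grp,
                "n_focal": nf,
                "n_total": int(total[t_i]),
                "n_sites": n_sites[grp],
                "A": A,
                "B": B,
                "score": score,
                "A_display": round_half_up(A),
                "B_display": round_half_up(B),
                "score_display": round_half_up(score),
            }
        )
    out = pd.DataFrame(rows).set_index("taxon")
    if taxon is not None:
        return out.loc[taxon].to_dict()
    return out.sort_values("score", ascending=False)


def ph_screening(
    records: pd.DataFrame,
    ranks: tuple[str, ...] = ("species", "genus", "family"),
    K: int = 3,
    n_perm: int = 999,
    n_boot: int = 1000,
    min_sites: int = MIN_SITES_DEFAULT,
    seed: int = 0,
) -> dict:
    """pH-band screening: stratum summary plus IndVal E over country x pH sites.

    Uses only records with non-missing species, substrateCategory and pH.
    Returns a dict with the substrate x band stratum summary (records,
    species, singletons, Good's coverage) and one screening IndicatorTable
    per taxonomic rank (statistic, permutation/BH p, bootstrap CI, K-fold
    held-out A/B).  Outputs are labelled screening evidence.
    """
    df = records.dropna(subset=["species", "substrateCategory", "pH"]).copy()
    if df.empty:
        return {"stratum_summary": pd.DataFrame(), "tables": {}, "label": "screening"}
    df["ph_band"] = band_ph(df["pH"])

    strata = []
    for (sub, band), part in df.groupby(["substrateCategory", "ph_band"], observed=True):
        counts = part["species"].value_counts()
        strata.append(
            {
                "substrateCategory": sub,
                "ph_band": PH_BAND_DISPLAY.get(band, band),
                "records": int(len(part)),
                "species": int(counts.size),
                "singletons": int((counts == 1).sum()),
                "coverage": round_half_up(goods_coverage(len(part), int((counts == 1).sum()))),
            }
        )
    summary = pd.DataFrame(strata)

    tables = {}
    for rank in ranks:
        if rank not in df.columns:
            continue
        frame = (
            df.groupby(["country", "ph_band", rank], observed=True)
            .size()
            .rename("y")
            .reset_index()
        )
        try:
            M = build_sites(
                frame, taxon_col=rank, group_col="ph_band", min_sites=min_sites
            )
        except ValueError:
            continue
        if M.X.shape[1] == 0 or len(M.groups) < 2:
            continue
        tab = indval_table(M)
        perm = blocked_permutation_test(M, n_perm=n_perm, seed=seed)
        ci = bootstrap_ci(M, B=n_boot, seed=seed + 1)
        n_blocks = M.sites["block"].nunique()
        cv = (
            blocked_kfold(M, K=min(K, n_blocks), seed=seed + 2)
            if n_blocks >= 2
            else pd.DataFrame(index=tab.index)
        )
        table = tab.join(perm[["p_value", "p_adjusted"]]).join(
            ci[["ci_lower", "ci_upper"]]
        )
        table = table.join(cv)
        table["rank"] = rank
        table["label"] = "screening"
        tables[rank] = table.sort_values("stat", ascending=False)
    return {"stratum_summary": summary, "tables": tables, "label": "screening"}
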