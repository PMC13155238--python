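"""Zero-truncated negative-binomial mixed model with log effort offsets.

The substrate-effects model treats the aggregated country x substrate x
species record count y (y > 0 only) as ZTNB with log link:

    log mu = beta_0 + beta_substrate + u_country + v_group [+ s_group,substrate]
             + offset,

where the offset is the log leave-one-out effort of the country x substrate
cell.  Random effects are Gaussian; the marginal likelihood is approximated by
the Laplace method: for given variance parameters theta = (log k, log sigmas)
the fixed effects and the random-effect vector are profiled by an inner
Newton optimisation of the penalised log-likelihood, and theta is optimised
in an outer quasi-Newton loop.

Random substrate slopes per group use a diagonal covariance (one intercept
variance plus one shared slope variance) rather than a fully correlated
covariance; see docs/methods.md for the rationale.

Wald covariance for the fixed effects conditions on the estimated variance
parameters (the beta block of the inverse joint Hessian at the mode), the
standard GLMM practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.linalg import cho_factor, cho_solve

from .ztnb import ztnb_eta_derivatives, ztnb_rvs

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit",
    "rate_ratios",
    "emm_pairwise",
    "bootstrap_ranks",
    "order_deviations",
]


@dataclass
class ModelSpec:
    """Specification of the substrate-effects mixed model."""

    reference: str = "LIG"
    group_col: str = "species"
    group_slopes: bool = False
    rarity_threshold: int = 100


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FitResult:
    """Fitted ZTNB mixed model."""

    spec: ModelSpec
    substrates: list[str]
    beta: pd.Series
    vcov_beta: pd.DataFrame
    k: float
    sigmas: dict[str, float]
    u: dict[str, pd.Series]
    u_sd: dict[str, pd.Series]
    loglik: float
    converged: bool
    boundary: bool
    n_obs: int
    grad_norm: float
    design: dict = field(repr=False, default_factory=dict)

    def linear_predictor(self, include_u: bool = True, include_offset: bool = True):
        d = self.design
        eta = d["X"] @ self.beta.to_numpy()
        if include_u:
            eta = eta + d["Z"] @ self._u_vector()
        if include_offset:
            eta = eta + d["offset"]
        return np.asarray(eta)

    def _u_vector(self) -> np.ndarray:
        return np.concatenate([self.u[name].to_numpy() for name in self.design["comp_order"]])

    def fitted_mu(self, include_u: bool = True) -> np.ndarray:
        return np.exp(self.linear_predictor(include_u=include_u))


def _build_design(frame: pd.DataFrame, spec: ModelSpec):
    frame = frame.reset_index(drop=True)
    subs = sorted(frame["substrateCategory"].unique())
    if spec.reference not in subs:
        raise ValueError(f"reference substrate {spec.reference!r} not present in the frame")
    subs = [spec.reference] + [s for s in subs if s != spec.reference]
    n = len(frame)

    sub_idx = frame["substrateCategory"].map({s: i for i, s in enumerate(subs)}).to_numpy()
    x_cols = ["(Intercept)"] + subs[1:]
    X = np.zeros((n, len(x_cols)))
    X[:, 0] = 1.0
    for j, s in enumerate(subs[1:], start=1):
        X[:, j] = sub_idx == j

    comp_order: list[str] = []
    blocks = []
    labels: dict[str, list] = {}

    countries = sorted(frame["country"].unique())
    ci = frame["country"].map({c: i for i, c in enumerate(countries)}).to_numpy()
    Zc = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), ci)), shape=(n, len(countries))
    )
    comp_order.append("country")
    blocks.append(Zc)
    labels["country"] = countries

    groups = sorted(frame[spec.group_col].unique())
    gi = frame[spec.group_col].map({g: i for i, g in enumerate(groups)}).to_numpy()
    Zg = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), gi)), shape=(n, len(groups))
    )
    comp_order.append("group")
    blocks.append(Zg)
    labels["group"] = groups

    if spec.group_slopes:
        # one column per (group, non-reference substrate): indicator of rows of
        # that group on that substrate; a single shared slope variance
        G, S1 = len(groups), len(subs) - 1
        rows = np.arange(n)
        on = sub_idx > 0
        col = gi[on] * S1 + (sub_idx[on] - 1)
        Zs = sparse.csr_matrix(
            (np.ones(on.sum()), (rows[on], col)), shape=(n, G * S1)
        )
        comp_order.append("slope")
        blocks.append(Zs)
        labels["slope"] = [(g, s) for g in groups for s in subs[1:]]

    Z = sparse.hstack(blocks, format="csr")
    comp_sizes = {name: b.shape[1] for name, b in zip(comp_order, blocks)}
    A = sparse.hstack([sparse.csr_matrix(X)] + blocks, format="csr")
    return {
        "frame": frame,
        "substrates": subs,
        "x_cols": x_cols,
        "X": X,
        "Z": Z,
        "A": A,
        "comp_order": comp_order,
        "comp_sizes": comp_sizes,
        "labels": labels,
        "y": frame["y"].to_numpy(dtype=float),
        "offset": frame["log_offset"].to_numpy(dtype=float),
        "country_codes": ci,
        "group_codes": gi,
        "sub_idx": sub_idx,
    }


def _inner_newton(y, A, offset, k, pen, z0, weights, tol=1e-9, max_iter=60):
    """Profile (beta, u) for fixed (k, variances) by damped Newton.

    pen is the diagonal of the quadratic penalty (0 for fixed effects,
    1/sigma^2 for random effects).  Returns the optimum, the objective, the
    observation log-likelihood, and the (clipped) Hessian.
    """
    z = z0.copy()

    def objective(zv):
        eta = A @ zv + offset
        ll, d1, d2 = ztnb_eta_derivatives(y, eta, k)
        with np.errstate(over="ignore", invalid="ignore"):
            obj = -np.sum(weights * ll) + 0.5 * np.sum(pen * zv**2)
        if not np.isfinite(obj):
            obj = np.inf
        return obj, ll, d1, d2

    obj, ll, d1, d2 = objective(z)
    H = None
    for _ in range(max_iter):
        g = -(A.T @ (weights * d1)) + pen * z
        w_h = np.clip(-d2, 1e-10, None) * weights
        Aw = A.multiply(w_h[:, None])
        H = (A.T @ Aw).toarray()
        H[np.diag_indices_from(H)] += pen + 1e-10
        try:
            cf = cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-6
            cf = cho_factor(H, lower=True)
        step = cho_solve(cf, g)
        gnorm = float(np.max(np.abs(g)))
        if gnorm < 1e-6:
            break
        gts = float(g @ step)
        t = 1.0
        accepted = False
        for _ in range(40):
            z_new = z - t * step
            obj_new, ll_new, d1_new, d2_new = objective(z_new)
            if np.isfinite(obj_new) and (
                obj_new <= obj - 1e-4 * t * gts or obj_new <= obj + 1e-12
            ):
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break  # no finite improving step; stay at the current point
        converged_now = abs(obj - obj_new) < tol * (1.0 + abs(obj)) and gnorm < 1e-3
        z, obj, ll, d1, d2 = z_new, obj_new, ll_new, d1_new, d2_new
        if converged_now:
            break
    # final Hessian at the optimum
    w_h = np.clip(-d2, 1e-10, None) * weights
    Aw = A.multiply(w_h[:, None])
    H = (A.T @ Aw).toarray()
    H[np.diag_indices_from(H)] += pen + 1e-10
    g = -(A.T @ (weights * d1)) + pen * z
    return z, obj, float(np.sum(weights * ll)), H, float(np.max(np.abs(g)))


def fit(
    frame: pd.DataFrame,
    spec: ModelSpec | None = None,
    weights: np.ndarray | None = None,
    start_theta: np.ndarray | None = None,
    outer_maxiter: int = 60,
) -> FitResult:
    """Fit the ZTNB mixed model by Laplace-approximated maximum likelihood.

    Starting values follow a fixed recipe (Poisson GLM fixed effects, k = 1,
    random-effect SDs 0.3); the procedure is deterministic given the data.
    """
    spec = spec or ModelSpec()
    if frame.empty:
        raise ValueError("empty count frame")
    if (frame["y"] < 1).any():
        raise ValueError("count frame must contain positive counts only")
    if not np.isfinite(frame["log_offset"]).all():
        raise ValueError("all offsets must be finite")

    d = _build_design(frame, spec)
    y, A, offset = d["y"], d["A"], d["offset"]
    n = len(y)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    p = len(d["x_cols"])
    q = sum(d["comp_sizes"].values())

    # Poisson GLM starting values for the fixed effects
    Xd = d["X"]
    try:
        import statsmodels.api as sm

        glm = sm.GLM(y, Xd, family=sm.families.Poisson(), offset=offset, freq_weights=w)
        beta0 = glm.fit(maxiter=50).params
    except Exception:
        beta0 = np.zeros(p)
        beta0[0] = np.log(max(y.mean(), 1.0)) - np.mean(offset)
    z_state = {"z": np.concatenate([beta0, np.zeros(q)])}

    comp_order = d["comp_order"]
    n_comp = len(comp_order)
    theta0 = (
        np.asarray(start_theta, dtype=float)
        if start_theta is not None
        else np.concatenate([[0.0], np.full(n_comp, np.log(0.3))])
    )
    comp_slices = {}
    start = p
    for name in comp_order:
        comp_slices[name] = slice(start, start + d["comp_sizes"][name])
        start += d["comp_sizes"][name]

    def penalty_from_theta(theta):
        pen = np.zeros(p + q)
        for j, name in enumerate(comp_order):
            sd = np.exp(theta[1 + j])
            pen[comp_slices[name]] = 1.0 / sd**2
        return pen

    def nll(theta):
        k = np.exp(theta[0])
        pen = penalty_from_theta(theta)
        z, obj, ll, H, gnorm = _inner_newton(y, A, offset, k, pen, z_state["z"], w)
        z_state["z"] = z
        Huu = H[p:, p:]
        sign, logdet = np.linalg.slogdet(Huu)
        if sign <= 0:
            return 1e10
        log_det_D = 0.0
        for j, name in enumerate(comp_order):
            log_det_D += 2.0 * theta[1 + j] * d["comp_sizes"][name]
        return obj + 0.5 * log_det_D + 0.5 * logdet

    bounds = [(-4.0, 8.0)] + [(-5.0, 3.0)] * n_comp
    res = optimize.minimize(
        nll,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": outer_maxiter, "eps": 1e-4, "ftol": 1e-9},
    )
    theta = res.x
    k = float(np.exp(theta[0]))
    pen = penalty_from_theta(theta)
    z, obj, ll, H, gnorm = _inner_newton(y, A, offset, k, pen, z_state["z"], w)

    # Wald covariance of beta: beta block of the inverse joint Hessian
    Hinv = np.linalg.inv(H)
    vcov_beta = Hinv[:p, :p]
    # conditional SDs of the random effects
    u_sd_all = np.sqrt(np.clip(np.diag(Hinv)[p:], 0.0, None))

    sigmas = {name: float(np.exp(theta[1 + j])) for j, name in enumerate(comp_order)}
    boundary = any(theta[1 + j] <= bounds[1 + j][0] + 1e-6 for j in range(n_comp))

    u = {}
    u_sd = {}
    for name in comp_order:
        sl = comp_slices[name]
        lab = d["labels"][name]
        idx = pd.Index(lab) if name != "slope" else pd.MultiIndex.from_tuples(lab)
        u[name] = pd.Series(z[sl], index=idx, name=name)
        u_sd[name] = pd.Series(u_sd_all[sl.start - p : sl.stop - p], index=idx)

    beta = pd.Series(z[:p], index=d["x_cols"], name="beta")

    result = FitResult(
        spec=spec,
        substrates=d["substrates"],
        beta=beta,
        vcov_beta=pd.DataFrame(vcov_beta, index=d["x_cols"], columns=d["x_cols"]),
        k=k,
        sigmas=sigmas,
        u=u,
        u_sd=u_sd,
        loglik=float(-res.fun),
        converged=bool(res.success or res.fun < 1e9),
        boundary=boundary,
        n_obs=n,
        grad_norm=gnorm,
        design=d,
    )
    if not np.isfinite(result.loglik):
        raise ConvergenceError(f"model did not converge (gradient norm {gnorm:.3g})")
    return result


def rate_ratios(fit_result: FitResult, alpha: float = 0.05) -> pd.DataFrame:
    """Exponentiated substrate contrasts vs the reference with Wald CIs.

    The reference row reports a ratio of exactly 1.00 with no interval.
    """
    zcrit = stats.norm.ppf(1 - alpha / 2)
    rows = [
        {
            "substrateCategory": fit_result.spec.reference,
            "rate_ratio": 1.0,
            "ci_lower": np.nan,
            "ci_upper": np.nan,
            "log_ratio": 0.0,
            "se": np.nan,
        }
    ]
    for s in fit_result.substrates[1:]:
        b = fit_result.beta[s]
        se = float(np.sqrt(fit_result.vcov_beta.loc[s, s]))
        with np.errstate(over="ignore"):  # inf = unbounded bound, e.g. SAX-scale data
            rows.append(
                {
                    "substrateCategory": s,
                    "rate_ratio": float(np.exp(b)),
                    "ci_lower": float(np.exp(b - zcrit * se)),
                    "ci_upper": float(np.exp(b + zcrit * se)),
                    "log_ratio": float(b),
                    "se": se,
                }
            )
    return pd.DataFrame(rows)


def _emm_eta(fit_result: FitResult) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Linear predictor of each substrate EMM at offset 0, REs at 0, and the
    contrast matrix mapping beta to the EMM vector."""
    subs = fit_result.substrates
    p = len(fit_result.beta)
    L = np.zeros((len(subs), p))
    L[:, 0] = 1.0
    for i, s in enumerate(subs[1:], start=1):
        L[i, i] = 1.0
    eta = L @ fit_result.beta.to_numpy()
    return eta, L, subs


def emm_pairwise(fit_result: FitResult, n_mc: int = 200_000, seed: int = 0) -> pd.DataFrame:
    """Pairwise response-scale EMM ratios at unit effort with max-|z| adjustment.

    EMMs set the offset to 0 and all random effects to their population mean;
    the family-wise adjustment is the single-step max-|z| procedure under the
    joint normal approximation of all pairwise log-ratio contrasts (the
    behaviour of Tukey-adjusted response-scale ratios in standard EMM
    software).  The adjusted p-value is evaluated by quasi-Monte-Carlo on the
    contrast correlation matrix.
    """
    eta, L, subs = _emm_eta(fit_result)
    V = fit_result.vcov_beta.to_numpy()
    pairs = [(i, j) for i in range(len(subs)) for j in range(i + 1, len(subs))]
    C = np.array([L[i] - L[j] for i, j in pairs])
    est = C @ fit_result.beta.to_numpy()
    cov = C @ V @ C.T
    se = np.sqrt(np.diag(cov))
    zstat = est / se
    corr = cov / np.outer(se, se)

    # max-|z| null draws (deterministic generator)
    rng = np.random.default_rng(seed)
    ev, evec = np.linalg.eigh(corr)
    root = evec @ np.diag(np.sqrt(np.clip(ev, 0.0, None)))
    draws = rng.standard_normal((n_mc, corr.shape[0])) @ root.T
    maxabs = np.abs(draws).max(axis=1)

    p_raw = 2 * stats.norm.sf(np.abs(zstat))
    p_adj = np.array([(1 + np.sum(maxabs >= abs(z))) / (1 + n_mc) for z in zstat])
    p_adj = np.maximum(p_adj, p_raw)

    with np.errstate(over="ignore"):
        out = pd.DataFrame(
        {
            "contrast": [f"{subs[i]} / {subs[j]}" for i, j in pairs],
            "ratio": np.exp(est),
            "se_log": se,
            "z": zstat,
            "p_value": p_raw,
            "p_adjusted": np.minimum(p_adj, 1.0),
            "ci_lower": np.exp(est - 1.959963984540054 * se),
            "ci_upper": np.exp(est + 1.959963984540054 * se),
        }
    )
    return out


def emm_table(fit_result: FitResult) -> pd.DataFrame:
    """Per-substrate EMMs on the response scale at unit effort."""
    eta, L, subs = _emm_eta(fit_result)
    V = fit_result.vcov_beta.to_numpy()
    se = np.sqrt(np.einsum("ip,pq,iq->i", L, V, L))
    with np.errstate(over="ignore"):
        return pd.DataFrame(
            {
                "substrateCategory": subs,
                "emm": np.exp(eta),
                "ci_lower": np.exp(eta - 1.959963984540054 * se),
                "ci_upper": np.exp(eta + 1.959963984540054 * se),
            }
        )


def simulate_from_fit(fit_result: FitResult, rng: np.random.Generator, redraw_u: bool = True):
    """Parametric simulation of the response for the fitted design.

    Redraws the random effects from their estimated distributions (the
    parametric-bootstrap convention) and then draws ZTNB counts row-wise.
    """
    d = fit_result.design
    eta = d["X"] @ fit_result.beta.to_numpy() + d["offset"]
    if redraw_u:
        u_new = []
        for name in d["comp_order"]:
            sd = fit_result.sigmas[name]
            u_new.append(rng.normal(0.0, sd, d["comp_sizes"][name]))
        eta = eta + d["Z"] @ np.concatenate(u_new)
    else:
        eta = eta + d["Z"] @ fit_result._u_vector()
    mu = np.exp(np.asarray(eta))
    return ztnb_rvs(mu, fit_result.k, rng)


def bootstrap_ranks(
    fit_result: FitResult,
    B: int = 2000,
    rarity_threshold: int | None = None,
    seed: int = 0,
    outer_maxiter: int = 25,
) -> pd.DataFrame:
    """Uncertainty-aware substrate ranks from parametric-bootstrap EMMs.

    Per replicate: simulate counts from the fitted model, refit, compute EMMs
    at offset 0, and rank substrates descending by EMM (rank 1 = largest).
    Substrates whose data totals fall below the rarity threshold are excluded
    from the ranking.  Information-weighted ranks shrink each replicate's
    substrate EMMs toward the replicate grand mean with factor (1 - w_s),
    w_s = n_s / sum(n_s), before ranking.
    """
    spec = fit_result.spec
    rarity = spec.rarity_threshold if rarity_threshold is None else rarity_threshold
    d = fit_result.design
    frame = d["frame"]
    totals = frame.groupby("substrateCategory", observed=True)["y"].sum()
    keep = [s for s in fit_result.substrates if totals.get(s, 0) >= rarity]
    if len(keep) < 2:
        raise ValueError("fewer than two substrates pass the rarity threshold")
    w_s = (totals[keep] / totals[keep].sum()).to_numpy()

    rng = np.random.default_rng(seed)
    theta_hat = np.concatenate(
        [[np.log(fit_result.k)], [np.log(max(fit_result.sigmas[c], 1e-4)) for c in d["comp_order"]]]
    )
    ranks = []
    wranks = []
    failures = 0
    for _ in range(B):
        y_star = simulate_from_fit(fit_result, rng)
        frame_b = frame.copy()
        frame_b["y"] = y_star
        try:
            fb = fit(frame_b, spec, start_theta=theta_hat, outer_maxiter=outer_maxiter)
        except Exception:
            failures += 1
            continue
        emms = emm_table(fb).set_index("substrateCategory")["emm"]
        vals = emms.reindex(keep).to_numpy()
        if not np.isfinite(vals).all() or (vals <= 0).any():
            failures += 1
            continue
        log_v = np.log(vals)
        order = (-log_v).argsort()
        r = np.empty(len(keep), dtype=int)
        r[order] = np.arange(1, len(keep) + 1)
        ranks.append(r)
        shrunk = np.mean(log_v) + w_s * (log_v - np.mean(log_v))
        order_w = (-shrunk).argsort()
        rw = np.empty(len(keep), dtype=int)
        rw[order_w] = np.arange(1, len(keep) + 1)
        wranks.append(rw)
    if not ranks:
        raise ConvergenceError("all bootstrap replicates failed to refit")
    R = np.array(ranks)
    RW = np.array(wranks)
    out = pd.DataFrame(
        {
            "substrateCategory": keep,
            "median_rank": np.median(R, axis=0),
            "rank_25": np.percentile(R, 25, axis=0),
            "rank_75": np.percentile(R, 75, axis=0),
            "rank_2.5": np.percentile(R, 2.5, axis=0),
            "rank_97.5": np.percentile(R, 97.5, axis=0),
            "info_weighted_median": np.median(RW, axis=0),
            "n_boot": len(ranks),
            "n_failed": failures,
        }
    )
    return out.sort_values("median_rank").reset_index(drop=True)


def order_deviations(
    order_frame: pd.DataFrame,
    reference: str = "LIG",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, FitResult]:
    """Order-level random-slope deviations (BLUPs) from the population contrast.

    Fits the order-level model with random intercepts and substrate slopes for
    orders plus a country intercept, and reports the conditional modes of the
    slope deviations with conditional-variance-approximation intervals; 0
    means no deviation from the population-level substrate contrast.  The
    reference substrate carries no deviation parameter.
    """
    spec = ModelSpec(reference=reference, group_col="order", group_slopes=True)
    fr = fit(order_frame, spec)
    zc = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for (order, substrate), val in fr.u["slope"].items():
        sd = fr.u_sd["slope"][(order, substrate)]
        rows.append(
            {
                "order": order,
                "substrateCategory": substrate,
                "deviation": float(val),
                "ci_lower": float(val - zc * sd),
                "ci_upper": float(val + zc * sd),
                "excludes_zero": bool(val - zc * sd > 0 or val + zc * sd < 0),
            }
        )
    return pd.DataFrame(rows), fr
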