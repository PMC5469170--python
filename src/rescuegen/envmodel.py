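"""Hierarchical Bayesian regression of individual homozygosity on environment.

Model: for individual i with standardized site-level predictors x_i,

    HL_i ~ Normal(mu_i, sigma^2)
    mu_i = beta0 + sum_j gamma_j beta_j x_ij + b_basin(i) + s_site(i)

with per-variable inclusion indicators gamma_j ~ Bernoulli(0.5) and a
Gaussian slab on included effects (stochastic-search variable selection;
for a linear model this yields the same posterior over inclusion as a
reversible-jump sampler, with a simpler, fully conjugate Gibbs sweep).
The slab variance is hierarchical — inverse-gamma centred on the
unit-information scale var(y)/mean(x'x) and updated from the currently
included effects — so that excluded-variable inclusion probabilities
stay near the prior under pure noise (a fixed wide slab would crush them
through the Occam factor) while true effects are detected and estimated
essentially unshrunk. Basin and site intercepts are exchangeable normals
whose scales carry half-normal(1) priors, updated by slice sampling. The
residual variance gets a vague inverse-gamma prior.

Predictive use (cross-validation) relies on the fixed effects only:
clustering intercepts absorb spatial autocorrelation during fitting but
are not transferable to unseen clusters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rescuegen.containers import SiteEnvTable

__all__ = [
    "HLModelSpec",
    "HLModelFit",
    "standardize_and_prune",
    "build_model_spec",
    "fit_hl_model",
    "cross_validate",
    "effect_direction",
]


# ---------------------------------------------------------------------------
# Predictor preparation
# ---------------------------------------------------------------------------

def standardize_and_prune(
    env: SiteEnvTable,
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> tuple[SiteEnvTable, dict]:
    """Drop one variable from every highly correlated pair, then standardize.

    Pearson correlations are computed across sites (one record per site).
    Greedy pruning: while any pair has |r| >= threshold, drop the member
    of the worst pair with the larger mean absolute correlation to all
    remaining variables; a `priority` list protects variables (listed
    variables are kept in preference to unlisted ones). Constant
    variables are dropped with a warning. Returns the standardized
    survivor table and a report of dropped variables.
    """
    if env.n_sites < 2:
        raise ValueError("pruning requires at least 2 sites")
    frame = env.frame.copy()
    dropped: dict[str, str] = {}
    for col in env.variables:
        if frame[col].std(ddof=0) == 0:
            warnings.warn(f"variable {col!r} is constant; dropped", stacklevel=2)
            dropped[col] = "constant"
            frame = frame.drop(columns=col)
    keep = [c for c in frame.columns if c not in SiteEnvTable.ID_COLS]
    protected = set(priority or [])

    def worst_pair(cols: list[str]) -> tuple[str, str, float] | None:
        corr = frame[cols].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] < threshold:
            return None
        return cols[i], cols[j], float(corr[i, j])

    while len(keep) > 1:
        hit = worst_pair(keep)
        if hit is None:
            break
        a, b, r = hit
        if a in protected and b not in protected:
            victim = b
        elif b in protected and a not in protected:
            victim = a
        else:
            corr = frame[keep].corr().abs()
            victim = a if corr[a].mean() >= corr[b].mean() else b
        dropped[victim] = f"|r|={r:.3f} with {a if victim == b else b}"
        keep.remove(victim)

    pruned = SiteEnvTable(frame[list(SiteEnvTable.ID_COLS) + keep])
    return pruned.standardized(), {"dropped": dropped, "kept": keep}


@dataclass
class HLModelSpec:
    """Response, standardized predictors and clustering labels for one fit."""

    y: np.ndarray
    X: np.ndarray
    variable_names: list[str]
    basin: np.ndarray  # integer codes per individual
    site: np.ndarray  # integer codes per individual
    prior_inclusion: float = 0.5
    slab_a: float = 2.0  # inverse-gamma shape for the slab variance
    slab_b_scale: float = 1.0  # slab prior mean as a multiple of var(y)/mean(x'x)
    n_iter: int = 4000
    burn_in: int = 1000
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError("response length does not match predictor rows")
        if len(self.variable_names) != p:
            raise ValueError("one name per predictor column required")
        if n < 50:
            raise ValueError("model requires at least 50 individuals")
        for labels, what in ((self.basin, "basin"), (self.site, "site")):
            if np.asarray(labels).shape != (n,):
                raise ValueError(f"every individual needs a {what} label")
        self.basin = np.asarray(self.basin, dtype=int)
        self.site = np.asarray(self.site, dtype=int)
        if not 0 < self.prior_inclusion < 1:
            raise ValueError("prior inclusion probability must be in (0, 1)")


@dataclass
class HLModelFit:
    variable_names: list[str]
    inclusion_prob: np.ndarray
    effect_mean: np.ndarray  # posterior mean of gamma*beta (model-averaged)
    effect_sd: np.ndarray
    effect_ci: np.ndarray  # (p, 2) central 95% interval of gamma*beta
    intercept: float
    sigma2_mean: float
    basin_sd_mean: float
    site_sd_mean: float
    r_squared: float
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    cv_r_squared: float | None = None

    def table(self, prob_threshold: float = 0.7) -> pd.DataFrame:
        return pd.DataFrame({
            "variable": self.variable_names,
            "inclusion_prob": self.inclusion_prob,
            "effect_mean": self.effect_mean,
            "direction": effect_direction(self, prob_threshold),
        })


def build_model_spec(
    env: SiteEnvTable,
    hl: pd.DataFrame,
    **kwargs,
) -> HLModelSpec:
    """Join a standardized site table with a per-individual HL frame.

    `hl` needs columns individual_id, population, hl and optionally
    site/basin; individuals without a resolvable site inherit their
    population's mean environmental values (and a per-population pseudo
    site label).
    """
    variables = env.variables
    site_rows = env.frame.set_index("site_id")
    pop_means = env.frame.groupby("population")[variables].mean()
    pop_basin = env.frame.drop_duplicates("population").set_index("population")["basin"]

    X = np.zeros((len(hl), len(variables)))
    site_labels: list[str] = []
    basin_labels: list[str] = []
    for i, row in enumerate(hl.itertuples(index=False)):
        site = getattr(row, "site", None)
        if site is not None and site in site_rows.index:
            X[i] = site_rows.loc[site, variables].to_numpy(dtype=float)
            site_labels.append(str(site))
            basin_labels.append(str(site_rows.loc[site, "basin"]))
        else:
            X[i] = pop_means.loc[row.population].to_numpy(dtype=float)
            site_labels.append(f"popmean:{row.population}")
            basin_labels.append(str(pop_basin.loc[row.population]))
    site_codes = pd.factorize(site_labels)[0]
    basin_codes = pd.factorize(basin_labels)[0]
    return HLModelSpec(
        y=hl["hl"].to_numpy(dtype=float),
        X=X,
        variable_names=list(variables),
        basin=basin_codes,
        site=site_codes,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _slice_sample_scale(
    value: float, sum_sq: float, k: int, rng: np.random.Generator,
    prior_scale: float = 1.0, width: float = 0.5, max_steps: int = 50,
) -> float:
    """Slice-sample a random-effect scale with half-normal(prior_scale) prior.

    Target: p(s) ∝ s^(−k) exp(−sum_sq/(2s²)) exp(−s²/(2 prior_scale²)), s>0.
    """

    def logp(s: float) -> float:
        if s <= 1e-6:
            return -math.inf
        return -k * math.log(s) - sum_sq / (2 * s * s) - s * s / (2 * prior_scale**2)

    y0 = logp(value) + math.log(rng.random())
    lo, hi = max(1e-6, value - width), value + width
    for _ in range(max_steps):
        if logp(lo) < y0 or lo <= 1e-6:
            break
        lo = max(1e-6, lo - width)
    for _ in range(max_steps):
        if logp(hi) < y0:
            break
        hi += width
    for _ in range(max_steps):
        s = rng.uniform(lo, hi)
        if logp(s) > y0:
            return s
        if s < value:
            lo = s
        else:
            hi = s
    return value


def _run_chain(spec: HLModelSpec, seed: int) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    y, X = spec.y, spec.X
    n, p = X.shape
    n_basin = int(spec.basin.max()) + 1
    n_site = int(spec.site.max()) + 1
    xtx = np.einsum("ij,ij->j", X, X)
    if (xtx == 0).any():
        raise ValueError("singular predictor matrix: zero-variance column")
    # hierarchical slab centred on the unit-information scale
    unit_info = float(y.var()) / float(xtx.mean())
    slab_a = spec.slab_a
    slab_b = spec.slab_b_scale * (slab_a - 1.0) * unit_info
    v_slab = unit_info
    logit_prior = math.log(spec.prior_inclusion / (1 - spec.prior_inclusion))

    beta0 = float(y.mean())
    beta = np.zeros(p)
    gamma = rng.random(p) < spec.prior_inclusion
    b = np.zeros(n_basin)
    s = np.zeros(n_site)
    sigma2 = float(y.var()) or 1e-4
    sd_b, sd_s = 0.1, 0.1

    keep = spec.n_iter - spec.burn_in
    out = {
        "gamma": np.zeros((keep, p)),
        "gb": np.zeros((keep, p)),  # gamma * beta
        "beta0": np.zeros(keep),
        "sigma2": np.zeros(keep),
        "sd_b": np.zeros(keep),
        "sd_s": np.zeros(keep),
    }

    fixed = X @ (gamma * beta)
    for it in range(spec.n_iter):
        # intercept
        resid = y - fixed - b[spec.basin] - s[spec.site]
        prec = n / sigma2 + 1e-4
        beta0 = rng.normal((resid.sum() / sigma2) / prec, math.sqrt(1 / prec))

        # per-variable inclusion + effect (beta integrated out for gamma)
        r = y - beta0 - fixed - b[spec.basin] - s[spec.site]
        for j in range(p):
            if gamma[j]:
                r += X[:, j] * beta[j]
            a = xtx[j] / sigma2 + 1.0 / v_slab
            m = (X[:, j] @ r) / sigma2
            log_odds = logit_prior + 0.5 * (m * m / a) - 0.5 * math.log(v_slab * a)
            gamma[j] = rng.random() < 1.0 / (1.0 + math.exp(-log_odds))
            if gamma[j]:
                beta[j] = rng.normal(m / a, math.sqrt(1 / a))
                r -= X[:, j] * beta[j]
            else:
                beta[j] = 0.0
        fixed = X @ (gamma * beta)

        # slab variance from the currently included effects
        k_in = int(gamma.sum())
        ssb = float(np.sum(beta[gamma] ** 2))
        v_slab = 1.0 / rng.gamma(slab_a + k_in / 2, 1.0 / (slab_b + ssb / 2))

        # basin and site intercepts (conjugate given scales)
        resid = y - beta0 - fixed - s[spec.site]
        for g in range(n_basin):
            mask = spec.basin == g
            k = int(mask.sum())
            prec = k / sigma2 + 1.0 / sd_b**2
            b[g] = rng.normal((resid[mask].sum() / sigma2) / prec, math.sqrt(1 / prec))
        resid = y - beta0 - fixed - b[spec.basin]
        for g in range(n_site):
            mask = spec.site == g
            k = int(mask.sum())
            prec = k / sigma2 + 1.0 / sd_s**2
            s[g] = rng.normal((resid[mask].sum() / sigma2) / prec, math.sqrt(1 / prec))

        # scales (half-normal(1) priors) and residual variance
        sd_b = _slice_sample_scale(sd_b, float(np.sum(b**2)), n_basin, rng)
        sd_s = _slice_sample_scale(sd_s, float(np.sum(s**2)), n_site, rng)
        eps = y - beta0 - fixed - b[spec.basin] - s[spec.site]
        sigma2 = 1.0 / rng.gamma(0.001 + n / 2, 1.0 / (0.001 + float(eps @ eps) / 2))

        if it >= spec.burn_in:
            t = it - spec.burn_in
            out["gamma"][t] = gamma
            out["gb"][t] = gamma * beta
            out["beta0"][t] = beta0
            out["sigma2"][t] = sigma2
            out["sd_b"][t] = sd_b
            out["sd_s"][t] = sd_s
    return out


def _split_rhat(chains: list[np.ndarray]) -> float:
    """Split-chain potential scale reduction factor."""
    halves = []
    for c in chains:
        h = len(c) // 2
        halves.extend([c[:h], c[h:2 * h]])
    m = len(halves)
    n = len(halves[0])
    means = np.array([h.mean() for h in halves])
    variances = np.array([h.var(ddof=1) for h in halves])
    W = variances.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def _ess(chains: list[np.ndarray]) -> float:
    """Crude effective sample size from lag-autocorrelation (per chain, summed)."""
    total = 0.0
    for c in chains:
        n = len(c)
        c = c - c.mean()
        var = c @ c / n
        if var == 0:
            total += n
            continue
        rho_sum = 0.0
        for lag in range(1, min(n // 2, 200)):
            rho = (c[:-lag] @ c[lag:]) / ((n - lag) * var)
            if rho < 0.05:
                break
            rho_sum += rho
        total += n / (1 + 2 * rho_sum)
    return total


def fit_hl_model(spec: HLModelSpec) -> HLModelFit:
    """Posterior for the spike-and-slab hierarchical homozygosity model.

    Runs `spec.n_chains` Gibbs chains; a fit whose split-chain R-hat on
    the residual variance or any model-averaged effect exceeds 1.1 is
    returned with ``converged=False`` rather than raised.
    """
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_chains)
    chains = [_run_chain(spec, int(s.generate_state(1)[0] % 2**31)) for s in seeds]

    def stack(key: str) -> np.ndarray:
        return np.concatenate([c[key] for c in chains], axis=0)

    gamma = stack("gamma")
    gb = stack("gb")
    sigma2 = stack("sigma2")
    p = gb.shape[1]

    rhat = {"sigma2": _split_rhat([c["sigma2"] for c in chains])}
    ess = {"sigma2": _ess([c["sigma2"] for c in chains])}
    for j, name in enumerate(spec.variable_names):
        rhat[name] = _split_rhat([c["gb"][:, j] for c in chains])
        ess[name] = _ess([c["gb"][:, j] for c in chains])
    converged = all(v <= 1.1 for v in rhat.values())

    ci = np.quantile(gb, [0.025, 0.975], axis=0).T
    var_y = float(spec.y.var())
    return HLModelFit(
        variable_names=list(spec.variable_names),
        inclusion_prob=gamma.mean(axis=0),
        effect_mean=gb.mean(axis=0),
        effect_sd=gb.std(axis=0),
        effect_ci=ci,
        intercept=float(stack("beta0").mean()),
        sigma2_mean=float(sigma2.mean()),
        basin_sd_mean=float(stack("sd_b").mean()),
        site_sd_mean=float(stack("sd_s").mean()),
        r_squared=1.0 - float(sigma2.mean()) / var_y if var_y > 0 else math.nan,
        rhat=rhat,
        ess=ess,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Cluster-fold cross-validation
# ---------------------------------------------------------------------------

def _assign_folds(
    cluster_of: np.ndarray, n_folds: int
) -> list[np.ndarray]:
    """Whole clusters into folds, greedily balancing individual counts."""
    clusters, counts = np.unique(cluster_of, return_counts=True)
    if len(clusters) < n_folds:
        raise ValueError(f"{len(clusters)} clusters cannot fill {n_folds} folds")
    order = np.argsort(-counts)
    fold_of_cluster: dict = {}
    load = np.zeros(n_folds, dtype=int)
    for idx in order:
        f = int(np.argmin(load))
        fold_of_cluster[clusters[idx]] = f
        load[f] += counts[idx]
    return [
        np.where(np.isin(cluster_of, [c for c, f in fold_of_cluster.items() if f == k]))[0]
        for k in range(n_folds)
    ]


def cross_validate(
    spec: HLModelSpec,
    cluster_of: np.ndarray,
    n_folds: int = 5,
) -> tuple[float, list[np.ndarray]]:
    """Cluster-fold cross-validated r² of the fixed-effect predictions.

    Folds are unions of whole clusters (clusters are never split), sized
    toward equal individual counts. Test predictions use the intercept
    plus posterior-model-averaged effects (E[γβ]) only — no clustering
    intercepts — and predictions are clipped to [0, 1]. cv r² = 1 −
    SSE/SST pooled over folds around the grand mean; it may be negative.
    Returns ``(cv_r2, fold_index_arrays)``.
    """
    cluster_of = np.asarray(cluster_of)
    if cluster_of.shape != spec.y.shape:
        raise ValueError("one cluster label per individual required")
    folds = _assign_folds(cluster_of, n_folds)
    sse = 0.0
    for k, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(len(spec.y)), test_idx)
        sub = HLModelSpec(
            y=spec.y[train],
            X=spec.X[train],
            variable_names=spec.variable_names,
            basin=pd.factorize(spec.basin[train])[0],
            site=pd.factorize(spec.site[train])[0],
            prior_inclusion=spec.prior_inclusion,
            slab_a=spec.slab_a,
            slab_b_scale=spec.slab_b_scale,
            n_iter=spec.n_iter,
            burn_in=spec.burn_in,
            n_chains=1,
            seed=spec.seed + 1000 + k,
        )
        fit = fit_hl_model(sub)
        pred = np.clip(fit.intercept + spec.X[test_idx] @ fit.effect_mean, 0.0, 1.0)
        sse += float(np.sum((spec.y[test_idx] - pred) ** 2))
    sst = float(np.sum((spec.y - spec.y.mean()) ** 2))
    return 1.0 - sse / sst, folds


def effect_direction(fit: HLModelFit, prob_threshold: float = 0.7) -> list[str]:
    """positive/negative for strongly included variables, else neutral."""
    labels = []
    for prob, eff in zip(fit.inclusion_prob, fit.effect_mean):
        if prob > prob_threshold:
            labels.append("positive" if eff > 0 else "negative")
        else:
            labels.append("neutral")
    return labels
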