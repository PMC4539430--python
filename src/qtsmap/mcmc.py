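"""Stage 2b: full-model effect estimation by MCMC.

All terms declared significant by the scan are assembled into one
hierarchical linear model — fixed additive (``a``) and epistatic (``aa``)
effects with vague normal priors, random environment (``e``),
additive-by-environment (``ae``) and epistasis-by-environment (``aae``)
effects with inverse-gamma variance priors, plus the residual — and the
joint posterior is explored with a Gibbs sampler. Every effect is estimated
by its posterior mean, tested with a t statistic (mean over posterior SD,
df = effective sample size - 1) and reported with -log10 P and the
heritability it explains on the realized design.

Identifiability: a random interaction vector with a nonzero mean is
confounded with its main effect, so each draw is re-expressed in the
sum-to-zero convention (the mean of ``ae``/``aae`` across environments is
folded into ``a``/``aa``, the mean of ``e`` into the intercept) before
summaries are accumulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._data import as_genotype_matrix, as_phenotype_table
from .core import (
    AdditiveTerm,
    EpistaticTerm,
    GenotypeMatrix,
    QTSEffectSet,
    partition_heritability,
)
from .mlm import ScanResult

logger = logging.getLogger(__name__)

__all__ = [
    "FullModelSpec",
    "ChainConfig",
    "PosteriorSummary",
    "build_full_model",
    "run_mcmc",
    "summarize_architecture",
    "FullModelMcmc",
]


@dataclass
class FullModelSpec:
    """Terms of the full model: additive markers and epistatic pairs."""

    additive: list[str] = field(default_factory=list)
    epistatic: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.additive)) != len(self.additive):
            raise ValueError("duplicate additive terms")
        pairs = [tuple(sorted(p)) for p in self.epistatic]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate epistatic pairs")
        self.epistatic = pairs

    @property
    def is_empty(self) -> bool:
        return not self.additive and not self.epistatic


@dataclass
class ChainConfig:
    """Gibbs chain length: total iterations, burn-in, thinning stride."""

    iterations: int = 12000
    burnin: int = 2000
    thin: int = 2
    ess_warn: float = 100.0

    def __post_init__(self):
        if not 0 <= self.burnin < self.iterations:
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thinning stride must be >= 1")


def build_full_model(
    scan: ScanResult, G: GenotypeMatrix | None = None, prune_window_cm: float = 30.0
) -> FullModelSpec:
    """Assemble the full model from a scan's significant terms.

    Significant 1D markers enter as additive terms and significant 2D pairs
    as epistatic terms; each pair's members also receive additive terms (the
    model is hierarchical). When ``G`` is given, clusters of significant
    terms within ``prune_window_cm`` on one chromosome are pruned to their
    local F-peak so the model does not carry near-collinear copies of the
    same signal. An empty scan yields an intercept + environment model with
    a logged notice.
    """
    t = scan.table
    sig1 = t[(t["family"] == "1d") & t["significant"]].copy()
    sig2 = t[(t["family"] == "2d") & t["significant"]].copy()

    def pos(m):
        j = G.marker_index(m)
        row = G.markers.iloc[j]
        return str(row["chrom"]), float(row["pos_cm"])

    additive: list[str] = []
    for _, row in sig1.sort_values("F", ascending=False).iterrows():
        m = row["markers"]
        if G is not None and prune_window_cm is not None:
            c, x = pos(m)
            if any(
                c == pos(m2)[0] and abs(x - pos(m2)[1]) <= prune_window_cm for m2 in additive
            ):
                continue
        additive.append(m)

    pairs: list[tuple[str, str]] = []
    for _, row in sig2.sort_values("F", ascending=False).iterrows():
        i, j = row["markers"].split(":")
        if G is not None and prune_window_cm is not None:

            def near(a, b):
                ca, xa = pos(a)
                cb, xb = pos(b)
                return ca == cb and abs(xa - xb) <= prune_window_cm

            if any(
                (near(i, pi) and near(j, pj)) or (near(i, pj) and near(j, pi))
                for pi, pj in pairs
            ):
                continue
        pairs.append(tuple(sorted((i, j))))

    for i, j in pairs:
        for m in (i, j):
            if m not in additive:
                additive.append(m)
    model = FullModelSpec(additive=sorted(additive), epistatic=pairs)
    if model.is_empty:
        logger.info("no significant terms; full model reduces to intercept + environment")
    return model


@dataclass
class PosteriorSummary:
    """Posterior means, tests and heritabilities for every model effect."""

    effects: pd.DataFrame
    total_h2_pct: float
    mu: float
    sigma2_eps: float
    env_effects: np.ndarray
    min_ess: float
    converged: bool
    n_draws: int

    def write(self, path) -> None:
        self.effects.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _ess(draws: np.ndarray) -> float:
    import arviz as az

    if np.allclose(draws, draws[0]):
        return float(len(draws))
    return float(az.ess(draws[None, :]))


def run_mcmc(
    model: FullModelSpec,
    G,
    y,
    chain_config: ChainConfig | None = None,
    seed=0,
    prior_a: float = 0.01,
    prior_b: float = 0.01,
) -> PosteriorSummary:
    """Gibbs-sample the full model and summarize every effect's posterior.

    Fixed effects (intercept, ``a``, ``aa``) are sampled from their joint
    normal conditional (flat prior, tiny ridge for numerical safety); each
    random group (``e``, per-term ``ae``, per-pair ``aae``) carries its own
    variance component with an InverseGamma(``prior_a``, ``prior_b``) prior;
    the residual variance has the same prior. Effects are summarized after
    re-expression in the sum-to-zero convention. If the smallest effective
    sample size falls below ``chain_config.ess_warn`` the summary is still
    returned with ``converged=False``.
    """
    cfg = chain_config or ChainConfig()
    G = as_genotype_matrix(G)
    y = as_phenotype_table(y, G)
    rng = np.random.default_rng(seed)
    vals = y.aligned_to(G.line_ids)
    keep = np.isfinite(vals).all(axis=1)
    if not keep.all():
        logger.warning("dropping %d line(s) with incomplete profiles", (~keep).sum())
    vals = vals[keep]
    n, H = vals.shape
    N = n * H
    yv = vals.T.reshape(-1)  # env-major

    def stack(v):
        return np.tile(v, H)

    cols = {m: G.values[keep, G.marker_index(m)] for m in model.additive}
    for i, j in model.epistatic:
        for m in (i, j):
            if m not in cols:
                cols[m] = G.values[keep, G.marker_index(m)]

    X_list = [np.ones(N)]
    fixed_names = [("mu", "", "")]
    for m in model.additive:
        X_list.append(stack(cols[m]))
        fixed_names.append(("a", m, ""))
    for i, j in model.epistatic:
        X_list.append(stack(cols[i] * cols[j]))
        fixed_names.append(("aa", f"{i}:{j}", ""))
    X = np.column_stack(X_list)
    p = X.shape[1]

    # random groups: env main effect, ae per additive marker, aae per pair
    groups = [("e", "", np.ones(n))]
    for m in model.additive:
        groups.append(("ae", m, cols[m]))
    for i, j in model.epistatic:
        groups.append(("aae", f"{i}:{j}", cols[i] * cols[j]))
    n_g = len(groups)
    # each group's H random columns have disjoint support (one env block each),
    # so the conditional update of a whole group is diagonal
    g_code = np.stack([v for (_, _, v) in groups])  # (n_g, n)
    g_ztz = np.sum(g_code * g_code, axis=1)  # (n_g,)

    XtX = X.T @ X + 1e-10 * np.eye(p)
    cXtX = np.linalg.cholesky(XtX)

    beta = np.linalg.solve(XtX, X.T @ yv)
    u = np.zeros((n_g, H))
    s2_g = np.full(n_g, max(np.var(yv) * 0.05, 1e-6))
    s2 = max(float(np.var(yv - X @ beta)), 1e-8)

    yv2 = vals.T.copy()  # (H, n) view of the stacked response
    fitted_u = np.zeros((H, n))
    n_keep = (cfg.iterations - cfg.burnin + cfg.thin - 1) // cfg.thin
    draws_beta = np.empty((n_keep, p))
    draws_u = np.empty((n_keep, n_g, H))
    draws_s2 = np.empty(n_keep)
    kidx = 0
    half = H / 2.0
    for it in range(cfg.iterations):
        # fixed effects from their joint normal conditional
        r = (yv2 - fitted_u).reshape(-1)
        mean = np.linalg.solve(XtX, X.T @ r)
        beta = mean + np.sqrt(s2) * np.linalg.solve(cXtX.T, rng.standard_normal(p))
        resid = (yv - X @ beta).reshape(H, n) - fitted_u
        # random groups, sequentially (diagonal conditional per group)
        for gi in range(n_g):
            v = g_code[gi]
            old = np.outer(u[gi], v)  # (H, n)
            resid += old
            zr = resid @ v  # (H,)
            prec = g_ztz[gi] / s2 + 1.0 / s2_g[gi]
            u[gi] = zr / s2 / prec + rng.standard_normal(H) / np.sqrt(prec)
            new = np.outer(u[gi], v)
            resid -= new
            fitted_u += new - old
            s2_g[gi] = 1.0 / rng.gamma(prior_a + half, 1.0 / (prior_b + 0.5 * (u[gi] @ u[gi])))
        s2 = 1.0 / rng.gamma(
            prior_a + N / 2.0, 1.0 / (prior_b + 0.5 * float(np.sum(resid * resid)))
        )
        if it >= cfg.burnin and (it - cfg.burnin) % cfg.thin == 0:
            # sum-to-zero re-expression: interaction means fold into main effects
            b = beta.copy()
            means = u.mean(axis=1)
            b[: n_g] += means  # e-bar -> mu, ae-bar -> a, aae-bar -> aa (same order)
            draws_beta[kidx] = b
            draws_u[kidx] = u - means[:, None]
            draws_s2[kidx] = s2
            kidx += 1
    draws_beta, draws_u, draws_s2 = draws_beta[:kidx], draws_u[:kidx], draws_s2[:kidx]

    # --- summaries
    rows = []
    ess_all = []

    def summarize(name, markers, env, draws):
        mean = float(np.mean(draws))
        sd = float(np.std(draws, ddof=1))
        ess = _ess(draws)
        ess_all.append(ess)
        if sd > 0:
            tstat = mean / sd
            pval = 2.0 * stats.t.sf(abs(tstat), df=max(ess - 1.0, 1.0))
        else:
            tstat, pval = np.inf, 0.0
        rows.append(
            {
                "effect": name,
                "markers": markers,
                "environment": env,
                "estimate": mean,
                "sd": sd,
                "t": tstat,
                "minus_log10_p": float(-np.log10(max(pval, 1e-300))),
                "ess": ess,
            }
        )

    for k, (kind, markers, _) in enumerate(fixed_names):
        if kind == "mu":
            continue
        summarize(kind, markers, "", draws_beta[:, k])
    for gi, (kind, markers, _) in enumerate(groups):
        if kind == "e":
            continue
        for h in range(H):
            summarize(f"{kind}_{h + 1}", markers, str(h + 1), draws_u[:, gi, h])

    effects = pd.DataFrame(
        rows,
        columns=["effect", "markers", "environment", "estimate", "sd", "t", "minus_log10_p", "ess"],
    )

    mu_hat = float(np.mean(draws_beta[:, 0]))
    s2_hat = float(np.mean(draws_s2))
    env_hat = np.mean(draws_u[:, 0, :], axis=0)

    # heritabilities from the posterior-mean effect set
    est_set = _effects_to_set(effects, mu_hat, env_hat, s2_hat, H)
    if est_set.additive or est_set.epistatic:
        report = partition_heritability(est_set, _subset(G, keep))
        key = report.components.set_index(["effect", "markers", "environment"])["h2_pct"]
        effects["h2_pct"] = [
            float(key.get((r["effect"], r["markers"], r["environment"]), np.nan))
            for _, r in effects.iterrows()
        ]
        total = float(report.total_h2_pct)
    else:
        effects["h2_pct"] = np.nan
        total = 0.0

    min_ess = float(min(ess_all)) if ess_all else float(kidx)
    converged = min_ess >= cfg.ess_warn
    if not converged:
        logger.warning("minimum effective sample size %.1f below %.1f", min_ess, cfg.ess_warn)
    return PosteriorSummary(
        effects=effects,
        total_h2_pct=total,
        mu=mu_hat,
        sigma2_eps=s2_hat,
        env_effects=env_hat,
        min_ess=min_ess,
        converged=converged,
        n_draws=kidx,
    )


def _subset(G: GenotypeMatrix, mask) -> GenotypeMatrix:
    return GenotypeMatrix(
        G.line_ids[mask], G.markers, G.values[mask], max_het_fraction=1.0, max_missing_fraction=1.0
    )


def _effects_to_set(effects: pd.DataFrame, mu, env, s2, H) -> QTSEffectSet:
    additive, epistatic = [], []
    for markers, sub in effects.groupby("markers", sort=False):
        kinds = set(sub["effect"])
        if "a" in kinds:
            ae = np.zeros(H)
            for h in range(H):
                row = sub[sub["effect"] == f"ae_{h + 1}"]
                if len(row):
                    ae[h] = float(row["estimate"].iloc[0])
            ae = ae - ae.mean()
            additive.append(
                AdditiveTerm(markers, float(sub[sub["effect"] == "a"]["estimate"].iloc[0]), ae)
            )
        if "aa" in kinds:
            i, j = markers.split(":")
            aae = np.zeros(H)
            for h in range(H):
                row = sub[sub["effect"] == f"aae_{h + 1}"]
                if len(row):
                    aae[h] = float(row["estimate"].iloc[0])
            aae = aae - aae.mean()
            epistatic.append(
                EpistaticTerm(
                    *sorted((i, j)), float(sub[sub["effect"] == "aa"]["estimate"].iloc[0]), aae
                )
            )
    return QTSEffectSet(
        mu=mu, additive=additive, epistatic=epistatic, env_effects=np.asarray(env) - np.mean(env),
        sigma2_eps=s2, n_env=H,
    )


def summarize_architecture(
    summary: PosteriorSummary, G: GenotypeMatrix | None = None, trait: str = "trait"
) -> pd.DataFrame:
    """Human-readable per-effect report (one trait per call).

    Columns: Trait, QTS, Chr, Allele, Effect, Estimate, -log10(P), h2 (%),
    Total h2 (%) on the first row. Alleles are looked up from the genotype
    matrix when provided.
    """
    rows = []
    eff = summary.effects
    order = {"a": 0, "ae": 1, "aa": 2, "aae": 3}

    def sort_key(r):
        base = r["effect"].split("_")[0]
        return (r["markers"], order.get(base, 9), r["environment"])

    for _, r in eff.assign(_k=[sort_key(r) for _, r in eff.iterrows()]).sort_values("_k").iterrows():
        markers = r["markers"]
        chrom = allele = ""
        if G is not None:
            ms = markers.split(":")
            chroms, alleles = [], []
            for m in ms:
                row = G.markers.iloc[G.marker_index(m)]
                chroms.append(str(row["chrom"]))
                alleles.append(f"{row['allele_high']}/{row['allele_low']}")
            chrom = ";".join(chroms)
            allele = ";".join(alleles)
        rows.append(
            {
                "Trait": trait,
                "QTS": markers.replace(":", " and "),
                "Chr": chrom,
                "Allele": allele,
                "Effect": r["effect"],
                "Estimate": r["estimate"],
                "minus_log10_P": r["minus_log10_p"],
                "h2_pct": r["h2_pct"],
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["Trait", "QTS", "Chr", "Allele", "Effect", "Estimate", "minus_log10_P", "h2_pct"],
    )
    out["Total_h2_pct"] = np.nan
    if len(out):
        out.loc[out.index[0], "Total_h2_pct"] = summary.total_h2_pct
    else:
        out = pd.DataFrame(
            [{c: np.nan for c in out.columns} | {"Trait": trait, "Total_h2_pct": summary.total_h2_pct}]
        )
    return out


class FullModelMcmc(BaseEstimator):
    """Full-model Gibbs estimation as a scikit-learn estimator.

    ``fit(X, y, model=...)`` accepts a :class:`FullModelSpec` or a
    :class:`~qtsmap.mlm.ScanResult` (from which the model is built) and
    stores the :class:`PosteriorSummary` in ``summary_``.
    """

    def __init__(
        self,
        iterations: int = 12000,
        burnin: int = 2000,
        thin: int = 2,
        prior_a: float = 0.01,
        prior_b: float = 0.01,
        prune_window_cm: float = 30.0,
        random_state: int = 0,
    ):
        self.iterations = iterations
        self.burnin = burnin
        self.thin = thin
        self.prior_a = prior_a
        self.prior_b = prior_b
        self.prune_window_cm = prune_window_cm
        self.random_state = random_state

    def fit(self, X, y, model=None):
        G = as_genotype_matrix(X)
        if model is None:
            raise ValueError("a FullModelSpec or ScanResult must be supplied via model=")
        if isinstance(model, ScanResult):
            model = build_full_model(model, G, self.prune_window_cm)
        self.model_ = model
        self.summary_ = run_mcmc(
            model,
            G,
            y,
            ChainConfig(self.iterations, self.burnin, self.thin),
            seed=self.random_state,
            prior_a=self.prior_a,
            prior_b=self.prior_b,
        )
        self.effects_ = self.summary_.effects
        self.n_features_in_ = G.n_markers
        return self
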