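"""Stage 2a: candidate scans with F-tests and permutation thresholds.

A quantitative trait SNP is "detected" when it has an effect in *some*
environment, so every test here is a joint partial F of a term's genetic
effect together with its environment interactions:

* 1D family — for each screened candidate marker i, the H-column block
  ``x_i * 1[env = h]`` (spanning ``a_i`` and ``ae_hi``) is added to a
  baseline of per-environment cofactor regressions (environment means plus
  every background cofactor crossed with environment, which absorbs the
  background QTSs' additive *and* additive-by-environment variance).
* 2D family — for each marker pair, the block ``x_i x_j * 1[env = h]``
  (spanning ``aa_ij`` and ``aae_hij``) over the same kind of baseline. With
  +/-1 RIL codes the pair product is orthogonal to both member codes, which
  has two consequences: additive cofactors never absorb epistatic signal,
  and the pair sweep reduces to Gram-matrix identities
  (``sum_k x_ik x_jk w_k = (X' diag(w) X)_ij``), so the 2D family is
  searched exhaustively over all marker pairs whenever the pair count fits a
  budget, falling back to the screened pair neighbourhoods otherwise.
  Near-constant products (tightly linked pairs) are excluded by a minimum
  product-variance filter.

Experiment-wise significance is calibrated by permutation: whole line
profiles (a line's values across every environment) are permuted jointly,
the maximum F over each scan family is recorded per permutation, and the
threshold is the ceil((B+1)(1-alpha))-th smallest of the B maxima; the 1D
and 2D families get separate thresholds.

Cofactor choice: the background pool is the screen's clumped region
representatives; candidates within ``cofactor_window_cm`` of a tested 1D
marker on the same chromosome are left out of that test's baseline so that
tightly linked co-screened neighbours do not absorb the tested marker's own
signal (the composite-interval-mapping convention).

A mixed-model fit of one term — additive effect fixed, environment and the
term's interactions as REML-estimated variance components, Wald F with
Satterthwaite df — is available as :func:`fit_term_model`. It is not used
for detection: with few environments the F for ``a`` against a random
``ae`` has noncentrality bounded by ``H a^2 / sigma2_ae`` regardless of
population size, which leaves even strong QTSs undetectable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from ._data import as_genotype_matrix, as_phenotype_table

logger = logging.getLogger(__name__)

__all__ = [
    "TermFit",
    "ScanResult",
    "fit_term_model",
    "permutation_threshold",
    "scan",
    "MixedModelScan",
]

#: variance-ratio grid for the REML term fit (gamma = component / residual)
GAMMA_GRID = (0.0, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)

#: exhaustive 2D search allowed up to this many pairs
DEFAULT_PAIR_BUDGET = 2e5

#: pairs whose centred product variance falls below this fraction of n are
#: excluded from the 2D family (near-constant products of linked markers)
MIN_PAIR_VARIANCE = 0.25


def _complete_lines(G, y):
    """Drop lines with any missing phenotype; scan designs must be balanced."""
    vals = y.aligned_to(G.line_ids)
    keep = np.isfinite(vals).all(axis=1)
    if not keep.all():
        logger.warning("dropping %d line(s) with incomplete phenotype profiles", (~keep).sum())
    return G.values[keep], vals[keep]


def _orth_basis(A: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Rank-revealing orthonormal basis of the column space of ``A``."""
    if A.size == 0:
        return np.empty((A.shape[0], 0))
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        return np.empty((A.shape[0], 0))
    r = int(np.sum(s > tol * s[0]))
    return U[:, :r]


def _normalize_candidates(candidates, pairs=None):
    """Split a CandidateSet (or plain marker list) into scan families.

    Returns (markers, pairs, cofactor_pool): the 1D terms, the screened 2D
    terms (used when the exhaustive sweep is out of budget) and the
    background cofactor pool.
    """
    if hasattr(candidates, "markers"):
        markers = list(candidates.markers)
        if pairs is None:
            pairs = [tuple(sorted(p)) for p in getattr(candidates, "pairs", []) or []]
        pool = list(getattr(candidates, "representatives", []) or markers)
        pair_pool = [tuple(p) for p in getattr(candidates, "pair_representatives", []) or []]
    else:
        markers = list(candidates)
        if pairs is None:
            pairs = [tuple(sorted(p)) for p in combinations(markers, 2)]
        pool = markers
        pair_pool = []
    pairs = [tuple(sorted(p)) for p in pairs]
    return markers, pairs, pool, pair_pool


def _cofactors_for(term, pool, G, window_cm):
    if window_cm is None:
        return [c for c in pool if c not in term]
    meta = G.markers.set_index("marker")
    out = []
    for c in pool:
        if c in term:
            continue
        keep = True
        for m in term:
            if meta.at[c, "chrom"] == meta.at[m, "chrom"] and abs(
                meta.at[c, "pos_cm"] - meta.at[m, "pos_cm"]
            ) <= window_cm:
                keep = False
                break
        if keep:
            out.append(c)
    return out


class _ScanEngine:
    """Shared projection machinery for the observed scan and its permutations.

    All statistics are per-environment partial F tests. Because cofactor
    codes are line-level constants, the projection matrix of a baseline is
    the same in every environment, so a baseline is represented by one
    orthonormal basis ``U`` of ``[1, cofactors]`` over lines.
    """

    def __init__(
        self,
        G,
        Xg: np.ndarray,
        vals: np.ndarray,
        markers: list[str],
        pairs: list[tuple[str, str]],
        pool: list[str],
        pair_pool: list[tuple[str, str]],
        cofactor_window_cm: float | None,
        pair_search: str = "auto",
        pair_budget: float = DEFAULT_PAIR_BUDGET,
        min_pair_variance: float = MIN_PAIR_VARIANCE,
    ):
        self.G = G
        self.Xg = Xg
        self.n, self.H = vals.shape
        self.cols = {m: j for j, m in enumerate(G.marker_ids)}
        self.markers = [m for m in markers if np.nanvar(Xg[:, self.cols[m]]) > 0]
        self.pool = pool
        self.pair_pool = pair_pool
        self.min_pair_variance = min_pair_variance
        # background epistasis control: products of screened pair regions
        # (orthogonal to every single-marker code, so safe in all 1D baselines)
        prod_cols = [
            Xg[:, self.cols[i]] * Xg[:, self.cols[j]]
            for i, j in pair_pool
            if i in self.cols and j in self.cols
        ]

        # ---- 1D groups: candidates sharing one cofactor signature
        groups: dict[tuple, list[str]] = {}
        for m in self.markers:
            cof = tuple(_cofactors_for((m,), pool, G, cofactor_window_cm))
            groups.setdefault(cof, []).append(m)
        self.groups_1d = []
        for cof, members in groups.items():
            base = np.column_stack(
                [np.ones(self.n)] + [Xg[:, self.cols[c]] for c in cof] + prod_cols
            )
            U = _orth_basis(base)
            Xm = np.column_stack([Xg[:, self.cols[m]] for m in members])
            Xt = Xm - U @ (U.T @ Xm)
            den = np.einsum("nk,nk->k", Xt, Xt)
            ok = den > 1e-8 * self.n
            self.groups_1d.append(
                {
                    "members": [m for m, o in zip(members, ok) if o],
                    "U": U,
                    "Xt": Xt[:, ok],
                    "den": den[ok],
                    "df2": self.H * (self.n - U.shape[1] - 1),
                }
            )

        # ---- 2D family
        p = G.n_markers
        if pair_search == "auto":
            pair_search = "exhaustive" if math.comb(p, 2) <= pair_budget else "screened"
        self.pair_search = pair_search
        base_all = np.column_stack(
            [np.ones(self.n)] + [Xg[:, self.cols[c]] for c in pool]
        )
        self.U_all = _orth_basis(base_all)
        self.df2_2d = self.H * (self.n - self.U_all.shape[1] - 1)
        if pair_search == "exhaustive":
            # den_ij = || M (x_i * x_j) ||^2 from Gram identities
            X = Xg
            if not np.isin(X, (-1.0, 1.0)).all():
                raise ValueError(
                    "exhaustive pair search requires fully homozygous +/-1 codes; "
                    "use pair_search='screened'"
                )
            cc = X.T @ X * 0.0 + float(self.n)  # c'c = n for +/-1 codes
            proj = np.zeros((p, p))
            for el in range(self.U_all.shape[1]):
                Gl = X.T @ (self.U_all[:, el : el + 1] * X)
                proj += Gl * Gl
            self.pair_den = cc - proj
            iu = np.triu_indices(p, k=1)
            valid = self.pair_den[iu] > min_pair_variance * self.n
            self.pair_iu = (iu[0][valid], iu[1][valid])
            self.screened_pairs = None
        else:
            self.screened_pairs = []
            for i, j in pairs:
                ci, cj = self.cols[i], self.cols[j]
                c = Xg[:, ci] * Xg[:, cj]
                ct = c - self.U_all @ (self.U_all.T @ c)
                den = float(ct @ ct)
                if den > min_pair_variance * self.n:
                    self.screened_pairs.append(((i, j), ct, den))

    # -- helpers ---------------------------------------------------------

    def _project_y(self, Yw: np.ndarray, U: np.ndarray) -> np.ndarray:
        """Residualize (n, H, B) phenotypes against a line-level basis."""
        n, H, B = Yw.shape
        flat = Yw.reshape(n, H * B)
        out = flat - U @ (U.T @ flat)
        return out.reshape(n, H, B)

    def f_1d(self, Yw: np.ndarray):
        """Joint (a, ae) partial F for every 1D candidate.

        ``Yw`` has shape (n, H, B); returns (term list, F array (terms, B)).
        """
        terms, fs = [], []
        for g in self.groups_1d:
            if not g["members"]:
                continue
            Yt = self._project_y(Yw, g["U"])
            S = np.einsum("nhb,nhb->b", Yt, Yt)
            num = np.einsum("nk,nhb->khb", g["Xt"], Yt)
            extra = np.einsum("khb->kb", num**2 / g["den"][:, None, None])
            df2 = g["df2"]
            with np.errstate(invalid="ignore", divide="ignore"):
                F = (extra / self.H) / ((S[None, :] - extra) / df2)
            terms.extend(g["members"])
            fs.append(F)
        if not terms:
            return [], np.empty((0, Yw.shape[2]))
        return terms, np.vstack(fs)

    def _pair_extra_exhaustive(self, Yt: np.ndarray) -> np.ndarray:
        """Extra SS of every pair for one projected phenotype (n, H)."""
        X = self.Xg
        num2 = np.zeros_like(self.pair_den)
        for h in range(Yt.shape[1]):
            Gh = X.T @ (Yt[:, h : h + 1] * X)
            num2 += Gh * Gh
        with np.errstate(invalid="ignore", divide="ignore"):
            return num2 / self.pair_den

    def f_2d_max(self, Yw: np.ndarray) -> np.ndarray:
        """Max pair F per phenotype column (permutation maxima)."""
        B = Yw.shape[2]
        Yt = self._project_y(Yw, self.U_all)
        S = np.einsum("nhb,nhb->b", Yt, Yt)
        out = np.full(B, -np.inf)
        if self.pair_search == "exhaustive":
            if len(self.pair_iu[0]) == 0:
                return out
            for b in range(B):
                extra = self._pair_extra_exhaustive(Yt[:, :, b])[self.pair_iu]
                emax = float(np.nanmax(extra))
                out[b] = (emax / self.H) / ((S[b] - emax) / self.df2_2d)
        else:
            if not self.screened_pairs:
                return out
            for (_, ct, den) in self.screened_pairs:
                num = np.einsum("n,nhb->hb", ct, Yt)
                extra = np.sum(num**2, axis=0) / den
                with np.errstate(invalid="ignore", divide="ignore"):
                    F = (extra / self.H) / ((S - extra) / self.df2_2d)
                out = np.fmax(out, F)
        return out

    def f_2d_observed(self, Yw: np.ndarray):
        """Pair F values for the observed phenotype (B = 1).

        Returns (pairs list, F array); in exhaustive mode the full pair
        matrix is computed and returned sparsely via the valid-pair index.
        """
        Yt = self._project_y(Yw, self.U_all)
        S = float(np.einsum("nhb,nhb->", Yt, Yt))
        marker_ids = self.G.marker_ids
        if self.pair_search == "exhaustive":
            extra = self._pair_extra_exhaustive(Yt[:, :, 0])[self.pair_iu]
            with np.errstate(invalid="ignore", divide="ignore"):
                F = (extra / self.H) / ((S - extra) / self.df2_2d)
            pairs = [
                tuple(sorted((marker_ids[i], marker_ids[j])))
                for i, j in zip(*self.pair_iu)
            ]
            return pairs, F
        pairs, fs = [], []
        for (pair, ct, den) in self.screened_pairs:
            num = np.einsum("n,nhb->hb", ct, Yt)
            extra = float(np.sum(num**2) / den)
            with np.errstate(invalid="ignore", divide="ignore"):
                fs.append((extra / self.H) / ((S - extra) / self.df2_2d))
            pairs.append(tuple(sorted(pair)))
        return pairs, np.asarray(fs)


def _make_engine(G, y, candidates, pairs, cofactor_window_cm, pair_search, pair_budget):
    G = as_genotype_matrix(G)
    y = as_phenotype_table(y, G)
    markers, spairs, pool, pair_pool = _normalize_candidates(candidates, pairs)
    if not markers:
        raise ValueError("candidate set is empty")
    Xg, vals = _complete_lines(G, y)
    engine = _ScanEngine(
        G,
        Xg,
        vals,
        markers,
        spairs,
        pool,
        pair_pool,
        cofactor_window_cm,
        pair_search=pair_search,
        pair_budget=pair_budget,
    )
    return engine, vals


def permutation_threshold(
    G,
    y,
    candidates,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed=0,
    cofactor_window_cm: float | None = 30.0,
    families=("1d", "2d"),
    pair_search: str = "auto",
    pair_budget: float = DEFAULT_PAIR_BUDGET,
) -> dict[str, float]:
    """Experiment-wise F thresholds by the max-statistic permutation method.

    Whole line profiles are permuted across lines (a line keeps its
    multi-environment phenotype vector), the scan's maximum F is recorded
    per permutation and family, and the threshold is the
    ceil((B+1)(1-alpha))-th smallest of the B maxima. The 1D and 2D families
    get separate thresholds.
    """
    if n_permutations < 19:
        raise ValueError("at least 19 permutations are required")
    engine, vals = _make_engine(
        G, y, candidates, None, cofactor_window_cm, pair_search, pair_budget
    )
    rng = np.random.default_rng(seed)
    n, H = vals.shape
    B = n_permutations
    perms = np.array([rng.permutation(n) for _ in range(B)])
    Yw = np.transpose(vals[perms], (1, 2, 0))  # (n, H, B)
    k = int(np.ceil((B + 1) * (1 - alpha)))
    out = {}
    for family in families:
        if family == "1d":
            _, F = engine.f_1d(Yw)
            maxima = np.nanmax(F, axis=0) if F.size else np.full(B, -np.inf)
        else:
            maxima = engine.f_2d_max(Yw)
        finite = np.isfinite(maxima)
        if not finite.all():
            logger.warning(
                "family %s: %d permutation(s) without a finite maximum", family, (~finite).sum()
            )
        out[family] = float(np.sort(maxima)[k - 1]) if finite.any() else np.inf
    return out


@dataclass
class ScanResult:
    """Per-term F statistics, thresholds and significance flags."""

    table: pd.DataFrame
    thresholds: dict[str, float]
    candidates: list[str]
    cofactor_window_cm: float | None = None

    def significant_markers(self) -> list[str]:
        t = self.table
        sel = t[(t["family"] == "1d") & t["significant"]]
        return [m for m in sel["markers"]]

    def significant_pairs(self) -> list[tuple[str, str]]:
        t = self.table
        sel = t[(t["family"] == "2d") & t["significant"]]
        return [tuple(m.split(":")) for m in sel["markers"]]

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def scan(
    G,
    y,
    candidates,
    n_permutations: int = 200,
    alpha: float = 0.05,
    seed=0,
    cofactor_window_cm: float | None = 30.0,
    thresholds: dict[str, float] | None = None,
    compute_pvalues: bool = True,
    pairs: list[tuple[str, str]] | None = None,
    pair_search: str = "auto",
    pair_budget: float = DEFAULT_PAIR_BUDGET,
    keep_2d: int = 200,
) -> ScanResult:
    """1D scan over screened candidates and 2D scan over marker pairs.

    Every candidate marker is tested for its additive effect jointly with
    its environment interactions; every marker pair (exhaustively when the
    panel allows, else the screened pair neighbourhoods) for its epistatic
    effect jointly with its environment interactions. Significance is
    declared against permutation thresholds (computed here with
    ``n_permutations`` unless precomputed ``thresholds`` are supplied). The
    result table keeps all 1D terms, every significant pair and the
    ``keep_2d`` strongest non-significant pairs.
    """
    engine, vals = _make_engine(
        G, y, candidates, pairs, cofactor_window_cm, pair_search, pair_budget
    )
    if thresholds is None:
        thresholds = permutation_threshold(
            G,
            y,
            candidates,
            n_permutations=n_permutations,
            alpha=alpha,
            seed=seed,
            cofactor_window_cm=cofactor_window_cm,
            pair_search=pair_search,
            pair_budget=pair_budget,
        )
    Yw = vals[:, :, None]
    rows = []
    thr1 = thresholds.get("1d", np.inf)
    terms, F1 = engine.f_1d(Yw)
    for m, F in zip(terms, F1[:, 0]):
        g = next(g for g in engine.groups_1d if m in g["members"])
        p = float(stats.f.sf(F, engine.H, g["df2"])) if compute_pvalues else np.nan
        rows.append(
            {
                "family": "1d",
                "markers": m,
                "F": float(F),
                "df1": engine.H,
                "df2": g["df2"],
                "p": p,
                "threshold": thr1,
                "significant": bool(np.isfinite(F) and F >= thr1),
            }
        )
    skipped = set(engine.markers) ^ set(terms)
    for m in skipped:
        logger.warning("1D term %s skipped (degenerate after projection)", m)
        rows.append(
            {
                "family": "1d",
                "markers": m,
                "F": np.nan,
                "df1": np.nan,
                "df2": np.nan,
                "p": np.nan,
                "threshold": thr1,
                "significant": False,
            }
        )
    thr2 = thresholds.get("2d", np.inf)
    pair_terms, F2 = engine.f_2d_observed(Yw)
    if len(pair_terms):
        F2 = np.asarray(F2)
        sig = np.isfinite(F2) & (F2 >= thr2)
        keep = set(np.flatnonzero(sig))
        rest = np.argsort(-np.where(np.isfinite(F2), F2, -np.inf))
        for idx in rest:
            if len(keep) >= sig.sum() + keep_2d:
                break
            keep.add(int(idx))
        for idx in sorted(keep):
            F = F2[idx]
            pv = float(stats.f.sf(F, engine.H, engine.df2_2d)) if compute_pvalues else np.nan
            rows.append(
                {
                    "family": "2d",
                    "markers": ":".join(pair_terms[idx]),
                    "F": float(F),
                    "df1": engine.H,
                    "df2": engine.df2_2d,
                    "p": pv,
                    "threshold": thr2,
                    "significant": bool(sig[idx]),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["family", "markers", "F", "df1", "df2", "p", "threshold", "significant"],
    )
    return ScanResult(
        table=table,
        thresholds=dict(thresholds),
        candidates=engine.markers,
        cofactor_window_cm=cofactor_window_cm,
    )


class MixedModelScan(BaseEstimator):
    """Candidate scan with permutation thresholds as a scikit-learn estimator.

    ``fit(X, y, candidates=...)`` runs the 1D and 2D scans and stores the
    results in ``results_`` (a :class:`ScanResult`); ``thresholds_`` holds
    the permutation thresholds actually used.
    """

    def __init__(
        self,
        n_permutations: int = 200,
        alpha: float = 0.05,
        cofactor_window_cm: float | None = 30.0,
        compute_pvalues: bool = True,
        pair_search: str = "auto",
        random_state: int = 0,
    ):
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.cofactor_window_cm = cofactor_window_cm
        self.compute_pvalues = compute_pvalues
        self.pair_search = pair_search
        self.random_state = random_state

    def fit(self, X, y, candidates=None, thresholds=None):
        G = as_genotype_matrix(X)
        if candidates is None:
            candidates = list(G.marker_ids)
        self.results_ = scan(
            G,
            y,
            candidates,
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            seed=self.random_state,
            cofactor_window_cm=self.cofactor_window_cm,
            thresholds=thresholds,
            compute_pvalues=self.compute_pvalues,
            pair_search=self.pair_search,
        )
        self.thresholds_ = self.results_.thresholds
        self.n_features_in_ = G.n_markers
        return self


# ---------------------------------------------------------------------------
# single-term mixed-model fit (REML)


@dataclass
class _TermDesign:
    """Stacked design for one tested term over complete line profiles."""

    X: np.ndarray  # (N, p) fixed effects
    Z: np.ndarray  # (N, q) random-effect columns (may be empty)
    gidx: np.ndarray  # variance-group index per Z column
    n_groups: int
    test_col: int  # column of X holding the tested effect
    fixed_names: list[str]


def _build_design(Xg, cols, term, cofactors, H) -> _TermDesign:
    """Assemble the stacked fixed/random design for a marker or pair term."""
    n = Xg.shape[0]
    N = n * H

    def stack(v):
        return np.tile(v, H)

    fixed = [np.ones(N)]
    names = ["mu"]
    for c in cofactors:
        fixed.append(stack(Xg[:, cols[c]]))
        names.append(f"a[{c}]")
    if len(term) == 1:
        x = Xg[:, cols[term[0]]]
        fixed.append(stack(x))
        names.append(f"a[{term[0]}]")
        test_col = len(fixed) - 1
        rand_covs = [("env", np.ones(n)), ("ae", x)]
    else:
        xi = Xg[:, cols[term[0]]]
        xj = Xg[:, cols[term[1]]]
        fixed.extend([stack(xi), stack(xj), stack(xi * xj)])
        names.extend([f"a[{term[0]}]", f"a[{term[1]}]", f"aa[{term[0]}:{term[1]}]"])
        test_col = len(fixed) - 1
        rand_covs = [("env", np.ones(n)), ("ae", xi), ("ae", xj), ("aae", xi * xj)]
    X = np.column_stack(fixed)

    if H < 2:
        return _TermDesign(X, np.empty((N, 0)), np.empty(0, dtype=int), 0, test_col, names)
    group_names: list[str] = []
    Zs, gidx = [], []
    for gname, v in rand_covs:
        if gname not in group_names:
            group_names.append(gname)
        g = group_names.index(gname)
        for h in range(H):
            col = np.zeros(N)
            col[h * n : (h + 1) * n] = v
            Zs.append(col)
            gidx.append(g)
    Z = np.column_stack(Zs)
    return _TermDesign(X, Z, np.array(gidx), len(group_names), test_col, names)


class _RemlWorkspace:
    """Sufficient statistics for profiled REML over one design.

    The residual variance is profiled out; the criterion as a function of
    the variance ratios ``gamma`` (one per group) is

        crit = log|M| + log|X' V0^-1 X| + (N - p) log(y' P y)

    with ``V0 = I + Z diag(gamma) Z'`` handled through the Woodbury
    identity, ``M = I_q + G^{1/2} Z'Z G^{1/2}``. Evaluations are batched
    over a grid of gamma vectors.
    """

    def __init__(self, design: _TermDesign, Y: np.ndarray):
        X, Z = design.X, design.Z
        self.design = design
        self.N, self.p = X.shape
        self.q = Z.shape[1]
        self.Y = Y
        self.XtX = X.T @ X
        self.XtY = X.T @ Y
        self.yty = np.sum(Y * Y, axis=0)
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.ZtY = Z.T @ Y

    def _pieces(self, gamma_vectors: np.ndarray):
        G = gamma_vectors[:, self.design.gidx] if self.q else np.zeros((len(gamma_vectors), 0))
        ngrid = len(gamma_vectors)
        p, B = self.p, self.Y.shape[1]
        if self.q:
            sq = np.sqrt(G)
            M = np.eye(self.q) + sq[:, :, None] * self.ZtZ[None] * sq[:, None, :]
            sZtX = sq[:, :, None] * self.ZtX[None]
            sZtY = sq[:, :, None] * self.ZtY[None]
            WX = np.linalg.solve(M, sZtX)
            WY = np.linalg.solve(M, sZtY)
            XtVX = self.XtX[None] - np.einsum("gqp,gqr->gpr", sZtX, WX)
            XtVY = self.XtY[None] - np.einsum("gqp,gqb->gpb", sZtX, WY)
            yVy = self.yty[None] - np.einsum("gqb,gqb->gb", sZtY, WY)
            _, logdetM = np.linalg.slogdet(M)
        else:
            XtVX = np.broadcast_to(self.XtX, (ngrid, p, p)).copy()
            XtVY = np.broadcast_to(self.XtY, (ngrid, p, B)).copy()
            yVy = np.broadcast_to(self.yty, (ngrid, B)).copy()
            logdetM = np.zeros(ngrid)
        return XtVX, XtVY, yVy, logdetM

    def criterion(self, gamma_vectors: np.ndarray):
        """Profiled REML criterion, shape (ngrid, B); +inf where singular."""
        XtVX, XtVY, yVy, logdetM = self._pieces(np.atleast_2d(gamma_vectors))
        ngrid, B = yVy.shape
        crit = np.full((ngrid, B), np.inf)
        sign, logdetC = np.linalg.slogdet(XtVX)
        ok = sign > 0
        if not ok.any():
            return crit
        beta = np.full_like(XtVY, np.nan)
        beta[ok] = np.linalg.solve(XtVX[ok], XtVY[ok])
        quad = yVy - np.einsum("gpb,gpb->gb", XtVY, beta)
        good = ok[:, None] & (quad > 0)
        crit[good] = ((logdetM + logdetC)[:, None] + (self.N - self.p) * np.log(quad))[good]
        return crit

    def fit(self, gamma: np.ndarray, y_col: int = 0):
        """Point fit at one gamma vector: beta, covariance, sigma2."""
        XtVX, XtVY, yVy, _ = self._pieces(np.atleast_2d(gamma))
        XtVX, XtVY, yVy = XtVX[0], XtVY[0, :, y_col], yVy[0, y_col]
        try:
            np.linalg.cholesky(XtVX)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError("singular fixed-effect design") from None
        beta = np.linalg.solve(XtVX, XtVY)
        quad = float(yVy - XtVY @ beta)
        sigma2 = quad / (self.N - self.p)
        Cinv = np.linalg.inv(XtVX)
        return beta, sigma2 * Cinv, sigma2

    def minus2_reml_theta(self, sigma2: float, thetas: np.ndarray, y_col: int = 0) -> float:
        """-2 REML log-likelihood in variance-component parametrization."""
        gamma = np.asarray(thetas, dtype=float) / sigma2
        XtVX, XtVY, yVy, logdetM = self._pieces(np.atleast_2d(gamma))
        sign, logdetC = np.linalg.slogdet(XtVX[0])
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVX[0], XtVY[0, :, y_col])
        quad = float(yVy[0, y_col] - XtVY[0, :, y_col] @ beta)
        return (
            (self.N - self.p) * np.log(sigma2)
            + float(logdetM[0])
            + float(logdetC)
            + quad / sigma2
        )


def _gamma_grid(n_groups: int) -> np.ndarray:
    if n_groups == 0:
        return np.zeros((1, 0))
    return np.array(list(product(GAMMA_GRID, repeat=n_groups)))


def _wald_f(ws: _RemlWorkspace, gamma: np.ndarray, y_col: int = 0):
    beta, cov, sigma2 = ws.fit(gamma, y_col)
    t = ws.design.test_col
    v = cov[t, t]
    if v <= 0:
        return np.nan, beta, sigma2
    return float(beta[t] ** 2 / v), beta, sigma2


def _satterthwaite_df(ws: _RemlWorkspace, gamma: np.ndarray, sigma2: float, y_col: int = 0) -> float:
    """Approximate Satterthwaite denominator df by finite differences.

    df = 2 v^2 / (g' A g) with v the tested coefficient's sampling variance,
    g its gradient in the variance components and A the asymptotic
    covariance of the REML variance estimates (twice the inverse Hessian of
    the -2 REML log-likelihood). Falls back to the residual df when the
    Hessian is not usable (e.g. all ratios on the zero boundary).
    """
    resid_df = ws.N - ws.p
    active = np.flatnonzero(np.asarray(gamma) > 0)
    params = np.concatenate([[sigma2], np.asarray(gamma)[active] * sigma2])

    def v_of(params_):
        s2 = params_[0]
        g = np.array(gamma, dtype=float)
        g[active] = params_[1:] / s2
        _, cov, s2_hat = ws.fit(g, y_col)
        t = ws.design.test_col
        # variance at the given components, not re-profiled
        return cov[t, t] / s2_hat * s2

    def m2l(params_):
        s2 = params_[0]
        g = np.array(gamma, dtype=float)
        g[active] = params_[1:] / s2
        return ws.minus2_reml_theta(s2, g * s2, y_col)

    m = len(params)
    h = 1e-4 * np.maximum(np.abs(params), 1e-8)
    try:
        v0 = v_of(params)
        grad = np.zeros(m)
        for i in range(m):
            e = np.zeros(m)
            e[i] = h[i]
            grad[i] = (v_of(params + e) - v_of(params - e)) / (2 * h[i])
        Hm = np.zeros((m, m))
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m)
                ei[i] = h[i]
                ej = np.zeros(m)
                ej[j] = h[j]
                Hm[i, j] = Hm[j, i] = (
                    m2l(params + ei + ej) - m2l(params + ei - ej)
                    - m2l(params - ei + ej) + m2l(params - ei - ej)
                ) / (4 * h[i] * h[j])
        A = 2.0 * np.linalg.inv(Hm)
        denom = float(grad @ A @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(resid_df)
        df = 2.0 * v0**2 / denom
        return float(np.clip(df, 1.0, resid_df))
    except np.linalg.LinAlgError:
        return float(resid_df)


@dataclass
class TermFit:
    """One fitted term: Wald F for its effect and the surrounding estimates."""

    term: tuple[str, ...]
    F: float
    df1: int
    df2: float
    p: float
    beta: dict
    sigma2: float
    gamma: np.ndarray
    converged: bool = True


def fit_term_model(G, y, term, cofactors=(), refine: bool = True, compute_pvalue: bool = True) -> TermFit:
    """Fit the restricted mixed model for one marker or marker pair.

    The tested term's additive (and, for a pair, epistatic) effect is fixed;
    the environment main effect and the term's environment interactions are
    independent random effects whose variance ratios are estimated by
    profiled REML (coarse log-grid search, Nelder-Mead refinement when
    ``refine``). Returns the Wald F of the tested effect (1 numerator df)
    with an approximate Satterthwaite denominator df. In a single
    environment the model has no random terms and the fit is exact OLS, so F
    equals the classical partial F of adding the tested effect to the
    cofactor regression.

    Raises
    ------
    ValueError
        If a tested marker is monomorphic or appears among the cofactors.
    numpy.linalg.LinAlgError
        If the fixed-effect design is singular (collinear cofactors).
    """
    G = as_genotype_matrix(G)
    y = as_phenotype_table(y, G)
    term = (term,) if isinstance(term, str) else tuple(term)
    cofactors = list(cofactors)
    for m in term:
        if m in cofactors:
            raise ValueError(f"tested marker {m!r} cannot be its own cofactor")
    Xg, vals = _complete_lines(G, y)
    cols = {m: j for j, m in enumerate(G.marker_ids)}
    for m in term:
        if np.nanvar(Xg[:, cols[m]]) == 0:
            raise ValueError(f"tested marker {m!r} has zero variance")
    H = vals.shape[1]
    design = _build_design(Xg, cols, term, cofactors, H)
    Y = vals.T.reshape(-1, 1)  # env-major stacking
    ws = _RemlWorkspace(design, Y)
    grid = _gamma_grid(design.n_groups)
    crit = ws.criterion(grid)[:, 0]
    if not np.isfinite(crit).any():
        raise np.linalg.LinAlgError("singular design for term")
    best = int(np.argmin(crit))
    gamma = grid[best].copy()
    if refine and design.n_groups:
        floor = 1e-8
        x0 = np.log(np.maximum(gamma, floor))
        res = optimize.minimize(
            lambda t: float(ws.criterion(np.exp(t)[None])[0, 0]),
            x0,
            method="Nelder-Mead",
            options={"maxiter": 200 * design.n_groups, "xatol": 1e-4, "fatol": 1e-8},
        )
        cand = np.exp(res.x)
        cand[cand < 2 * floor] = 0.0
        if float(ws.criterion(cand[None])[0, 0]) <= crit[best]:
            gamma = cand
    F, beta, sigma2 = _wald_f(ws, gamma)
    if design.n_groups and compute_pvalue:
        df2 = _satterthwaite_df(ws, gamma, sigma2)
    else:
        df2 = float(ws.N - ws.p)
    p = float(stats.f.sf(F, 1, df2)) if compute_pvalue and np.isfinite(F) else np.nan
    return TermFit(term, F, 1, df2, p, dict(zip(design.fixed_names, beta)), sigma2, gamma)
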