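"""Stage 1: generalized multifactor dimensionality reduction (GMDR) screening.

GMDR reduces a genome-wide marker panel to a small candidate set before any
model fitting. For a quantitative trait the score statistic of each
line-by-environment observation is its residual from the null covariate
model (grand mean plus environment means). Observations are binned by the
joint genotype at a 1-, 2- or 3-locus marker combination crossed with the
environment; a cell is labelled high-risk when the summed training scores in
it are positive and low-risk when negative. Combinations are ranked by
cross-validated testing balanced accuracy (folds split whole lines, so a
line's observations never straddle the train/test boundary), and the markers
of the best models per order form the candidate set passed to the
mixed-model scan.

Environments enter the cell definition because a QTS whose effect reverses
across environments (a strong ``ae`` with a modest ``a``) produces cell
means of opposite sign in the two environments; pooling observations over
environments would cancel exactly that signal, while environment-specific
cells retain it. With a single environment the scheme reduces to the
classical quantitative-trait GMDR.

Cross-validation consistency is reported per combination as the number of
folds whose testing balanced accuracy exceeds 0.5 (a chance classifier), a
per-model quantity that does not require scoring every competitor in every
fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from ._data import as_genotype_matrix, as_phenotype_table
from .core import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "GmdrModelScore",
    "CandidateSet",
    "compute_score_residuals",
    "classify_cells",
    "evaluate_combo",
    "screen",
    "GmdrScreen",
]

_ZERO_TOL = 1e-12


@dataclass
class GmdrModelScore:
    """Cross-validated score of one marker combination."""

    combo: tuple[str, ...]
    order: int
    mean_accuracy: float
    consistency: int
    fold_accuracies: np.ndarray = field(repr=False, default=None)


@dataclass
class CandidateSet:
    """Candidate markers and pair families nominated by the GMDR screen.

    ``markers`` is the 1D scan set: every marker of a retained model plus its
    linkage neighbourhood. ``pairs`` are the 2D scan terms: the pair
    neighbourhoods of retained two-locus models. ``representatives`` are the
    clumped region representatives used as background cofactors; ``models``
    holds the retained model scores themselves.
    """

    markers: list[str]
    models: list[GmdrModelScore]
    pairs: list[tuple[str, str]] = field(default_factory=list)
    representatives: list[str] = field(default_factory=list)
    pair_representatives: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("candidate markers must be unique")


def compute_score_residuals(y: PhenotypeTable) -> np.ndarray:
    """GMDR score statistic: residual from the mean + environment null model.

    Returns an (n_lines, n_env) array ``s_hk = y_hk - mean_h`` (the
    environment mean absorbs the grand mean); scores sum to zero within
    every environment. Missing phenotypes give NaN scores.
    """
    vals = y.values
    n_obs = np.sum(np.isfinite(vals), axis=0)
    if (n_obs < 2).any():
        bad = y.env_ids[int(np.argmin(n_obs))]
        raise ValueError(f"environment {bad!r} has fewer than 2 observations")
    with np.errstate(invalid="ignore"):
        env_means = np.nanmean(vals, axis=0)
    return vals - env_means


def _as_score_matrix(scores) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    return scores


def _fold_assignment(n: int, k_folds: int, seed) -> np.ndarray:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    folds[rng.permutation(n)] = np.arange(n) % k_folds
    return folds


def classify_cells(scores, G, combo) -> dict[tuple, str]:
    """Label each genotype-by-environment cell HIGH, LOW or UNCLASSIFIED.

    ``scores`` is an (n_lines,) or (n_lines, n_env) array of score
    residuals. Cells are keyed by the joint genotype at the combination's
    markers, followed by the environment index when there is more than one
    environment. A cell is HIGH when its summed score is positive, LOW when
    negative, UNCLASSIFIED when empty or exactly zero. Observations missing a
    genotype or a score fall in no cell.
    """
    G = as_genotype_matrix(G)
    combo = tuple(combo)
    if not 1 <= len(combo) <= 3:
        raise ValueError("combination order must be 1, 2 or 3")
    S = _as_score_matrix(scores)
    H = S.shape[1]
    cols = np.column_stack([G.column(m) for m in combo])
    sums: dict[tuple, float] = {}
    for k in range(S.shape[0]):
        if not np.isfinite(cols[k]).all():
            continue
        geno = tuple(cols[k])
        for h in range(H):
            if not np.isfinite(S[k, h]):
                continue
            key = geno + (h,) if H > 1 else geno
            sums[key] = sums.get(key, 0.0) + S[k, h]
    labels: dict[tuple, str] = {}
    for key, total in sums.items():
        if abs(total) <= _ZERO_TOL:
            labels[key] = "UNCLASSIFIED"
        else:
            labels[key] = "HIGH" if total > 0 else "LOW"
    return labels


def _subset(G: GenotypeMatrix, mask: np.ndarray) -> GenotypeMatrix:
    return GenotypeMatrix(
        G.line_ids[mask],
        G.markers,
        G.values[mask],
        max_het_fraction=1.0,
        max_missing_fraction=1.0,
    )


def evaluate_combo(scores, G, combo, k_folds: int = 10, seed=0) -> GmdrModelScore:
    """Cross-validated testing balanced accuracy of one marker combination.

    Folds are assigned to whole lines (seeded). In each fold the cells are
    labelled on the training lines' observations; a test observation is a
    true positive when its score is positive and its cell is HIGH. Balanced
    accuracy is the mean of sensitivity and specificity over classified test
    observations; folds with no classifiable test observation of one class
    are excluded from the mean with a logged warning.
    """
    G = as_genotype_matrix(G)
    if isinstance(scores, PhenotypeTable):
        scores = compute_score_residuals(scores)
    combo = tuple(combo)
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    S = _as_score_matrix(scores)
    n, H = S.shape
    if n < k_folds:
        raise ValueError("need at least one line per fold")
    folds = _fold_assignment(n, k_folds, seed)
    accs = np.full(k_folds, np.nan)
    cols = np.column_stack([G.column(m) for m in combo])
    for f in range(k_folds):
        train = folds != f
        labels = classify_cells(S[train], _subset(G, train), combo)
        tp = fn = tn = fp = 0
        for k in np.flatnonzero(~train):
            if not np.isfinite(cols[k]).all():
                continue
            geno = tuple(cols[k])
            for h in range(H):
                if not np.isfinite(S[k, h]):
                    continue
                key = geno + (h,) if H > 1 else geno
                lab = labels.get(key, "UNCLASSIFIED")
                if lab == "UNCLASSIFIED":
                    continue
                positive = S[k, h] > 0
                predicted = lab == "HIGH"
                tp += positive and predicted
                fn += positive and not predicted
                tn += (not positive) and (not predicted)
                fp += (not positive) and predicted
        if tp + fn == 0 or tn + fp == 0:
            logger.warning("fold %d of combo %s has no classifiable test observations", f, combo)
            continue
        accs[f] = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
    good = np.isfinite(accs)
    mean_acc = float(np.nanmean(accs)) if good.any() else np.nan
    consistency = int(np.sum(accs[good] > 0.5))
    return GmdrModelScore(combo, len(combo), mean_acc, consistency, accs)


# ---------------------------------------------------------------------------
# vectorized exhaustive search (fully homozygous +/-1 panels)


def _order1_accuracies(X, S, folds, k_folds):
    """Per-marker, per-fold balanced accuracy; NaN for undefined folds."""
    n, p = X.shape
    H = S.shape[1]
    A = (X > 0).astype(float)  # +1 indicator
    B = 1.0 - A
    pos = (S > 0).astype(float)  # (n, H)
    accs = np.full((k_folds, p), np.nan)
    for f in range(k_folds):
        tr = (folds != f).astype(float)
        te = 1.0 - tr
        TP = np.zeros(p)
        FN = np.zeros(p)
        FP = np.zeros(p)
        TN = np.zeros(p)
        for I in (A, B):
            cnt = tr @ I  # training lines per cell, same for every env
            for h in range(H):
                ts = (S[:, h] * tr) @ I
                tpos = (pos[:, h] * te) @ I
                tneg = ((1.0 - pos[:, h]) * te) @ I
                high = (ts > _ZERO_TOL) & (cnt > 0.5)
                low = (ts < -_ZERO_TOL) & (cnt > 0.5)
                TP += tpos * high
                FN += tpos * low
                FP += tneg * high
                TN += tneg * low
        with np.errstate(invalid="ignore", divide="ignore"):
            accs[f] = 0.5 * (TP / (TP + FN) + TN / (TN + FP))
    return accs


def _order2_accuracies(X, S, folds, k_folds):
    """All-pairs, per-fold balanced accuracy via bilinear cell identities.

    For +/-1 codes the sum of a weight vector ``w`` over the cell
    ``(x_i = u, x_j = v)`` equals ``(S0 + u S1_i + v S1_j + u v S2_ij) / 4``
    with ``S0 = sum w``, ``S1 = X'w`` and ``S2 = X' diag(w) X``, which turns
    the exhaustive pair search into a handful of Gram products per fold and
    environment.
    """
    n, p = X.shape
    H = S.shape[1]
    iu = np.triu_indices(p, k=1)
    pos = (S > 0).astype(float)
    accs = np.full((k_folds, len(iu[0])), np.nan)

    def gram(w):
        return w.sum(), X.T @ w, X.T @ (w[:, None] * X)

    def cell(stats, u, v):
        S0, S1, S2 = stats
        return 0.25 * (S0 + u * S1[:, None] + v * S1[None, :] + u * v * S2)[iu]

    for f in range(k_folds):
        tr = (folds != f).astype(float)
        te = 1.0 - tr
        cnt_stats = gram(tr)
        ts_stats = [gram(S[:, h] * tr) for h in range(H)]
        tpos_stats = [gram(pos[:, h] * te) for h in range(H)]
        tneg_stats = [gram((1.0 - pos[:, h]) * te) for h in range(H)]
        TP = np.zeros(len(iu[0]))
        FN = np.zeros_like(TP)
        FP = np.zeros_like(TP)
        TN = np.zeros_like(TP)
        for u in (1.0, -1.0):
            for v in (1.0, -1.0):
                cnt = cell(cnt_stats, u, v)
                present = cnt > 0.5
                for h in range(H):
                    ts = cell(ts_stats[h], u, v)
                    high = (ts > _ZERO_TOL) & present
                    low = (ts < -_ZERO_TOL) & present
                    tpos = cell(tpos_stats[h], u, v)
                    tneg = cell(tneg_stats[h], u, v)
                    TP += tpos * high
                    FN += tpos * low
                    FP += tneg * high
                    TN += tneg * low
        with np.errstate(invalid="ignore", divide="ignore"):
            accs[f] = 0.5 * (TP / (TP + FN) + TN / (TN + FP))
    return accs, list(zip(iu[0], iu[1]))


def _order3_accuracies(X, S, folds, k_folds, chunk=2048):
    """Chunked 3-locus evaluator (generic levels; small panels only)."""
    n, p = X.shape
    H = S.shape[1]
    combos = list(combinations(range(p), 3))
    lev = (X + 1).astype(np.int64)  # 0,1,2 levels
    n_cells = 27
    accs = np.full((k_folds, len(combos)), np.nan)
    pos = (S > 0).astype(float)
    for start in range(0, len(combos), chunk):
        block = combos[start : start + chunk]
        idx = np.array(block)
        code = lev[:, idx[:, 0]] * 9 + lev[:, idx[:, 1]] * 3 + lev[:, idx[:, 2]]  # (n, c)
        c = len(block)
        offs = np.arange(c) * n_cells
        flat = code + offs[None, :]
        size = c * n_cells
        for f in range(k_folds):
            tr = folds != f
            te = ~tr

            def acc_w(w, mask):
                return np.bincount(
                    flat[mask].ravel(), weights=np.repeat(w[mask], c), minlength=size
                )

            cnt = acc_w(np.ones(n), tr)
            present = cnt > 0.5
            TP = np.zeros(c)
            FN = np.zeros(c)
            FP = np.zeros(c)
            TN = np.zeros(c)
            for h in range(H):
                ts = acc_w(S[:, h], tr)
                high = (ts > _ZERO_TOL) & present
                low = (ts < -_ZERO_TOL) & present
                tpos = acc_w(pos[:, h], te)
                tneg = acc_w(1.0 - pos[:, h], te)
                TP += np.add.reduceat(tpos * high, offs)
                FN += np.add.reduceat(tpos * low, offs)
                FP += np.add.reduceat(tneg * high, offs)
                TN += np.add.reduceat(tneg * low, offs)
            with np.errstate(invalid="ignore", divide="ignore"):
                accs[f, start : start + c] = 0.5 * (TP / (TP + FN) + TN / (TN + FP))
    return accs, combos


def _generic_accuracies(G, S, combos, folds, k_folds):
    """Fallback per-combo evaluation for panels with heterozygous/missing codes."""
    accs = np.full((k_folds, len(combos)), np.nan)
    marker_ids = G.marker_ids
    n, H = S.shape
    for i, c in enumerate(combos):
        combo = tuple(marker_ids[j] for j in c)
        cols = np.column_stack([G.column(m) for m in combo])
        for f in range(k_folds):
            train = folds != f
            sums: dict[tuple, float] = {}
            for k in np.flatnonzero(train):
                if not np.isfinite(cols[k]).all():
                    continue
                geno = tuple(cols[k])
                for h in range(H):
                    if np.isfinite(S[k, h]):
                        key = geno + (h,) if H > 1 else geno
                        sums[key] = sums.get(key, 0.0) + S[k, h]
            tp = fn = tn = fp = 0
            for k in np.flatnonzero(~train):
                if not np.isfinite(cols[k]).all():
                    continue
                geno = tuple(cols[k])
                for h in range(H):
                    if not np.isfinite(S[k, h]):
                        continue
                    key = geno + (h,) if H > 1 else geno
                    total = sums.get(key)
                    if total is None or abs(total) <= _ZERO_TOL:
                        continue
                    positive = S[k, h] > 0
                    predicted = total > 0
                    tp += positive and predicted
                    fn += positive and not predicted
                    tn += (not positive) and (not predicted)
                    fp += (not positive) and predicted
            if tp + fn > 0 and tn + fp > 0:
                accs[f, i] = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
    return accs


def _rank_and_retain(G, combos, accs, retain_m, clump_window_cm):
    """Rank combos, then retain the best with regional diversity (clumping).

    Ranking is (accuracy desc, consistency desc, lexicographic ids). A model
    is retained only if at least one of its markers lies farther than
    ``clump_window_cm`` (same chromosome) from every marker already retained
    at this order, so linkage shadows of one strong QTS cannot fill every
    slot. ``clump_window_cm=None`` disables the diversity constraint.
    """
    marker_ids = G.marker_ids
    meta = G.markers
    chrom = meta["chrom"].to_numpy()
    pos = meta["pos_cm"].to_numpy()
    mean_acc = np.nanmean(np.where(np.isfinite(accs), accs, np.nan), axis=0)
    mean_acc = np.where(np.isfinite(mean_acc), mean_acc, -np.inf)
    consistency = np.nansum(np.where(np.isfinite(accs), accs > 0.5, False), axis=0)
    names = [tuple(sorted(marker_ids[j] for j in c)) for c in combos]
    order = sorted(range(len(combos)), key=lambda i: (-mean_acc[i], -consistency[i], names[i]))
    out = []
    pool: list[int] = []  # marker column indices already retained

    def novel(j):
        return all(
            chrom[j] != chrom[k] or abs(pos[j] - pos[k]) > clump_window_cm for k in pool
        )

    for i in order:
        if len(out) == retain_m:
            break
        cols = list(combos[i])
        if clump_window_cm is not None and pool and not any(novel(j) for j in cols):
            continue
        pool.extend(cols)
        out.append(
            GmdrModelScore(
                names[i],
                len(names[i]),
                float(mean_acc[i]) if np.isfinite(mean_acc[i]) else np.nan,
                int(consistency[i]),
                accs[:, i],
            )
        )
    return out


def _neighbourhood(G, marker: str, width: int) -> list[str]:
    """Markers within ``width`` map positions of ``marker`` on its chromosome."""
    meta = G.markers
    j = G.marker_index(marker)
    chrom = meta.at[j, "chrom"]
    same = meta.index[meta["chrom"] == chrom].to_numpy()
    k = int(np.where(same == j)[0][0])
    lo, hi = max(0, k - width), min(len(same), k + width + 1)
    return [meta.at[int(i), "marker"] for i in same[lo:hi]]


def screen(
    G,
    y,
    max_order: int = 3,
    retain_m: int = 10,
    k_folds: int = 10,
    seed=0,
    combo_budget: float = 5e7,
    clump_window_cm: float | None = 30.0,
    expand_markers: int = 15,
    expand_pair_markers: int = 5,
) -> CandidateSet:
    """Exhaustive GMDR screen; returns the candidate set for the scan.

    Every combination of each order up to ``max_order`` is scored
    independently by k-fold cross-validated balanced accuracy. The top
    ``retain_m`` models per order are retained under a regional diversity
    constraint (``clump_window_cm``), because linkage shadows of a single
    strong QTS otherwise crowd out weaker regions. Each retained model
    marker is then expanded by ``expand_markers`` neighbours on each side
    into the 1D candidate list (cross-validated accuracy localizes a region,
    not a marker; the scan's F profile does the fine mapping), and each
    retained two-locus model contributes the ``expand_pair_markers``-wide
    pair neighbourhood of its two markers as explicit 2D scan terms.

    Raises
    ------
    ValueError
        When the total number of combinations exceeds ``combo_budget`` —
        lower ``max_order`` or pre-filter the panel instead of waiting.
    """
    G = as_genotype_matrix(G)
    y = as_phenotype_table(y, G)
    if max_order not in (1, 2, 3):
        raise ValueError("max_order must be 1, 2 or 3")
    if retain_m < 1:
        raise ValueError("retain_m must be at least 1")
    p = G.n_markers
    total = sum(math.comb(p, d) for d in range(1, max_order + 1))
    if total > combo_budget:
        raise ValueError(
            f"{total:.3g} combinations exceed the budget of {combo_budget:.3g}; "
            "lower max_order or pre-filter the marker panel"
        )
    S = compute_score_residuals(y)
    X = G.values
    n = G.n_lines
    folds = _fold_assignment(n, k_folds, seed)
    homozygous = bool(np.isin(X, (-1.0, 1.0)).all()) and np.isfinite(S).all()
    marker_ids = G.marker_ids

    retained: list[GmdrModelScore] = []
    for order in range(1, max_order + 1):
        if order == 1:
            combos = [(j,) for j in range(p)]
            if homozygous:
                accs = _order1_accuracies(X, S, folds, k_folds)
            else:
                accs = _generic_accuracies(G, S, combos, folds, k_folds)
        elif order == 2:
            if homozygous:
                accs, combos = _order2_accuracies(X, S, folds, k_folds)
            else:
                combos = list(combinations(range(p), 2))
                accs = _generic_accuracies(G, S, combos, folds, k_folds)
        else:
            if homozygous:
                accs, combos = _order3_accuracies(X, S, folds, k_folds)
            else:
                combos = list(combinations(range(p), 3))
                accs = _generic_accuracies(G, S, combos, folds, k_folds)
        retained.extend(_rank_and_retain(G, combos, accs, retain_m, clump_window_cm))

    ranked = sorted(
        retained,
        key=lambda m: (
            -(m.mean_accuracy if np.isfinite(m.mean_accuracy) else -np.inf),
            -m.consistency,
            m.combo,
        ),
    )
    representatives: list[str] = []
    for model in ranked:
        for mk in model.combo:
            if mk not in representatives:
                representatives.append(mk)
    markers: list[str] = []
    for model in ranked:
        for mk in model.combo:
            for nb in _neighbourhood(G, mk, expand_markers):
                if nb not in markers:
                    markers.append(nb)
    pairs: list[tuple[str, str]] = []
    seen = set()
    for model in ranked:
        if model.order != 2:
            continue
        a, b = model.combo
        for na in _neighbourhood(G, a, expand_pair_markers):
            for nb in _neighbourhood(G, b, expand_pair_markers):
                if na == nb:
                    continue
                key = tuple(sorted((na, nb)))
                if key not in seen:
                    seen.add(key)
                    pairs.append(key)
    pair_reps = [tuple(m.combo) for m in ranked if m.order == 2]
    return CandidateSet(
        markers=markers,
        models=retained,
        pairs=pairs,
        representatives=representatives,
        pair_representatives=pair_reps,
    )


class GmdrScreen(SelectorMixin, BaseEstimator):
    """GMDR marker screening as a scikit-learn feature selector.

    Parameters
    ----------
    max_order : int, default 2
        Highest combination order searched exhaustively (1-3).
    retain_m : int, default 10
        Models retained per order; the union of their markers is selected.
    k_folds : int, default 10
    combo_budget : float, default 5e7
        Refuse searches larger than this many combinations.
    random_state : int, default 0
        Seeds the cross-validation fold assignment.

    Attributes
    ----------
    candidates_ : CandidateSet
    support_ : boolean mask over markers
    n_features_in_ : int
    """

    def __init__(
        self,
        max_order=2,
        retain_m=10,
        k_folds=10,
        combo_budget=5e7,
        clump_window_cm=30.0,
        expand_markers=15,
        expand_pair_markers=5,
        random_state=0,
    ):
        self.max_order = max_order
        self.retain_m = retain_m
        self.k_folds = k_folds
        self.combo_budget = combo_budget
        self.clump_window_cm = clump_window_cm
        self.expand_markers = expand_markers
        self.expand_pair_markers = expand_pair_markers
        self.random_state = random_state

    def fit(self, X, y):
        G = as_genotype_matrix(X)
        self.candidates_ = screen(
            G,
            y,
            max_order=self.max_order,
            retain_m=self.retain_m,
            k_folds=self.k_folds,
            seed=self.random_state,
            combo_budget=self.combo_budget,
            clump_window_cm=self.clump_window_cm,
            expand_markers=self.expand_markers,
            expand_pair_markers=self.expand_pair_markers,
        )
        self.n_features_in_ = G.n_markers
        sel = set(self.candidates_.markers)
        self.support_ = np.array([m in sel for m in G.marker_ids])
        self.marker_ids_ = G.marker_ids
        return self

    def _get_support_mask(self):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        tags.input_tags.allow_nan = True
        return tags
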