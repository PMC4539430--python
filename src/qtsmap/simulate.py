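"""Simulation of RIL populations and replicated power studies.

Genotypes are generated marker-by-marker along each chromosome as a
first-order Markov chain: the first marker of a chromosome is +1 or -1 with
probability 1/2, and each subsequent marker switches sign with probability

    R = 2 r / (1 + 2 r),   r = (1 - exp(-2 d / 100)) / 2,

the expected recombination between fixed RIL genotypes separated by ``d``
centimorgan under Haldane's (no-interference) map function. This is exact
for all pairwise RIL expectations and far cheaper than simulating whole
gametes through the selfing generations.

Phenotypes follow the QTS mixed model (see :mod:`qtsmap.core`): additive,
epistatic, environment and interaction effects plus i.i.d. Gaussian noise
whose variance is solved so that the genetic terms explain a target
heritability on the realized genotype matrix.

The power-study driver runs the full two-step pipeline (GMDR screen ->
mixed-model scan with a permutation threshold -> optional MCMC estimation)
over replicated simulated datasets and tabulates, per true QTS term, the
detection power and the mean effect estimates over detecting replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneticMap,
    GenotypeMatrix,
    PhenotypeTable,
    QTSEffectSet,
    AdditiveTerm,
    EpistaticTerm,
    genetic_variance,
    recombination_fraction,
    ril_recombination_fraction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_ril_genotypes",
    "resolve_residual_variance",
    "simulate_phenotypes",
    "realized_heritability",
    "reference_truth",
    "reference_scenario",
    "SimulationScenario",
    "MappingConfig",
    "PowerStudyResult",
    "run_power_study",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_ril_genotypes(gmap: GeneticMap, n: int, seed=0) -> GenotypeMatrix:
    """Simulate ``n`` independent fully homozygous RILs on a genetic map.

    Each chromosome is an independent +/-1 Markov chain along its markers
    (switch probability from the RIL-at-fixation map function); chromosomes
    segregate independently. No heterozygotes, no missing values.
    """
    if gmap.n_markers == 0:
        raise ValueError("genetic map is empty")
    if n < 1:
        raise ValueError("population size must be at least 1")
    rng = _rng(seed)
    blocks = []
    for _, sub in gmap.chromosomes():
        m = len(sub)
        first = rng.choice(np.array([1.0, -1.0]), size=n)
        if m == 1:
            blocks.append(first[:, None])
            continue
        d = np.diff(sub["pos_cm"].to_numpy())
        R = ril_recombination_fraction(recombination_fraction(d))
        switch = rng.random((n, m - 1)) < R
        steps = np.concatenate([np.ones((n, 1)), np.where(switch, -1.0, 1.0)], axis=1)
        blocks.append(first[:, None] * np.cumprod(steps, axis=1))
    values = np.concatenate(blocks, axis=1)
    line_ids = [f"RIL{k + 1:04d}" for k in range(n)]
    markers = gmap.table.copy()
    markers["allele_high"], markers["allele_low"] = "A", "B"
    return GenotypeMatrix(line_ids, markers, values)


def resolve_residual_variance(truth: QTSEffectSet, G: GenotypeMatrix, h2_target: float) -> float:
    """Residual variance giving the genetic terms a target heritability.

    Solves ``V_g / (V_g + sigma2_eps) = h2_target`` where ``V_g`` is the
    summed empirical variance of every genetic term (a, aa, ae, aae; the
    environment main effect is excluded) over the realized design.
    """
    if not 0 < h2_target <= 1:
        raise ValueError("target heritability must lie in (0, 1]")
    vg = genetic_variance(truth, G)
    if vg <= 0:
        raise ValueError("truth has zero genetic variance on this genotype matrix")
    return vg * (1.0 - h2_target) / h2_target


def realized_heritability(truth: QTSEffectSet, G: GenotypeMatrix) -> float:
    """Fraction of modelled variance explained by the genetic terms of ``truth``."""
    vg = genetic_variance(truth, G)
    return vg / (vg + truth.sigma2_eps)


def simulate_phenotypes(
    G: GenotypeMatrix,
    truth: QTSEffectSet,
    env_effects: np.ndarray | None = None,
    seed=0,
) -> PhenotypeTable:
    """Draw phenotypes from the QTS mixed model on a genotype matrix.

    ``y_hk = mu + sum x a + sum xx aa + e_h + sum x ae_h + sum xx aae_h + eps``
    with ``eps ~ Normal(0, truth.sigma2_eps)`` i.i.d. Environment main
    effects come from ``env_effects`` if given, else ``truth.env_effects``,
    else zero.
    """
    rng = _rng(seed)
    n, H = G.n_lines, truth.n_env
    g = np.zeros((H, n))
    for t in truth.additive:
        x = G.column(t.marker)
        g += x[None, :] * t.a + np.outer(t.ae, x)
    for t in truth.epistatic:
        xx = G.column(t.marker_i) * G.column(t.marker_j)
        g += xx[None, :] * t.aa + np.outer(t.aae, xx)
    e = env_effects if env_effects is not None else truth.env_effects
    if e is None:
        e = np.zeros(H)
    e = np.asarray(e, dtype=float)
    if len(e) != H:
        raise ValueError("environment effect vector length must equal n_env")
    y = truth.mu + g + e[:, None]
    if truth.sigma2_eps > 0:
        y = y + rng.normal(0.0, np.sqrt(truth.sigma2_eps), size=(H, n))
    env_ids = [f"E{h + 1}" for h in range(H)]
    return PhenotypeTable(G.line_ids, env_ids, y.T)


# ---------------------------------------------------------------------------
# reference study configurations


def reference_truth(effect_scale: str = "large", n_env: int = 2) -> QTSEffectSet:
    """Bundled simulation truth: 3 additive QTSs and 1 epistatic pair.

    Two effect scales are provided, differing only in the magnitude of the
    generating values (both on a 3-chromosome x 175-marker, 1-cM map):

    ``"large"``
        a = (-3.24, -2.65, -1.77) at chr1:28, chr2:100, chr3:93 with
        ae_1 = (2.65, 4.05, 3.24); pair chr2:44 x chr3:63 with aa = 3.86,
        aae_1 = 4.47. Environment-2 interactions are the negatives
        (sum-to-zero convention).
    ``"small"``
        a = (-0.79, -0.67, -0.40), ae_1 = (0.63, 0.39, 0.32);
        aa = 0.39, aae_1 = 0.17; same positions and convention.

    The population mean is 10 trait units and the fixed environment effects
    are (+1, -1). Residual variance is left at 0 and is meant to be solved
    per dataset by :func:`resolve_residual_variance`.
    """
    if n_env != 2:
        raise ValueError("the reference truths are defined for two environments")
    scales = {
        "large": ((-3.24, -2.65, -1.77), (2.65, 4.05, 3.24), 3.86, 4.47),
        "small": ((-0.79, -0.67, -0.40), (0.63, 0.39, 0.32), 0.39, 0.17),
    }
    if effect_scale not in scales:
        raise ValueError("effect_scale must be 'large' or 'small'")
    a, ae1, aa, aae1 = scales[effect_scale]
    markers = ["chr1_snp28", "chr2_snp100", "chr3_snp93"]
    additive = [
        AdditiveTerm(m, a[i], np.array([ae1[i], -ae1[i]])) for i, m in enumerate(markers)
    ]
    epistatic = [EpistaticTerm("chr2_snp44", "chr3_snp63", aa, np.array([aae1, -aae1]))]
    return QTSEffectSet(
        mu=10.0,
        additive=additive,
        epistatic=epistatic,
        env_effects=np.array([1.0, -1.0]),
        sigma2_eps=0.0,
        n_env=2,
    )


@dataclass
class SimulationScenario:
    """A replicated simulation design: map, truth, size and heritability.

    Attributes
    ----------
    n : population size (number of RILs), >= 2.
    gmap : the genetic map markers are simulated on.
    truth : generating effects; its ``sigma2_eps`` is ignored and re-solved
        per replicate from ``h2_target``.
    h2_target : fraction of modelled phenotypic variance explained by the
        genetic terms, in (0, 1].
    env_mode : ``"fixed"`` uses ``truth.env_effects`` as-is every replicate;
        ``"random"`` draws ``e_h ~ Normal(0, sigma2_env)`` once per replicate.
    n_replicates : number of simulated datasets.
    base_seed : replicate ``i`` uses seed ``base_seed + i``; the threshold
        calibration dataset uses ``base_seed + n_replicates``.
    """

    n: int
    gmap: GeneticMap
    truth: QTSEffectSet
    h2_target: float
    env_mode: str = "fixed"
    sigma2_env: float = 1.0
    n_replicates: int = 200
    base_seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("population size must be at least 2")
        if not 0 < self.h2_target <= 1:
            raise ValueError("h2_target must lie in (0, 1]")
        if self.env_mode not in ("fixed", "random"):
            raise ValueError("env_mode must be 'fixed' or 'random'")
        have = set(self.gmap.marker_ids)
        for m in self.truth.markers():
            if m not in have:
                raise ValueError(f"truth marker {m!r} is not on the map")

    def replicate(self, index: int) -> tuple[GenotypeMatrix, PhenotypeTable, QTSEffectSet]:
        """Simulate one replicate: genotypes, phenotypes and the solved truth."""
        seed = self.base_seed + index
        rng = np.random.default_rng(seed)
        G = simulate_ril_genotypes(self.gmap, self.n, rng)
        sigma2 = resolve_residual_variance(self.truth, G, self.h2_target)
        truth = replace(self.truth, sigma2_eps=sigma2)
        if self.env_mode == "random":
            e = rng.normal(0.0, np.sqrt(self.sigma2_env), size=truth.n_env)
        else:
            e = truth.env_effects
        y = simulate_phenotypes(G, truth, env_effects=e, seed=rng)
        return G, y, truth


def reference_scenario(
    n: int,
    h2: float,
    effect_scale: str = "large",
    n_replicates: int = 200,
    base_seed: int = 0,
) -> SimulationScenario:
    """Convenience constructor for the bundled 525-marker RIL study design."""
    return SimulationScenario(
        n=n,
        gmap=GeneticMap.uniform(3, 175, 1.0),
        truth=reference_truth(effect_scale),
        h2_target=h2,
        n_replicates=n_replicates,
        base_seed=base_seed,
    )


# ---------------------------------------------------------------------------
# power study


@dataclass
class MappingConfig:
    """Settings for the two-step pipeline inside a power study.

    ``detection_window_markers = 0`` means a true QTS counts as detected only
    when that exact marker (or exact pair) is declared significant;
    ``estimate_window_markers`` controls how far a full-model term may sit
    from the truth and still contribute its estimate (the full model is
    pruned to local F-peaks, which can land on an immediate neighbour of the
    true marker).
    """

    max_order: int = 2
    retain_m: int = 10
    k_folds: int = 10
    n_permutations: int = 200
    alpha: float = 0.05
    cofactor_window_cm: float | None = 30.0
    detection_window_markers: int = 0
    estimate_window_markers: int = 2
    estimate_effects: bool = False
    mcmc_iterations: int = 4000
    mcmc_burnin: int = 1000
    mcmc_thin: int = 1
    prune_window_cm: float = 30.0


@dataclass
class PowerStudyResult:
    """Power and conditional mean estimates for every true QTS term."""

    table: pd.DataFrame
    n_replicates: int
    n_failed: int = 0
    thresholds: dict = field(default_factory=dict)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def _marker_pos(G: GenotypeMatrix, marker: str) -> tuple[str, int]:
    j = G.marker_index(marker)
    row = G.markers.iloc[j]
    return str(row["chrom"]), j


def _within_window(G: GenotypeMatrix, a: str, b: str, window: int) -> bool:
    """True when markers a and b are on one chromosome within ``window`` positions."""
    if a == b:
        return True
    ca, ja = _marker_pos(G, a)
    cb, jb = _marker_pos(G, b)
    return ca == cb and abs(ja - jb) <= window


def _match_additive(G, detected: Sequence[str], marker: str, window: int) -> str | None:
    hits = [m for m in detected if _within_window(G, m, marker, window)]
    if not hits:
        return None
    # nearest first, ties toward the lower marker index
    return min(hits, key=lambda m: (abs(G.marker_index(m) - G.marker_index(marker)), m))


def _match_pair(G, detected_pairs, pair, window: int):
    hits = [
        p
        for p in detected_pairs
        if (_within_window(G, p[0], pair[0], window) and _within_window(G, p[1], pair[1], window))
        or (_within_window(G, p[0], pair[1], window) and _within_window(G, p[1], pair[0], window))
    ]
    if not hits:
        return None
    return min(
        hits,
        key=lambda p: abs(G.marker_index(p[0]) - G.marker_index(pair[0]))
        + abs(G.marker_index(p[1]) - G.marker_index(pair[1])),
    )


def run_power_study(
    scenario: SimulationScenario, mapping_config: MappingConfig | None = None
) -> PowerStudyResult:
    """Replicate the two-step pipeline over simulated datasets and tally power.

    For every replicate the driver simulates genotypes and phenotypes, runs
    the GMDR screen and the mixed-model scan (1D and 2D families), and — when
    ``estimate_effects`` is on — fits the full model by MCMC. The
    experiment-wise F thresholds are calibrated once per scenario by
    permutation on a dedicated calibration dataset and reused across
    replicates. A true term counts as detected when a significant term lies
    within the declaration window of the truth (exact marker by default);
    estimates are averaged over the replicates in which the term was
    detected. Replicates that raise are recorded, logged and excluded.
    """
    from .gmdr import screen
    from .mlm import scan, permutation_threshold
    from .mcmc import build_full_model, run_mcmc, ChainConfig

    cfg = mapping_config or MappingConfig()
    truth = scenario.truth
    H = truth.n_env

    # --- once-per-scenario permutation thresholds on a calibration dataset
    cal_seed = scenario.base_seed + scenario.n_replicates
    G0, y0, _ = scenario.replicate(scenario.n_replicates)
    cand0 = screen(
        G0, y0, max_order=cfg.max_order, retain_m=cfg.retain_m, k_folds=cfg.k_folds, seed=cal_seed
    )
    thresholds = permutation_threshold(
        G0,
        y0,
        cand0,
        n_permutations=cfg.n_permutations,
        alpha=cfg.alpha,
        seed=cal_seed,
        cofactor_window_cm=cfg.cofactor_window_cm,
    )

    add_keys = [t.marker for t in truth.additive]
    pair_keys = [(t.marker_i, t.marker_j) for t in truth.epistatic]
    detect_counts = {k: 0 for k in add_keys + pair_keys}
    est_acc: dict = {k: [] for k in add_keys + pair_keys}
    n_failed = 0

    for rep in range(scenario.n_replicates):
        try:
            G, y, rep_truth = scenario.replicate(rep)
            seed = scenario.base_seed + rep
            cand = screen(
                G, y, max_order=cfg.max_order, retain_m=cfg.retain_m, k_folds=cfg.k_folds, seed=seed
            )
            res = scan(
                G,
                y,
                cand,
                alpha=cfg.alpha,
                seed=seed,
                cofactor_window_cm=cfg.cofactor_window_cm,
                thresholds=thresholds,
                compute_pvalues=False,
            )
            sig1 = res.significant_markers()
            sig2 = res.significant_pairs()
            detected_now = {}
            for m in add_keys:
                hit = _match_additive(G, sig1, m, cfg.detection_window_markers)
                detected_now[m] = hit is not None
                detect_counts[m] += bool(hit is not None)
            for p in pair_keys:
                hit = _match_pair(G, sig2, p, cfg.detection_window_markers)
                detected_now[p] = hit is not None
                detect_counts[p] += bool(hit is not None)
            if cfg.estimate_effects and (sig1 or sig2):
                model = build_full_model(res, G, prune_window_cm=cfg.prune_window_cm)
                summary = run_mcmc(
                    model,
                    G,
                    y,
                    ChainConfig(cfg.mcmc_iterations, cfg.mcmc_burnin, cfg.mcmc_thin),
                    seed=seed,
                )
                eff = summary.effects
                for m in add_keys:
                    if not detected_now[m]:
                        continue
                    cand_terms = [
                        mm
                        for mm in model.additive
                        if _within_window(G, mm, m, cfg.estimate_window_markers)
                    ]
                    mm = _match_additive(G, cand_terms, m, cfg.estimate_window_markers)
                    if mm is None:
                        continue
                    rows = eff[(eff["markers"] == mm) & (eff["effect"] == "a")]
                    aes = [
                        float(
                            eff[(eff["markers"] == mm) & (eff["effect"] == f"ae_{h + 1}")][
                                "estimate"
                            ].iloc[0]
                        )
                        for h in range(H)
                    ]
                    if len(rows):
                        est_acc[m].append([float(rows["estimate"].iloc[0])] + aes)
                for p in pair_keys:
                    if not detected_now[p]:
                        continue
                    cand_pairs = [
                        q
                        for q in model.epistatic
                        if _match_pair(G, [q], p, cfg.estimate_window_markers)
                    ]
                    q = _match_pair(G, cand_pairs, p, cfg.estimate_window_markers)
                    if q is None:
                        continue
                    key = f"{q[0]}:{q[1]}"
                    rows = eff[(eff["markers"] == key) & (eff["effect"] == "aa")]
                    aaes = [
                        float(
                            eff[(eff["markers"] == key) & (eff["effect"] == f"aae_{h + 1}")][
                                "estimate"
                            ].iloc[0]
                        )
                        for h in range(H)
                    ]
                    if len(rows):
                        est_acc[p].append([float(rows["estimate"].iloc[0])] + aaes)
        except Exception:  # noqa: BLE001 - a failed replicate must not kill the study
            n_failed += 1
            logger.warning("replicate %d failed and was excluded", rep, exc_info=True)

    n_ok = scenario.n_replicates - n_failed
    rows = []
    for t in truth.additive:
        chrom, _ = _marker_pos(G0, t.marker)
        row = {
            "kind": "additive",
            "chrom": chrom,
            "markers": t.marker,
            "n": scenario.n,
            "power_pct": 100.0 * detect_counts[t.marker] / max(n_ok, 1),
            "n_detected": detect_counts[t.marker],
            "par_a": t.a,
            "est_a": np.nan,
        }
        for h in range(H):
            row[f"par_ae_{h + 1}"] = t.ae[h]
            row[f"est_ae_{h + 1}"] = np.nan
        ests = est_acc[t.marker]
        if ests:
            mean = np.mean(ests, axis=0)
            row["est_a"] = mean[0]
            for h in range(H):
                row[f"est_ae_{h + 1}"] = mean[1 + h]
        rows.append(row)
    for t in truth.epistatic:
        key = (t.marker_i, t.marker_j)
        row = {
            "kind": "epistatic",
            "chrom": "",
            "markers": f"{t.marker_i}:{t.marker_j}",
            "n": scenario.n,
            "power_pct": 100.0 * detect_counts[key] / max(n_ok, 1),
            "n_detected": detect_counts[key],
            "par_a": t.aa,
            "est_a": np.nan,
        }
        for h in range(H):
            row[f"par_ae_{h + 1}"] = t.aae[h]
            row[f"est_ae_{h + 1}"] = np.nan
        ests = est_acc[key]
        if ests:
            mean = np.mean(ests, axis=0)
            row["est_a"] = mean[0]
            for h in range(H):
                row[f"est_ae_{h + 1}"] = mean[1 + h]
        rows.append(row)
    table = pd.DataFrame(rows)
    return PowerStudyResult(
        table=table, n_replicates=n_ok, n_failed=n_failed, thresholds=dict(thresholds)
    )
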