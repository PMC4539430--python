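"""Core domain types and genetics utilities.

This module houses the containers shared by every stage of the two-step
mapping pipeline — the genetic map, the coded genotype matrix, the
line-by-environment phenotype table and the full set of QTS model effects —
together with the elementary operations on them: biallelic genotype coding,
map-function arithmetic for recombinant inbred lines (RILs), and the
variance accounting used to report per-effect heritabilities.

Model
-----
The phenotype of line *k* in environment *h* is modelled as

    y_hk = mu + sum_i x_ik a_i + sum_{i<j} x_ik x_jk aa_ij
         + e_h + sum_i x_ik ae_hi + sum_{i<j} x_ik x_jk aae_hij + eps_hk

where ``x_ik`` is +1 for the homozygote of the high-frequency allele, -1 for
the homozygote of the low-frequency allele and 0 for a heterozygote; ``a``
is an additive effect, ``aa`` an additive-by-additive epistatic effect, and
``ae`` / ``aae`` their environment-specific deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "PhenotypeTable",
    "AdditiveTerm",
    "EpistaticTerm",
    "QTSEffectSet",
    "HeritabilityReport",
    "code_genotypes",
    "recombination_fraction",
    "ril_recombination_fraction",
    "partition_heritability",
]

MISSING_CALLS = {"NA", "N", "--", "..", "./.", ".", ""}


class GeneticMap:
    """Ordered marker positions (centimorgan) on one or more chromosomes.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``marker`` (unique ids), ``chrom`` and ``pos_cm``
        (non-negative, non-decreasing within a chromosome).
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chrom", "pos_cm"}
        if not required.issubset(table.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        table = table.reset_index(drop=True).copy()
        if table["marker"].duplicated().any():
            dup = table.loc[table["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id in map: {dup!r}")
        if (table["pos_cm"] < 0).any():
            raise ValueError("map positions must be non-negative")
        for chrom, sub in table.groupby("chrom", sort=False):
            if not sub["pos_cm"].is_monotonic_increasing:
                raise ValueError(f"positions on chromosome {chrom!r} must be non-decreasing")
        self.table = table

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 3,
        markers_per_chromosome: int = 175,
        spacing_cm: float = 1.0,
    ) -> "GeneticMap":
        """Evenly spaced markers, ``spacing_cm`` apart, on each chromosome.

        Marker ids are ``chr<C>_snp<I>`` with ``I`` 1-based, so the marker
        "SNP 28 on chromosome 1" is ``chr1_snp28``.
        """
        rows = []
        for c in range(1, n_chromosomes + 1):
            for i in range(1, markers_per_chromosome + 1):
                rows.append((f"chr{c}_snp{i}", str(c), (i - 1) * spacing_cm))
        return cls(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    def chromosomes(self) -> Iterable[tuple[str, pd.DataFrame]]:
        return self.table.groupby("chrom", sort=False)

    @classmethod
    def read(cls, path) -> "GeneticMap":
        """Read a tab-delimited map: marker_id, chromosome, position_cM (1 header line)."""
        df = pd.read_csv(path, sep="\t")
        df.columns = ["marker", "chrom", "pos_cm"] + list(df.columns[3:])
        df["chrom"] = df["chrom"].astype(str)
        return cls(df[["marker", "chrom", "pos_cm"]])

    def write(self, path) -> None:
        out = self.table.rename(
            columns={"marker": "marker_id", "chrom": "chromosome", "pos_cm": "position_cM"}
        )
        out.to_csv(path, sep="\t", index=False)


class GenotypeMatrix:
    """Coded genotypes for inbred lines: values in {+1, -1, 0, NaN}.

    ``+1`` is the homozygote of the high-frequency allele, ``-1`` the
    homozygote of the low-frequency allele, ``0`` a heterozygote and NaN a
    missing call.

    Parameters
    ----------
    line_ids : sequence of str
    markers : pandas.DataFrame
        One row per marker with columns ``marker``, ``chrom``, ``pos_cm``,
        ``allele_high``, ``allele_low``; row order matches the columns of
        ``values``.
    values : ndarray of shape (n_lines, n_markers)
    max_het_fraction : float, default 0.0
        Ceiling on the overall fraction of heterozygote (0) codes; the
        default reflects fully inbred RILs.
    max_missing_fraction : float, default 0.2
        Per-marker ceiling on the missing fraction.
    """

    def __init__(
        self,
        line_ids: Sequence[str],
        markers: pd.DataFrame,
        values: np.ndarray,
        max_het_fraction: float = 0.0,
        max_missing_fraction: float = 0.2,
    ):
        values = np.asarray(values, dtype=float)
        line_ids = np.asarray(line_ids, dtype=object)
        if values.ndim != 2 or values.shape != (len(line_ids), len(markers)):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"{len(line_ids)} lines x {len(markers)} markers"
            )
        finite = values[np.isfinite(values)]
        if finite.size and not np.isin(finite, (-1.0, 0.0, 1.0)).all():
            raise ValueError("coded genotypes must be in {+1, -1, 0, NaN}")
        if finite.size:
            het = float(np.mean(finite == 0.0))
            if het > max_het_fraction + 1e-12:
                raise ValueError(
                    f"heterozygote fraction {het:.3f} exceeds ceiling {max_het_fraction}"
                )
        miss = np.mean(~np.isfinite(values), axis=0)
        if (miss > max_missing_fraction + 1e-12).any():
            worst = markers["marker"].iloc[int(np.argmax(miss))]
            raise ValueError(
                f"marker {worst!r} missing fraction {miss.max():.3f} exceeds "
                f"ceiling {max_missing_fraction}"
            )
        self.line_ids = line_ids
        self.markers = markers.reset_index(drop=True)
        self.values = values
        self._index = {m: i for i, m in enumerate(self.markers["marker"])}
        if len(self._index) != len(self.markers):
            raise ValueError("marker ids must be unique")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["marker"].to_numpy()

    def marker_index(self, marker: str) -> int:
        try:
            return self._index[marker]
        except KeyError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.marker_index(marker)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)


class PhenotypeTable:
    """Trait values per line and environment (wide layout, NaN = missing)."""

    def __init__(self, line_ids: Sequence[str], env_ids: Sequence[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        line_ids = np.asarray(line_ids, dtype=object)
        env_ids = np.asarray(env_ids, dtype=object)
        if len(env_ids) < 1:
            raise ValueError("at least one environment is required")
        if values.shape != (len(line_ids), len(env_ids)):
            raise ValueError("phenotype values shape inconsistent with ids")
        self.line_ids = line_ids
        self.env_ids = env_ids
        self.values = values

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_env(self) -> int:
        return len(self.env_ids)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "PhenotypeTable":
        """Build from a long table with columns line_id, environment, value."""
        dup = df.duplicated(subset=["line_id", "environment"])
        if dup.any():
            pair = df.loc[dup, ["line_id", "environment"]].iloc[0]
            raise ValueError(
                f"duplicate phenotype row for line {pair['line_id']!r} in "
                f"environment {pair['environment']!r}"
            )
        wide = df.pivot(index="line_id", columns="environment", values="value")
        return cls(wide.index.to_numpy(), wide.columns.to_numpy(), wide.to_numpy())

    def to_long(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.line_ids, columns=self.env_ids)
        long = df.reset_index(names="line_id").melt(
            id_vars="line_id", var_name="environment", value_name="value"
        )
        return long.sort_values(["environment", "line_id"], kind="stable").reset_index(drop=True)

    def aligned_to(self, line_ids: Sequence[str]) -> np.ndarray:
        """Values reordered to the given line ids (all must be present)."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        missing = [l for l in line_ids if l not in pos]
        if missing:
            raise ValueError(f"phenotypes missing for lines: {missing[:5]}")
        idx = np.array([pos[l] for l in line_ids])
        return self.values[idx]


@dataclass
class AdditiveTerm:
    """Additive effect of one marker plus its environment interactions."""

    marker: str
    a: float
    ae: np.ndarray  # length H, environment-specific additive deviations

    def __post_init__(self):
        self.ae = np.asarray(self.ae, dtype=float)


@dataclass
class EpistaticTerm:
    """Additive-by-additive effect of an ordered marker pair (i < j)."""

    marker_i: str
    marker_j: str
    aa: float
    aae: np.ndarray  # length H

    def __post_init__(self):
        self.aae = np.asarray(self.aae, dtype=float)
        if self.marker_i == self.marker_j:
            raise ValueError("epistatic pair must involve two distinct markers")
        if str(self.marker_j) < str(self.marker_i):
            raise ValueError(
                f"epistatic pair ({self.marker_i}, {self.marker_j}) must be ordered i < j"
            )


@dataclass
class QTSEffectSet:
    """All parameters of the QTS mixed model, in trait units.

    Used both as the simulation truth and as an estimate container. With the
    sum-to-zero convention enabled (default), every environment-interaction
    vector must sum to zero across environments, which is how interaction
    effects are identifiable separately from the main effect.
    """

    mu: float = 0.0
    additive: list[AdditiveTerm] = field(default_factory=list)
    epistatic: list[EpistaticTerm] = field(default_factory=list)
    env_effects: np.ndarray | None = None  # e_h, length H; None = not fixed
    sigma2_eps: float = 0.0
    n_env: int = 1
    sum_to_zero: bool = True

    def __post_init__(self):
        if self.env_effects is not None:
            self.env_effects = np.asarray(self.env_effects, dtype=float)
            if len(self.env_effects) != self.n_env:
                raise ValueError("env_effects length must equal n_env")
        if self.sigma2_eps < 0:
            raise ValueError("residual variance must be non-negative")
        for t in self.additive:
            if len(t.ae) != self.n_env:
                raise ValueError(f"ae vector for {t.marker} must have length {self.n_env}")
        for t in self.epistatic:
            if len(t.aae) != self.n_env:
                raise ValueError(
                    f"aae vector for ({t.marker_i},{t.marker_j}) must have length {self.n_env}"
                )
        seen = set()
        for t in self.epistatic:
            key = (t.marker_i, t.marker_j)
            if key in seen:
                raise ValueError(f"duplicate epistatic pair {key}")
            seen.add(key)
        if self.sum_to_zero:
            for t in self.additive:
                if abs(t.ae.sum()) > 1e-8 * max(1.0, np.abs(t.ae).max()):
                    raise ValueError(f"ae for {t.marker} violates the sum-to-zero convention")
            for t in self.epistatic:
                if abs(t.aae.sum()) > 1e-8 * max(1.0, np.abs(t.aae).max()):
                    raise ValueError(
                        f"aae for ({t.marker_i},{t.marker_j}) violates sum-to-zero"
                    )

    def markers(self) -> list[str]:
        out = [t.marker for t in self.additive]
        for t in self.epistatic:
            out.extend([t.marker_i, t.marker_j])
        return sorted(set(out))


@dataclass
class HeritabilityReport:
    """Per-effect and total heritability, as percent of phenotypic variance."""

    components: pd.DataFrame  # columns: effect, markers, environment, h2_pct
    total_h2_pct: float

    def __post_init__(self):
        h2 = self.components["h2_pct"].to_numpy()
        if ((h2 < -1e-9) | (h2 > 100 + 1e-9)).any():
            raise ValueError("component heritabilities must lie in [0, 100]")
        if not (-1e-9 <= self.total_h2_pct <= 100 + 1e-9):
            raise ValueError("total heritability must lie in [0, 100]")


# ---------------------------------------------------------------------------
# genotype coding


def _parse_call(call) -> tuple[str, str] | None:
    """Split a diploid call string into its two alleles; None if missing."""
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return None
    s = str(call).strip().upper()
    if s in MISSING_CALLS:
        return None
    for sep in ("/", "|"):
        if sep in s:
            a, b = s.split(sep, 1)
            return a.strip(), b.strip()
    if len(s) == 2:
        return s[0], s[1]
    raise ValueError(f"cannot parse genotype call {call!r}")


def code_genotypes(
    raw_calls: pd.DataFrame,
    markers: pd.DataFrame | None = None,
    max_het_fraction: float = 1.0,
    max_missing_fraction: float = 1.0,
) -> GenotypeMatrix:
    """Code biallelic calls into the {+1, -1, 0} additive scale.

    The homozygote of the higher-frequency allele is coded +1, the
    homozygote of the lower-frequency allele -1, heterozygotes 0 and missing
    calls NaN. Allele-frequency ties are broken lexicographically: the
    alphabetically earlier allele is treated as high-frequency.

    Parameters
    ----------
    raw_calls : pandas.DataFrame
        Lines in the index, markers in the columns, cells like ``"GG"``,
        ``"G/A"`` or ``"NA"``.
    markers : pandas.DataFrame, optional
        Marker metadata (``marker``, ``chrom``, ``pos_cm``) in column order
        of ``raw_calls``; synthesized if omitted.

    Raises
    ------
    ValueError
        If a marker carries more than two alleles. Monomorphic markers are
        excluded with a logged warning rather than raising.
    """
    if markers is None:
        markers = pd.DataFrame(
            {"marker": raw_calls.columns, "chrom": "0", "pos_cm": np.arange(raw_calls.shape[1], dtype=float)}
        )
    markers = markers.reset_index(drop=True)
    kept_rows, cols = [], []
    n_mono = 0
    for jm, marker in enumerate(raw_calls.columns):
        calls = [_parse_call(c) for c in raw_calls[marker]]
        counts: dict[str, int] = {}
        for pair in calls:
            if pair is None:
                continue
            for al in pair:
                counts[al] = counts.get(al, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise ValueError(f"marker {marker!r} has more than two alleles: {alleles}")
        if len(alleles) < 2:
            n_mono += 1
            logger.warning("marker %r is monomorphic; excluded from the coded matrix", marker)
            continue
        # ties: lexicographically earlier allele wins the +1 (high-frequency) slot
        hi, lo = sorted(alleles, key=lambda al: (-counts[al], al))
        col = np.full(len(calls), np.nan)
        for k, pair in enumerate(calls):
            if pair is None:
                continue
            if pair[0] != pair[1]:
                col[k] = 0.0
            elif pair[0] == hi:
                col[k] = 1.0
            else:
                col[k] = -1.0
        row = markers.iloc[jm].to_dict()
        row.setdefault("marker", marker)
        row["allele_high"], row["allele_low"] = hi, lo
        kept_rows.append(row)
        cols.append(col)
    if n_mono:
        logger.warning("%d monomorphic marker(s) excluded", n_mono)
    if not cols:
        raise ValueError("no polymorphic biallelic markers remain after coding")
    meta = pd.DataFrame(kept_rows)
    values = np.column_stack(cols)
    return GenotypeMatrix(
        list(raw_calls.index.astype(str)),
        meta,
        values,
        max_het_fraction=max_het_fraction,
        max_missing_fraction=max_missing_fraction,
    )


def decode_genotypes(G: GenotypeMatrix) -> pd.DataFrame:
    """Inverse of :func:`code_genotypes` for homozygous calls (round-trip aid)."""
    out = {}
    for j, row in G.markers.iterrows():
        hi, lo = row["allele_high"], row["allele_low"]
        col = G.values[:, j]
        calls = np.where(col == 1.0, hi + hi, np.where(col == -1.0, lo + lo, hi + lo))
        calls = np.where(np.isfinite(col), calls, "NA")
        out[row["marker"]] = calls
    return pd.DataFrame(out, index=G.line_ids)


# ---------------------------------------------------------------------------
# map functions


def recombination_fraction(d):
    """Haldane map function: distance in cM to single-meiosis recombination.

    ``r = (1 - exp(-2 d / 100)) / 2``, assuming no crossover interference.
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def ril_recombination_fraction(r):
    """Recombination between fixed RIL genotypes after repeated selfing.

    For a single-meiosis fraction ``r`` the expected fraction of
    recombinant RILs at fixation is ``R = 2r / (1 + 2r)``.
    """
    r = np.asarray(r, dtype=float)
    if ((r < 0) | (r > 0.5)).any():
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


# ---------------------------------------------------------------------------
# heritability accounting


def effect_contributions(
    effects: QTSEffectSet, G: GenotypeMatrix
) -> tuple[pd.DataFrame, np.ndarray]:
    """Fitted contribution of every elementary effect over the realized design.

    Returns a component table (one row per elementary effect: a, each ae_h,
    aa, each aae_h) and the matrix of per-cell contributions with shape
    (n_components, n_env * n_lines). The environment main effect is not a
    component (it is excluded from heritability numerators by convention).
    """
    n, H = G.n_lines, effects.n_env
    rows, mats = [], []

    def add(effect, markers, env, contrib):
        rows.append({"effect": effect, "markers": markers, "environment": env})
        mats.append(contrib.ravel())

    for t in effects.additive:
        x = G.column(t.marker)
        if not np.isfinite(x).all():
            raise ValueError(f"marker {t.marker} has missing codes; cannot partition variance")
        add("a", t.marker, "", np.tile(x * t.a, (H, 1)))
        for h in range(H):
            c = np.zeros((H, n))
            c[h] = x * t.ae[h]
            add(f"ae_{h + 1}", t.marker, str(h + 1), c)
    for t in effects.epistatic:
        xx = G.column(t.marker_i) * G.column(t.marker_j)
        if not np.isfinite(xx).all():
            raise ValueError(
                f"pair ({t.marker_i},{t.marker_j}) has missing codes; cannot partition variance"
            )
        add("aa", f"{t.marker_i}:{t.marker_j}", "", np.tile(xx * t.aa, (H, 1)))
        for h in range(H):
            c = np.zeros((H, n))
            c[h] = xx * t.aae[h]
            add(f"aae_{h + 1}", f"{t.marker_i}:{t.marker_j}", str(h + 1), c)
    table = pd.DataFrame(rows, columns=["effect", "markers", "environment"])
    mat = np.vstack(mats) if mats else np.empty((0, n * H))
    return table, mat


def genetic_variance(effects: QTSEffectSet, G: GenotypeMatrix) -> float:
    """Summed empirical variance of all genetic-term contributions."""
    _, mat = effect_contributions(effects, G)
    if mat.size == 0:
        return 0.0
    return float(np.sum(np.var(mat, axis=1)))


def partition_heritability(
    effects: QTSEffectSet,
    G: GenotypeMatrix,
    env_variance_policy: str = "exclude",
) -> HeritabilityReport:
    """Partition phenotypic variance into per-effect heritabilities.

    Each elementary effect's contribution is its fitted value over the
    realized design (all lines crossed with all environments); its
    heritability is that contribution's empirical variance divided by the
    modelled phenotypic variance, times 100. The total is the sum of the
    genetic components, so the accounting identity ``sum(h2) == total``
    holds exactly.

    Parameters
    ----------
    env_variance_policy : {"exclude", "denominator"}
        ``"exclude"`` (default) leaves the environment main effect out of
        both numerator and denominator; ``"denominator"`` adds the empirical
        variance of the fixed environment effects to the denominator only.
    """
    if env_variance_policy not in ("exclude", "denominator"):
        raise ValueError("env_variance_policy must be 'exclude' or 'denominator'")
    table, mat = effect_contributions(effects, G)
    var_terms = np.var(mat, axis=1) if mat.size else np.zeros(0)
    denom = float(var_terms.sum()) + float(effects.sigma2_eps)
    if env_variance_policy == "denominator" and effects.env_effects is not None:
        denom += float(np.var(np.repeat(effects.env_effects, G.n_lines)))
    if denom <= 0:
        raise ValueError("total modelled phenotypic variance is zero; cannot partition")
    table = table.copy()
    table["h2_pct"] = 100.0 * var_terms / denom
    return HeritabilityReport(components=table, total_h2_pct=float(table["h2_pct"].sum()))
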