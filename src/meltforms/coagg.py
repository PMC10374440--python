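"""Proteoform-proteoform co-aggregation analysis.

Interacting proteins often aggregate together upon heating, so their melting
curves coincide.  This module (i) expands a protein-protein interaction
annotation (STRING-style combined scores) to all pairs of detected
proteoform groups, (ii) tests each pair for co-aggregation per cell line by
comparing the Euclidean distance of the two melting curves against an
empirical null of randomly drawn non-annotated pairs, (iii) scores pairs
that co-aggregate in at least one cell line for *differential*
co-aggregation across cell lines with the robust order-statistic F

    F = (RSS_(n-1) - RSS_(2)) / RSS_(2),

where RSS_n = sum_k (x_k^A - x_k^B)^2 per cell line and the second-highest /
second-lowest order statistics discard one outlier on either end, and (iv)
ranks protein pairs by average curve distance for ROC-based PPI prediction
benchmarks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

from .data import FoldChangeTensor
from .detect import ProteoformAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "PfPfPair",
    "expand_ppi_to_proteoforms",
    "curve_distance",
    "pair_rss_per_line",
    "coaggregation_pvalues",
    "differential_coaggregation_f",
    "run_coaggregation",
    "ppi_prediction_ranking",
]

MIN_SHARED_TEMPS = 4


@dataclass
class PfPfPair:
    """One candidate proteoform-proteoform interaction (unordered)."""

    proteoform_a: str
    proteoform_b: str
    per_line_rss: np.ndarray | None = None  # NaN where not comparable
    per_line_pvalue: np.ndarray | None = None
    per_line_padj: np.ndarray | None = None
    eligible: bool = False  # significant co-aggregation in >= 1 cell line
    f_diff: float = float("nan")
    f_infinite: bool = False
    top_decile: bool = False
    extra: dict = field(default_factory=dict)

    def key(self) -> frozenset[str]:
        return frozenset({self.proteoform_a, self.proteoform_b})


def expand_ppi_to_proteoforms(
    ppi: pd.DataFrame,
    assignments: dict[str, ProteoformAssignment],
    min_score: float = 950.0,
) -> list[PfPfPair]:
    """Expand protein pairs with combined score >= *min_score* to proteoform pairs.

    A protein annotated with three proteoform groups interacting with one
    annotated with two yields all 3 x 2 combinations.  Pairs whose genes lack
    an assignment are skipped and counted.
    """
    required = {"gene_a", "gene_b", "combined_score"}
    if missing := required - set(ppi.columns):
        raise ValueError(f"ppi table missing columns: {sorted(missing)}")
    skipped = 0
    seen: set[frozenset[str]] = set()
    out: list[PfPfPair] = []
    for ga, gb, score in zip(ppi["gene_a"], ppi["gene_b"], ppi["combined_score"]):
        if score < min_score or ga == gb:
            continue
        if ga not in assignments or gb not in assignments:
            skipped += 1
            continue
        for (pa, _), (pb, _) in itertools.product(
            assignments[ga].groups, assignments[gb].groups
        ):
            k = frozenset({pa, pb})
            if k in seen:
                continue
            seen.add(k)
            a, b = sorted((pa, pb))
            out.append(PfPfPair(proteoform_a=a, proteoform_b=b))
    if skipped:
        logger.info("skipped %d PPI entries lacking proteoform assignments", skipped)
    return out


def curve_distance(xa: np.ndarray, xb: np.ndarray,
                   min_shared: int = MIN_SHARED_TEMPS) -> float:
    """Euclidean distance between two melting curves over shared temperatures."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    ok = np.isfinite(xa) & np.isfinite(xb)
    if ok.sum() < min_shared:
        return float("nan")
    return float(np.sqrt(np.sum((xa[ok] - xb[ok]) ** 2)))


def pair_rss_per_line(
    profiles: FoldChangeTensor, id_a: str, id_b: str,
    min_shared: int = MIN_SHARED_TEMPS,
) -> np.ndarray:
    """RSS_n = sum_k (x_k^A - x_k^B)^2 for every cell line (NaN if < min_shared)."""
    ia, ib = profiles.item_index(id_a), profiles.item_index(id_b)
    xa, xb = profiles.x[ia], profiles.x[ib]
    ok = np.isfinite(xa) & np.isfinite(xb)
    diff2 = np.where(ok, (np.nan_to_num(xa) - np.nan_to_num(xb)) ** 2, 0.0)
    rss = diff2.sum(axis=1)
    rss[ok.sum(axis=1) < min_shared] = np.nan
    return rss


def empirical_pvalue(observed: float, null_sorted: np.ndarray) -> float:
    """Pseudo-count empirical p-value for a small-is-significant statistic.

    p = (1 + #{null <= observed}) / (n_null + 1); attains 1/(n_null+1) when
    the observed distance beats every null draw and 1 when none beats it.
    """
    n_le = int(np.searchsorted(null_sorted, observed, side="right"))
    return (1 + n_le) / (len(null_sorted) + 1)


def _null_distances(
    profiles: FoldChangeTensor,
    line: int,
    annotated: set[frozenset[str]],
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Distances of uniformly sampled non-annotated proteoform pairs in one line."""
    P = profiles.n_items
    if P < 2:
        raise ValueError("need at least two proteoform profiles for the null")
    out = np.empty(n_null)
    filled = 0
    attempts = 0
    while filled < n_null and attempts < 50 * n_null:
        attempts += 1
        i, j = rng.integers(0, P, size=2)
        if i == j:
            continue
        if frozenset({profiles.ids[i], profiles.ids[j]}) in annotated:
            continue
        d = curve_distance(profiles.x[i, line], profiles.x[j, line])
        if np.isfinite(d):
            out[filled] = d
            filled += 1
    if filled < n_null:
        logger.warning("null pool for line %d truncated to %d draws", line, filled)
    return out[:filled]


def coaggregation_pvalues(
    pairs: list[PfPfPair],
    profiles: FoldChangeTensor,
    n_null: int = 10000,
    seed: int = 0,
    alpha: float = 0.1,
) -> list[PfPfPair]:
    """Empirical per-cell-line co-aggregation test with BH adjustment.

    The observed statistic is the Euclidean distance between the two curves;
    the null is the distance distribution of ``n_null`` random non-annotated
    proteoform pairs in the same cell line.  Small distances indicate
    co-aggregation: p = (1 + #{null <= observed}) / (n_null + 1).  P values
    are BH-adjusted across pairs within each cell line; a pair becomes
    *eligible* for the differential analysis if any line has p_adj < alpha.
    """
    rng = np.random.default_rng(seed)
    annotated = {p.key() for p in pairs}
    N = len(profiles.cell_lines)
    for p in pairs:
        p.per_line_rss = pair_rss_per_line(profiles, p.proteoform_a, p.proteoform_b)
        p.per_line_pvalue = np.full(N, np.nan)
        p.per_line_padj = np.full(N, np.nan)

    for n in range(N):
        null = _null_distances(profiles, n, annotated, n_null, rng)
        if len(null) == 0:
            logger.warning("no null distances for cell line %s",
                           profiles.cell_lines[n])
            continue
        null_sorted = np.sort(null)
        idx_with_obs = []
        for p in pairs:
            ia = profiles.item_index(p.proteoform_a)
            ib = profiles.item_index(p.proteoform_b)
            d = curve_distance(profiles.x[ia, n], profiles.x[ib, n])
            if not np.isfinite(d):
                continue
            p.per_line_pvalue[n] = empirical_pvalue(d, null_sorted)
            idx_with_obs.append(p)
        if idx_with_obs:
            pvals = np.array([p.per_line_pvalue[n] for p in idx_with_obs])
            padj = multipletests(pvals, method="fdr_bh")[1]
            for p, q in zip(idx_with_obs, padj):
                p.per_line_padj[n] = q

    for p in pairs:
        p.eligible = bool(np.any(p.per_line_padj < alpha))
    return pairs


def differential_coaggregation_f(per_line_rss: np.ndarray,
                                 min_lines: int = 4) -> tuple[float, bool]:
    """Robust multigroup F = (RSS_(n-1) - RSS_(2)) / RSS_(2).

    Sorting the per-cell-line RSS values ascending, the statistic contrasts
    the second highest against the second lowest, so a single extreme cell
    line on either end cannot create a hit.  Returns (F, is_infinite);
    RSS_(2) = 0 yields an infinite sentinel with the flag set.  Requires RSS
    defined in >= ``min_lines`` cell lines.
    """
    vals = np.sort(np.asarray(per_line_rss, dtype=float)[
        np.isfinite(per_line_rss)])
    if len(vals) < min_lines:
        raise ValueError(f"need RSS in >= {min_lines} cell lines")
    second_lowest = vals[1]
    second_highest = vals[-2]
    if second_lowest == 0.0:
        return float("inf"), True
    return float((second_highest - second_lowest) / second_lowest), False


def run_coaggregation(
    profiles: FoldChangeTensor,
    ppi: pd.DataFrame,
    assignments: dict[str, ProteoformAssignment],
    min_score: float = 950.0,
    n_null: int = 10000,
    seed: int = 0,
    alpha: float = 0.1,
    top_fraction: float = 0.10,
    min_lines: int = 4,
) -> pd.DataFrame:
    """Full co-aggregation pipeline: expand, test, score, rank.

    Returns one row per proteoform pair with per-line minima of p and p_adj,
    the Eq.-style differential F, and a flag for the top decile of F among
    eligible pairs.
    """
    pairs = expand_ppi_to_proteoforms(ppi, assignments, min_score=min_score)
    pairs = coaggregation_pvalues(pairs, profiles, n_null=n_null, seed=seed,
                                  alpha=alpha)
    scored: list[PfPfPair] = []
    for p in pairs:
        if not p.eligible:
            continue
        try:
            p.f_diff, p.f_infinite = differential_coaggregation_f(
                p.per_line_rss, min_lines=min_lines)
        except ValueError:
            continue
        scored.append(p)
    if scored:
        fs = np.array([p.f_diff for p in scored])
        cutoff = float(np.percentile(fs[np.isfinite(fs)], 100 * (1 - top_fraction))) \
            if np.isfinite(fs).any() else np.inf
        for p in scored:
            p.top_decile = bool(p.f_diff >= cutoff)
    return pd.DataFrame(
        [
            {
                "proteoform_a": p.proteoform_a,
                "proteoform_b": p.proteoform_b,
                "n_lines_with_rss": int(np.isfinite(p.per_line_rss).sum()),
                "min_pvalue": np.nanmin(p.per_line_pvalue)
                if np.isfinite(p.per_line_pvalue).any() else np.nan,
                "min_padj": np.nanmin(p.per_line_padj)
                if np.isfinite(p.per_line_padj).any() else np.nan,
                "eligible": p.eligible,
                "F_diff": p.f_diff,
                "F_infinite": p.f_infinite,
                "top_decile": p.top_decile,
            }
            for p in pairs
        ]
    )


def ppi_prediction_ranking(
    protein_profiles: FoldChangeTensor,
    positives: set[frozenset[str]],
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, float]:
    """Rank protein pairs by average curve distance and score PPI prediction.

    For every pair of quantified proteins the Euclidean distance between
    their melting curves is averaged over cell lines where both are
    quantified; pairs are ranked ascending (small distance = predicted
    interaction).  Pairs in *positives* are labeled 1, all other
    (non-annotated) pairs 0, and a ROC curve/AUC is computed on the negated
    distance.  Returns (ranked table, fpr, tpr, auc).
    """
    ids = protein_profiles.ids
    if len(ids) < 2:
        raise ValueError("need at least two protein profiles")
    rows = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        ds = [
            curve_distance(protein_profiles.x[i, n], protein_profiles.x[j, n])
            for n in range(len(protein_profiles.cell_lines))
        ]
        ds = [d for d in ds if np.isfinite(d)]
        if not ds:
            continue
        pair = frozenset({ids[i], ids[j]})
        rows.append(
            {
                "protein_a": min(ids[i], ids[j]),
                "protein_b": max(ids[i], ids[j]),
                "avg_distance": float(np.mean(ds)),
                "label": int(pair in positives),
            }
        )
    table = pd.DataFrame(rows).sort_values("avg_distance").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if table.empty or table["label"].sum() == 0:
        raise ValueError("no positive pairs among scored pairs; AUC undefined")
    if (table["label"] == 0).sum() == 0:
        raise ValueError("no negative pairs among scored pairs; AUC undefined")
    fpr, tpr, _ = roc_curve(table["label"], -table["avg_distance"])
    return table, fpr, tpr, float(_sk_auc(fpr, tpr))
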