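"""Association of proteoform thermal stability with drug sensitivity.

Per-cell-line thermal stability of a proteoform is summarized by the area
under its fitted melting curve (AUC); selective drug sensitivity scores
(sDSS, one value per cell line and drug) quantify drug response.  For every
(proteoform, drug) combination with enough overlapping cell lines an
ordinary least-squares line of sDSS on AUC is fit; the slope's two-sided
t-test p-values are jointly Benjamini-Hochberg adjusted across all tests,
and associations with adjusted p < 0.1 are flagged significant.  Drugs are
pre-filtered to those with a minimal effect on at least one cell line
(max sDSS >= 6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["AssociationRecord", "filter_drugs", "associate"]


@dataclass
class AssociationRecord:
    proteoform_id: str
    drug_id: str
    n: int
    slope: float
    pearson_r: float
    p_value: float
    p_adj: float = float("nan")
    significant: bool = False


def filter_drugs(sdss: pd.DataFrame, min_max_sdss: float = 6.0) -> pd.DataFrame:
    """Keep drugs whose maximum sDSS over cell lines reaches *min_max_sdss*.

    ``sdss`` is a cell line x drug matrix (rows = cell lines).
    """
    if sdss.empty:
        raise ValueError("empty sDSS matrix")
    keep = sdss.columns[sdss.max(axis=0, skipna=True) >= min_max_sdss]
    return sdss[keep]


def associate(
    auc: pd.DataFrame,
    sdss: pd.DataFrame,
    exclude_cell_lines: list[str] | tuple[str, ...] = (),
    min_lines: int = 3,
    alpha: float = 0.1,
) -> list[AssociationRecord]:
    """OLS association of melting AUC with sDSS for all proteoform x drug tests.

    ``auc`` is a proteoform x cell line matrix (typically restricted to
    differentially melting proteoforms); ``sdss`` is a cell line x drug
    matrix.  Listed cell lines are excluded before testing.  Tests with
    fewer than *min_lines* overlapping cell lines or a zero-variance vector
    are recorded as untestable and skipped from the BH family.
    """
    drop = set(exclude_cell_lines)
    lines = [c for c in auc.columns if c in set(sdss.index) and c not in drop]
    if not lines:
        raise ValueError("no overlapping cell lines between AUC and sDSS tables")
    records: list[AssociationRecord] = []
    n_untestable = 0
    for pf in auc.index:
        x_all = auc.loc[pf, lines].to_numpy(dtype=float)
        for drug in sdss.columns:
            y_all = sdss.loc[lines, drug].to_numpy(dtype=float)
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            n = int(ok.sum())
            if n < min_lines:
                n_untestable += 1
                continue
            x, y = x_all[ok], y_all[ok]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                n_untestable += 1
                continue
            res = stats.linregress(x, y)
            records.append(
                AssociationRecord(
                    proteoform_id=str(pf),
                    drug_id=str(drug),
                    n=n,
                    slope=float(res.slope),
                    pearson_r=float(res.rvalue),
                    p_value=float(res.pvalue),
                )
            )
    if n_untestable:
        logger.info("skipped %d untestable proteoform x drug combinations",
                    n_untestable)
    if records:
        padj = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for r, q in zip(records, padj):
            r.p_adj = float(q)
            r.significant = bool(q < alpha)
    return records


def associations_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "proteoform_id": r.proteoform_id,
                "drug_id": r.drug_id,
                "n": r.n,
                "slope": r.slope,
                "pearson_r": r.pearson_r,
                "p_value": r.p_value,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in records
        ]
    )
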