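"""Data model and I/O for deep thermal proteome profiling (TPP) experiments.

A deep TPP experiment measures, for every identified peptide, the soluble
reporter-ion signal remaining after heating aliquots of each cell line to a
gradient of temperatures.  This module holds the two core containers --
:class:`PeptideQuantMatrix` (raw summed reporter-ion intensities on a
peptide x cell-line x temperature grid) and :class:`FoldChangeTensor`
(relative melting curves, normalized to the lowest temperature) -- together
with readers/writers for long and wide tab-separated tables, per-temperature
normalization, fold-change computation and peptide-level filters.

Missing values are always represented as NaN, never as zeros; zero
intensities in the input are treated as missing for fold-change purposes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideQuantMatrix",
    "FoldChangeTensor",
    "summarize_psms_to_peptides",
    "normalize_per_temperature",
    "to_fold_changes",
    "filter_min_cell_lines",
    "gene_ambiguity_ratio",
    "read_peptides_long",
    "write_peptides_long",
    "read_peptides_wide",
    "write_peptides_wide",
]


def _check_grid(temperatures: np.ndarray) -> None:
    if temperatures.ndim != 1 or len(temperatures) < 1:
        raise ValueError("temperature grid must be a non-empty 1-D array")
    if np.any(np.diff(temperatures) <= 0):
        raise ValueError("temperatures must be strictly increasing")


@dataclass
class PeptideQuantMatrix:
    """Summed reporter-ion intensities on a peptide x cell line x temperature grid.

    Attributes
    ----------
    peptide_ids
        Peptide keys (sequence plus modification state).
    gene_symbols
        One frozenset of gene symbols per peptide (>= 1 symbol each).
    intensity
        Array of shape (peptides, cell_lines, temperatures); NaN = missing.
    temperatures
        Strictly increasing grid in degrees Celsius.
    cell_lines
        Cell-line identifiers.
    """

    peptide_ids: list[str]
    gene_symbols: list[frozenset[str]]
    intensity: np.ndarray
    temperatures: np.ndarray
    cell_lines: list[str]

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        _check_grid(self.temperatures)
        P, N, K = len(self.peptide_ids), len(self.cell_lines), len(self.temperatures)
        if self.intensity.shape != (P, N, K):
            raise ValueError(
                f"intensity shape {self.intensity.shape} != ({P}, {N}, {K})"
            )
        if len(self.gene_symbols) != P:
            raise ValueError("one gene-symbol set required per peptide")
        for g in self.gene_symbols:
            if not g:
                raise ValueError("every peptide needs at least one gene symbol")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensity < 0):
                raise ValueError("intensities must be non-negative or missing")

    @property
    def is_ambiguous(self) -> np.ndarray:
        """Boolean flag per peptide: maps to more than one gene symbol."""
        return np.array([len(g) > 1 for g in self.gene_symbols])

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)

    def subset(self, indices: np.ndarray) -> "PeptideQuantMatrix":
        idx = np.asarray(indices)
        return PeptideQuantMatrix(
            peptide_ids=[self.peptide_ids[i] for i in idx],
            gene_symbols=[self.gene_symbols[i] for i in idx],
            intensity=self.intensity[idx].copy(),
            temperatures=self.temperatures.copy(),
            cell_lines=list(self.cell_lines),
        )

    def peptides_of_gene(self, gene: str) -> list[int]:
        """Indices of peptides whose symbol set contains *gene*."""
        hits = [i for i, g in enumerate(self.gene_symbols) if gene in g]
        if not hits:
            raise KeyError(f"gene symbol not found: {gene!r}")
        return hits


@dataclass
class FoldChangeTensor:
    """Relative melting curves x[i, n, k] for item i, cell line n, temperature k.

    Fold changes are relative to the lowest temperature of the grid, so the
    reference column is 1 wherever defined (simulated tensors carry
    measurement noise on every channel, including the reference).  Items may
    be peptides or summarized proteoform groups; ``gene_symbols`` carries the
    mapping needed to build per-gene peptide graphs.
    """

    ids: list[str]
    x: np.ndarray
    temperatures: np.ndarray
    cell_lines: list[str]
    gene_symbols: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        _check_grid(self.temperatures)
        P, N, K = len(self.ids), len(self.cell_lines), len(self.temperatures)
        if self.x.shape != (P, N, K):
            raise ValueError(f"x shape {self.x.shape} != ({P}, {N}, {K})")
        if not self.gene_symbols:
            self.gene_symbols = [frozenset({i}) for i in self.ids]
        if len(self.gene_symbols) != P:
            raise ValueError("one gene-symbol set required per item")
        with np.errstate(invalid="ignore"):
            if np.any(self.x < 0):
                raise ValueError("fold changes must be non-negative or missing")

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.x)

    @property
    def is_ambiguous(self) -> np.ndarray:
        return np.array([len(g) > 1 for g in self.gene_symbols])

    @property
    def n_items(self) -> int:
        return len(self.ids)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.x.shape

    def subset(self, indices) -> "FoldChangeTensor":
        idx = np.asarray(indices)
        return FoldChangeTensor(
            ids=[self.ids[i] for i in idx],
            x=self.x[idx].copy(),
            temperatures=self.temperatures.copy(),
            cell_lines=list(self.cell_lines),
            gene_symbols=[self.gene_symbols[i] for i in idx],
        )

    def genes(self) -> list[str]:
        """Sorted list of all gene symbols appearing in the tensor."""
        out: set[str] = set()
        for g in self.gene_symbols:
            out |= g
        return sorted(out)

    def item_index(self, item_id: str) -> int:
        try:
            return self.ids.index(item_id)
        except ValueError:
            raise KeyError(f"item not found: {item_id!r}") from None


# ---------------------------------------------------------------------------
# construction and transforms
# ---------------------------------------------------------------------------

def summarize_psms_to_peptides(psm_table: pd.DataFrame) -> PeptideQuantMatrix:
    """Sum PSM-level reporter-ion signal to peptide level.

    Parameters
    ----------
    psm_table
        Long table with columns ``peptide``, ``genes`` (semicolon-separated
        symbols), ``cell_line``, ``temperature``, ``intensity`` (a ``psm_id``
        column is permitted and ignored).  Each row is one PSM observation in
        one reporter channel.

    Rows with negative signal are rejected with a diagnostic.  Peptides whose
    rows disagree on gene annotation receive the union of symbols and are
    flagged ambiguous if the union has more than one element.
    """
    required = {"peptide", "genes", "cell_line", "temperature", "intensity"}
    missing = required - set(psm_table.columns)
    if missing:
        raise ValueError(f"psm_table missing columns: {sorted(missing)}")
    tbl = psm_table.copy()
    neg = tbl["intensity"] < 0
    if neg.any():
        logger.warning("rejecting %d PSM rows with negative signal", int(neg.sum()))
        tbl = tbl[~neg]
    if tbl.empty:
        raise ValueError("no valid PSM rows")

    temperatures = np.sort(tbl["temperature"].unique().astype(float))
    cell_lines = sorted(tbl["cell_line"].astype(str).unique())
    t_idx = {t: k for k, t in enumerate(temperatures)}
    n_idx = {c: n for n, c in enumerate(cell_lines)}

    gene_map: dict[str, set[str]] = {}
    for pep, genes in zip(tbl["peptide"], tbl["genes"]):
        syms = {g for g in str(genes).split(";") if g}
        gene_map.setdefault(str(pep), set()).update(syms)
    peptide_ids = sorted(gene_map)
    p_idx = {p: i for i, p in enumerate(peptide_ids)}

    intensity = np.full((len(peptide_ids), len(cell_lines), len(temperatures)), np.nan)
    for pep, cl, temp, sig in zip(
        tbl["peptide"], tbl["cell_line"], tbl["temperature"], tbl["intensity"]
    ):
        i, n, k = p_idx[str(pep)], n_idx[str(cl)], t_idx[float(temp)]
        if np.isnan(sig):
            continue
        if np.isnan(intensity[i, n, k]):
            intensity[i, n, k] = sig
        else:
            intensity[i, n, k] += sig

    return PeptideQuantMatrix(
        peptide_ids=peptide_ids,
        gene_symbols=[frozenset(gene_map[p]) for p in peptide_ids],
        intensity=intensity,
        temperatures=temperatures,
        cell_lines=cell_lines,
    )


def normalize_per_temperature(matrix: PeptideQuantMatrix) -> PeptideQuantMatrix:
    """Equalize channel medians across samples, one temperature at a time.

    Within each temperature channel, every sample (cell line) is rescaled by
    a multiplicative factor -- an affine shift in log space, hence monotone
    and rank-preserving -- so that the post-normalization median intensity is
    the same for all samples sharing that channel (the geometric mean of the
    per-sample medians).  This stands in for variance-stabilizing
    normalization at the scale the downstream fold changes consume.
    Channels with no data in any sample are left untouched with a warning.
    """
    out = matrix.intensity.copy()
    K = len(matrix.temperatures)
    for k in range(K):
        ch = out[:, :, k]  # peptides x samples
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            medians = np.nanmedian(ch, axis=0)
        have = np.isfinite(medians) & (medians > 0)
        if not have.any():
            logger.warning(
                "temperature channel %.6g has no data; left unnormalized",
                matrix.temperatures[k],
            )
            continue
        target = np.exp(np.mean(np.log(medians[have])))
        scale = np.ones(ch.shape[1])
        scale[have] = target / medians[have]
        out[:, :, k] = ch * scale[np.newaxis, :]
    return replace(matrix, intensity=out)


def to_fold_changes(matrix: PeptideQuantMatrix) -> FoldChangeTensor:
    """Convert intensities to fold changes relative to the lowest temperature.

    For each (peptide, cell line) series the value at the first (lowest)
    temperature is the reference; x[i, n, k] = I[i, n, k] / I[i, n, 0].
    Series whose reference is missing or zero are fully masked (zeros are
    treated as missing, never divided by); the number of masked series is
    logged.
    """
    I = matrix.intensity
    ref = I[:, :, 0]
    bad = ~np.isfinite(ref) | (ref <= 0)
    n_bad = int(bad.sum())
    if n_bad:
        logger.info("masking %d (peptide, cell line) series lacking a reference", n_bad)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = I / ref[:, :, np.newaxis]
    x[bad, :] = np.nan
    return FoldChangeTensor(
        ids=list(matrix.peptide_ids),
        x=x,
        temperatures=matrix.temperatures.copy(),
        cell_lines=list(matrix.cell_lines),
        gene_symbols=list(matrix.gene_symbols),
    )


def filter_min_cell_lines(t: FoldChangeTensor, min_lines: int = 2) -> FoldChangeTensor:
    """Keep items quantified (any non-masked value) in >= *min_lines* cell lines."""
    lines_per_item = t.valid_mask.any(axis=2).sum(axis=1)
    keep = np.flatnonzero(lines_per_item >= min_lines)
    return t.subset(keep)


def gene_ambiguity_ratio(gene: str, matrix: PeptideQuantMatrix | FoldChangeTensor) -> float:
    """Fraction of a gene's peptides that also map to other genes.

    ambiguous / (specific + ambiguous) over the peptides mapped to *gene*;
    a peptide is ambiguous if its symbol set has more than one element.
    """
    hits = [g for g in matrix.gene_symbols if gene in g]
    if not hits:
        raise KeyError(f"gene symbol not found: {gene!r}")
    n_amb = sum(len(g) > 1 for g in hits)
    return n_amb / len(hits)


# ---------------------------------------------------------------------------
# I/O: long and wide tab-separated dialects
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["peptide", "genes", "cell_line", "temperature", "intensity"]


def matrix_to_long_frame(matrix: PeptideQuantMatrix) -> pd.DataFrame:
    """Full-grid long table; missing intensities become NaN rows."""
    P, N, K = matrix.intensity.shape
    pep = np.repeat(matrix.peptide_ids, N * K)
    genes = np.repeat([";".join(sorted(g)) for g in matrix.gene_symbols], N * K)
    cl = np.tile(np.repeat(matrix.cell_lines, K), P)
    temp = np.tile(matrix.temperatures, P * N)
    return pd.DataFrame(
        {
            "peptide": pep,
            "genes": genes,
            "cell_line": cl,
            "temperature": temp,
            "intensity": matrix.intensity.ravel(),
        }
    )


def write_peptides_long(matrix: PeptideQuantMatrix, path) -> None:
    """Write the long-format TSV dialect (missing encoded as ``NA``)."""
    frame = matrix_to_long_frame(matrix)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_peptides_long(path) -> PeptideQuantMatrix:
    """Read the long-format TSV dialect (missing = empty field or ``NA``).

    The grid (temperatures, cell lines) is the union over all rows, so
    channels written as all-missing survive a round trip.  Duplicate rows for
    one grid cell are summed, which makes the reader double as a PSM-level
    ingest path.
    """
    try:
        tbl = pd.read_csv(path, sep="\t", na_values=["NA", ""], keep_default_na=True)
    except Exception as exc:  # surface the file name in parse failures
        raise ValueError(f"cannot parse peptide table {path}: {exc}") from exc
    missing = set(LONG_COLUMNS) - set(tbl.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if tbl.empty:
        raise ValueError(f"{path}: empty table")

    temperatures = np.sort(tbl["temperature"].astype(float).unique())
    cell_lines = sorted(tbl["cell_line"].astype(str).unique())
    t_idx = {t: k for k, t in enumerate(temperatures)}
    n_idx = {c: n for n, c in enumerate(cell_lines)}
    gene_map: dict[str, set[str]] = {}
    for pep, genes in zip(tbl["peptide"], tbl["genes"]):
        syms = {g for g in str(genes).split(";") if g}
        gene_map.setdefault(str(pep), set()).update(syms)
    peptide_ids = sorted(gene_map)
    p_idx = {p: i for i, p in enumerate(peptide_ids)}
    intensity = np.full((len(peptide_ids), len(cell_lines), len(temperatures)), np.nan)
    for pep, cl, temp, sig in zip(
        tbl["peptide"], tbl["cell_line"], tbl["temperature"], tbl["intensity"]
    ):
        if pd.isna(sig):
            continue
        if sig < 0:
            raise ValueError(f"{path}: negative intensity for peptide {pep!r}")
        i, n, k = p_idx[str(pep)], n_idx[str(cl)], t_idx[float(temp)]
        if np.isnan(intensity[i, n, k]):
            intensity[i, n, k] = sig
        else:
            intensity[i, n, k] += sig
    return PeptideQuantMatrix(
        peptide_ids=peptide_ids,
        gene_symbols=[frozenset(gene_map[p]) for p in peptide_ids],
        intensity=intensity,
        temperatures=temperatures,
        cell_lines=cell_lines,
    )


def write_peptides_wide(matrix: PeptideQuantMatrix, path) -> None:
    """Wide dialect: one ``cell_line:temperature`` column per channel."""
    P, N, K = matrix.intensity.shape
    cols = {
        "peptide": matrix.peptide_ids,
        "genes": [";".join(sorted(g)) for g in matrix.gene_symbols],
    }
    for n, cl in enumerate(matrix.cell_lines):
        for k, t in enumerate(matrix.temperatures):
            cols[f"{cl}:{t:g}"] = matrix.intensity[:, n, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, na_rep="NA",
                              float_format="%.17g")


def read_peptides_wide(path) -> PeptideQuantMatrix:
    tbl = pd.read_csv(path, sep="\t", na_values=["NA", ""], keep_default_na=True)
    if "peptide" not in tbl.columns or "genes" not in tbl.columns:
        raise ValueError(f"{path}: wide table needs 'peptide' and 'genes' columns")
    channels = [c for c in tbl.columns if c not in ("peptide", "genes")]
    parsed = []
    for c in channels:
        cl, _, t = c.rpartition(":")
        if not cl:
            raise ValueError(f"{path}: channel column {c!r} is not 'cell_line:temperature'")
        parsed.append((cl, float(t)))
    cell_lines = sorted({cl for cl, _ in parsed})
    temperatures = np.sort(np.unique([t for _, t in parsed]))
    t_idx = {t: k for k, t in enumerate(temperatures)}
    n_idx = {c: n for n, c in enumerate(cell_lines)}
    P = len(tbl)
    intensity = np.full((P, len(cell_lines), len(temperatures)), np.nan)
    for c, (cl, t) in zip(channels, parsed):
        intensity[:, n_idx[cl], t_idx[t]] = tbl[c].to_numpy(dtype=float)
    return PeptideQuantMatrix(
        peptide_ids=[str(p) for p in tbl["peptide"]],
        gene_symbols=[frozenset(str(g).split(";")) for g in tbl["genes"]],
        intensity=intensity,
        temperatures=temperatures,
        cell_lines=cell_lines,
    )
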