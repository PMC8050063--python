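"""Cell-type-specific differentially accessible peak (DAP) calling.

The core statistic: for each peak and each focal cell type, a one-sided
Fisher's exact test (enrichment of accessibility in the focal type) is
run against every other cell type; p-values are Benjamini-Hochberg
adjusted per (focal, other) comparison family across peaks, and a peak
is called specific to the focal type only if every adjusted p-value is
below the significance level. The one-sided all-pairs rule guarantees a
peak can be specific to at most one type.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .intervals import GenomicInterval


def fisher_exact_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher p for enrichment of the focal group.

    The 2x2 table is (a = accessible focal, b = inaccessible focal,
    c = accessible other, d = inaccessible other); p is the upper
    hypergeometric tail P(X >= a) with population N = a+b+c+d, K = a+c
    successes and n = a+b draws. The all-zero table returns 1 by
    convention.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("table counts must be non-negative")
    return float(fisher_greater_vec(np.array([a]), np.array([b]), np.array([c]), np.array([d]))[0])


def fisher_greater_vec(a, b, c, d) -> np.ndarray:
    """Vectorized upper-tail hypergeometric p-values; p in (0, 1]."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    N = a + b + c + d
    K = a + c
    n = a + b
    with np.errstate(invalid="ignore"):
        p = hypergeom.sf(a - 1, N, K, n)
    p = np.where(N == 0, 1.0, p)          # degenerate all-zero table
    return np.clip(p, np.finfo(float).tiny, 1.0)


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Sort ascending, q_i = p_(i) * m / i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class DapCallResult:
    """All pairwise test outcomes plus the final specificity verdicts.

    ``table`` holds one row per (peak, focal type) with the maximum
    adjusted p over comparisons, accessible fractions and the specific
    flag; ``padj`` maps each ordered (focal, other) pair to its
    per-peak BH-adjusted p-vector.
    """

    peaks: list[GenomicInterval]
    cell_types: list[str]
    padj: dict[tuple[str, str], np.ndarray]
    pvals: dict[tuple[str, str], np.ndarray]
    fractions: dict[str, np.ndarray]
    specific: dict[str, np.ndarray]       # focal type -> boolean per peak
    alpha: float

    def specific_peaks(self, cell_type: str) -> list[int]:
        return list(np.flatnonzero(self.specific[cell_type]))

    def peak_type_map(self) -> dict[int, str]:
        """Peak index -> the type it is specific to (unique by construction)."""
        out: dict[int, str] = {}
        for ct in self.cell_types:
            for i in self.specific_peaks(ct):
                if i in out:
                    raise AssertionError(
                        f"peak {i} specific to both {out[i]} and {ct}"
                    )
                out[i] = ct
        return out

    def to_table(self, specific_only: bool = False) -> pd.DataFrame:
        """Long table: peak coordinates, focal type, max adjusted p, fractions.

        Rows ordered by focal type, then ascending max adjusted p, then
        genomic order.
        """
        rows = []
        for ct in self.cell_types:
            others = [o for o in self.cell_types if o != ct]
            max_padj = np.max(np.vstack([self.padj[(ct, o)] for o in others]), axis=0)
            frac_out_max = np.max(
                np.vstack([self.fractions[o] for o in others]), axis=0
            )
            for i, pk in enumerate(self.peaks):
                if specific_only and not self.specific[ct][i]:
                    continue
                rows.append(
                    {
                        "chrom": pk.chrom,
                        "start": pk.start,
                        "end": pk.end,
                        "peak_index": i,
                        "cell_type": ct,
                        "max_p_adj": max_padj[i],
                        "frac_focal": self.fractions[ct][i],
                        "frac_other_max": frac_out_max[i],
                        "specific": bool(self.specific[ct][i]),
                    }
                )
        df = pd.DataFrame(rows)
        if len(df):
            df = df.sort_values(
                ["cell_type", "max_p_adj", "chrom", "start"], kind="stable"
            ).reset_index(drop=True)
        return df


def call_cell_type_specific_peaks(
    matrix,
    labels: Mapping[str, str],
    alpha: float = 0.05,
) -> DapCallResult:
    """All-pairwise one-sided Fisher screen for cell-type-specific peaks.

    ``matrix`` is a binarized cell-by-peak matrix (cells as accessible /
    inaccessible; fragment multiplicities never enter the tables).
    Every barcode in the matrix must be labeled; each cell type needs at
    least two cells. BH adjustment is applied per (focal, other) family
    across all peaks.
    """
    label_map = dict(labels)
    missing = [bc for bc in matrix.barcodes if bc not in label_map]
    if missing:
        raise ValueError(f"{len(missing)} barcodes without labels, e.g. {missing[:3]}")
    types = sorted({label_map[bc] for bc in matrix.barcodes})
    if len(types) < 2:
        raise ValueError("need at least two cell types")

    bc_rows: dict[str, list[int]] = {t: [] for t in types}
    for i, bc in enumerate(matrix.barcodes):
        bc_rows[label_map[bc]].append(i)
    for t in types:
        if len(bc_rows[t]) < 2:
            raise ValueError(f"cell type {t!r} has fewer than 2 cells")

    X = matrix.X.tocsr() if hasattr(matrix.X, "tocsr") else matrix.X
    acc: dict[str, np.ndarray] = {}
    n_cells: dict[str, int] = {}
    for t in types:
        rows = np.array(bc_rows[t], dtype=np.int64)
        acc[t] = np.asarray(X[rows, :].sum(axis=0)).ravel().astype(np.int64)
        n_cells[t] = len(rows)

    pvals: dict[tuple[str, str], np.ndarray] = {}
    padj: dict[tuple[str, str], np.ndarray] = {}
    for focal in types:
        for other in types:
            if focal == other:
                continue
            p = fisher_greater_vec(
                acc[focal], n_cells[focal] - acc[focal],
                acc[other], n_cells[other] - acc[other],
            )
            pvals[(focal, other)] = p
            padj[(focal, other)] = bh_adjust(p)

    specific: dict[str, np.ndarray] = {}
    for focal in types:
        ok = np.ones(len(matrix.features), dtype=bool)
        for other in types:
            if other != focal:
                ok &= padj[(focal, other)] < alpha
        specific[focal] = ok

    # uniqueness is a consequence of the one-sided all-pairs rule; assert it
    stacked = np.vstack([specific[t] for t in types])
    assert int(stacked.sum(axis=0).max(initial=0)) <= 1, "peak specific to >1 type"

    fractions = {t: acc[t] / n_cells[t] for t in types}
    return DapCallResult(
        peaks=list(matrix.features),
        cell_types=types,
        padj=padj,
        pvals=pvals,
        fractions=fractions,
        specific=specific,
        alpha=alpha,
    )


def write_dap_table(result: DapCallResult, path: str | Path, specific_only: bool = True) -> None:
    result.to_table(specific_only=specific_only).to_csv(path, sep="\t", index=False)
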