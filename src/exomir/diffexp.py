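"""Two-group differential expression on normalized values.

The fold change is computed on group means of normalized values with a
pseudo-count: ``log2fc = log2((mean_A + eps) / (mean_B + eps))``.  The test
is a two-sided pooled-variance Student t-test on ``log2(value + eps)``
(a z-test variant is available for comparison).  A miRNA is called
differentially expressed when ``|log2fc| >= 1`` and ``p < 0.05``; BH FDR is
computed and exported but never gates the call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_EPSILON = 1.0
LOG2FC_THRESHOLD = 1.0
P_THRESHOLD = 0.05
NEG_LOG10_CEILING = 300.0


class DiffexpError(ValueError):
    pass


@dataclass
class DEResult:
    mirna: str
    mean_a: float
    mean_b: float
    log2fc: float
    p_value: float
    bh_fdr: float = float("nan")
    is_dem: bool = False
    direction: str = "none"
    degenerate: bool = False


@dataclass
class ContrastSummary:
    label: str
    n_dem: int
    n_up: int
    n_down: int


def test_mirna(values_a, values_b, epsilon: float = DEFAULT_EPSILON,
               method: str = "t"):
    """Return ``(log2fc, p_value, degenerate)`` for one miRNA.

    Both groups need >= 2 replicates.  If both groups have zero variance the
    p-value degenerates to 1 (equal means) or 0 (unequal), flagged.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DiffexpError("need >= 2 replicates per group")
    if (a < 0).any() or (b < 0).any():
        raise DiffexpError("values must be non-negative")
    log2fc = float(np.log2((a.mean() + epsilon) / (b.mean() + epsilon)))
    la, lb = np.log2(a + epsilon), np.log2(b + epsilon)
    if np.allclose(la.var(ddof=1), 0.0) and np.allclose(lb.var(ddof=1), 0.0):
        if np.isclose(la.mean(), lb.mean()):
            return log2fc, 1.0, True
        return log2fc, 0.0, True
    if method == "t":
        p = float(stats.ttest_ind(la, lb, equal_var=True).pvalue)
    elif method == "z":
        na, nb = la.size, lb.size
        pooled = ((na - 1) * la.var(ddof=1) + (nb - 1) * lb.var(ddof=1)) / (na + nb - 2)
        z = (la.mean() - lb.mean()) / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise DiffexpError(f"unknown method {method!r}")
    return log2fc, p, False


def run_contrast(matrix: pd.DataFrame, samples_a: list[str], samples_b: list[str],
                 epsilon: float = DEFAULT_EPSILON, method: str = "t",
                 label: str = "A_vs_B"):
    """Test every row of a normalized matrix; returns ``(results, summary)``.

    ``log2fc`` is group A relative to group B.
    """
    missing = [s for s in samples_a + samples_b if s not in matrix.columns]
    if missing:
        raise DiffexpError(f"samples not in matrix: {missing}")
    results: list[DEResult] = []
    for mirna, row in matrix.iterrows():
        log2fc, p, degenerate = test_mirna(row[samples_a], row[samples_b],
                                           epsilon, method)
        results.append(DEResult(str(mirna), float(row[samples_a].mean()),
                                float(row[samples_b].mean()), log2fc, p,
                                degenerate=degenerate))
    pvals = np.array([r.p_value for r in results])
    if len(pvals):
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(results, fdr):
            r.bh_fdr = float(q)
    summary = call_dems(results, label)
    return results, summary


def call_dems(results: list[DEResult], label: str = "A_vs_B") -> ContrastSummary:
    """Flag DEMs in place (|log2fc| >= 1 and p < 0.05) and count directions."""
    n_up = n_down = 0
    for r in results:
        r.is_dem = abs(r.log2fc) >= LOG2FC_THRESHOLD and r.p_value < P_THRESHOLD
        if r.is_dem:
            r.direction = "up" if r.log2fc > 0 else "down"
            if r.log2fc > 0:
                n_up += 1
            else:
                n_down += 1
        else:
            r.direction = "none"
    return ContrastSummary(label, n_up + n_down, n_up, n_down)


def results_rows(results: list[DEResult]) -> list[dict]:
    return [{"mirna": r.mirna, "mean_a": r.mean_a, "mean_b": r.mean_b,
             "log2fc": r.log2fc, "p_value": r.p_value, "bh_fdr": r.bh_fdr,
             "is_dem": int(r.is_dem), "direction": r.direction,
             "degenerate": int(r.degenerate)}
            for r in results]


def volcano_rows(results: list[DEResult]) -> list[dict]:
    """Volcano-plot export: (mirna, log2fc, -log10 p, dem flag)."""
    rows = []
    for r in results:
        if r.p_value > 0:
            neg_log10 = min(-np.log10(r.p_value), NEG_LOG10_CEILING)
        else:
            neg_log10 = NEG_LOG10_CEILING
        rows.append({"mirna": r.mirna, "log2fc": r.log2fc,
                     "neg_log10_p": float(neg_log10), "is_dem": int(r.is_dem)})
    return rows


def heatmap_matrix(matrix: pd.DataFrame, dem_set: list[str],
                   epsilon: float = DEFAULT_EPSILON):
    """Row-standardized log2 values for the DEM set.

    Returns ``(frame, constant_rows)``; constant rows are emitted as zeros
    and listed separately.
    """
    dem = [m for m in dem_set if m in matrix.index]
    log_values = np.log2(matrix.loc[dem] + epsilon)
    constant: list[str] = []
    rows = {}
    for mirna, row in log_values.iterrows():
        sd = row.std(ddof=0)
        if sd == 0 or np.isnan(sd):
            rows[mirna] = row * 0.0
            constant.append(str(mirna))
        else:
            rows[mirna] = (row - row.mean()) / sd
    frame = pd.DataFrame(rows).T
    if len(dem):
        frame = frame.loc[dem]
        frame.index.name = "mirna"
    else:
        frame = pd.DataFrame(columns=matrix.columns)
        frame.index.name = "mirna"
    return frame, constant
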