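"""Normalization and differential new-RNA expression testing.

Counts are library-size normalized to transcripts-per-10,000 (TP10K), then
natural-log transformed as ln(TP10K + 1), optionally z-scaled per gene.
Differential expression of corrected new-RNA counts between each treated
group and the control uses a two-sided Wilcoxon rank-sum test (normal
approximation with tie correction) on the log-normalized values; fold
changes are ratios of group means on the linear TP10K scale.  A gene is
significant when its absolute fold change exceeds the threshold and the
Bonferroni-adjusted p-value is below alpha in at least one treated
comparison.  Mitochondrial and ribosomal-protein genes are excluded before
testing.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

logger = logging.getLogger("slamkit")

#: name prefixes removed before differential testing
DEFAULT_EXCLUDE_PREFIXES = ("MT-", "RPL", "RPS")


@dataclass
class NormalizedMatrix:
    """ln(TP10K + 1) values, optionally z-scaled per gene."""

    values: np.ndarray  # cells x genes, dense
    cells: list[str]
    genes: list[str]
    z_scaled: bool
    cell_totals: np.ndarray  # raw totals of retained cells, for inversion


def _to_dense(counts) -> np.ndarray:
    if sp.issparse(counts):
        return np.asarray(counts.todense(), dtype=float)
    return np.asarray(counts, dtype=float)


def normalize_tp10k_log(
    counts,
    cells: Sequence[str],
    genes: Sequence[str],
    z_scale: bool = False,
) -> NormalizedMatrix:
    """value[c, g] = ln(10,000 * counts[c, g] / total[c] + 1).

    Cells with zero total counts carry no information and are dropped with a
    warning.  With ``z_scale`` each gene column is standardized over the
    retained cells (constant genes stay at 0).
    """
    x = _to_dense(counts)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    totals = x.sum(axis=1)
    keep = totals > 0
    if not np.all(keep):
        logger.warning("dropping %d cells with zero total counts", int((~keep).sum()))
    x = x[keep]
    totals_kept = totals[keep]
    tp10k = 1e4 * x / totals_kept[:, None]
    values = np.log1p(tp10k)
    if z_scale:
        mu = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        values = (values - mu) / sd
    return NormalizedMatrix(
        values=values,
        cells=[c for c, k in zip(cells, keep) if k],
        genes=list(genes),
        z_scaled=z_scale,
        cell_totals=totals_kept,
    )


def denormalize(norm: NormalizedMatrix) -> np.ndarray:
    """Invert a non-z-scaled normalization back to raw counts."""
    if norm.z_scaled:
        raise ValueError("z-scaled values cannot be inverted to counts")
    tp10k = np.expm1(norm.values)
    return tp10k * norm.cell_totals[:, None] / 1e4


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """One gene in one treated-vs-control comparison."""

    gene: str
    group_pair: str
    fold_change: float
    p_value: float
    p_adjusted: float
    is_significant: bool


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p, normal approximation with tie correction.

    A gene constant across all cells of both groups has no rank information;
    p = 1 by convention.
    """
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


def _abs_fold_change(fc: float) -> float:
    """Symmetric magnitude of a ratio fold change (1/fc for fc < 1)."""
    if fc == 0.0:
        return np.inf
    if np.isinf(fc):
        return np.inf
    return max(fc, 1.0 / fc)


def diff_new_expression(
    N_matrix,
    cells: Sequence[str],
    genes: Sequence[str],
    groups: Sequence[str],
    control_label: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    exclude_patterns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Test each treated group against the control, gene by gene.

    ``N_matrix`` is cells x genes (corrected new counts).  The Wilcoxon test
    runs on ln(TP10K + 1) values; the fold change is the ratio of treated to
    control mean TP10K.  Bonferroni correction uses the number of genes
    tested per comparison, after exclusions.  Gene-name patterns in
    ``exclude_patterns`` (prefixes or fnmatch globs) are removed first;
    the default drops mitochondrial (MT-) and ribosomal-protein (RPL/RPS)
    genes.

    Returns a tidy frame with one row per (gene, comparison).
    """
    if exclude_patterns is None:
        exclude_patterns = DEFAULT_EXCLUDE_PREFIXES
    groups = list(groups)
    labels = sorted(set(groups))
    if control_label not in labels:
        raise ValueError(f"control label {control_label!r} not among groups")
    treated_labels = [g for g in labels if g != control_label]
    if not treated_labels:
        raise ValueError("need at least one treated group besides the control")
    group_arr = np.asarray(groups)
    for lab in labels:
        if (group_arr == lab).sum() < 3:
            raise ValueError(f"group {lab!r} has fewer than 3 cells")

    def excluded(name: str) -> bool:
        up = name.upper()
        for pat in exclude_patterns:
            if up.startswith(pat.upper()) or fnmatch.fnmatch(up, pat.upper()):
                return True
        return False

    keep_idx = [j for j, g in enumerate(genes) if not excluded(g)]
    kept_genes = [genes[j] for j in keep_idx]
    n_tests = len(kept_genes)
    if n_tests == 0:
        raise ValueError("no genes left after exclusion filters")

    norm = normalize_tp10k_log(N_matrix, cells, genes, z_scale=False)
    logvals = norm.values[:, keep_idx]
    tp10k = np.expm1(logvals)
    norm_groups = np.asarray([groups[list(cells).index(c)] for c in norm.cells])

    ctrl_mask = norm_groups == control_label
    rows = []
    for lab in treated_labels:
        trt_mask = norm_groups == lab
        pair = f"{lab}_vs_{control_label}"
        mean_ctrl = tp10k[ctrl_mask].mean(axis=0)
        mean_trt = tp10k[trt_mask].mean(axis=0)
        for k, gene in enumerate(kept_genes):
            if mean_ctrl[k] == 0.0 and mean_trt[k] == 0.0:
                fc = 1.0
            elif mean_ctrl[k] == 0.0:
                fc = np.inf
            else:
                fc = float(mean_trt[k] / mean_ctrl[k])
            p = _wilcoxon_p(logvals[trt_mask, k], logvals[ctrl_mask, k])
            p_adj = min(1.0, p * n_tests)
            sig = (_abs_fold_change(fc) > fc_threshold) and (p_adj < alpha)
            rows.append((gene, pair, fc, p, p_adj, sig))

    return pd.DataFrame(
        rows,
        columns=["gene", "comparison", "fold_change", "p", "p_adj", "significant"],
    )


def significant_genes(de_table: pd.DataFrame) -> list[str]:
    """Genes significant in at least one treated comparison (union rule)."""
    sig = de_table.loc[de_table["significant"], "gene"]
    return sorted(set(sig))
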