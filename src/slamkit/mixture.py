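"""Binomial mixture model for new-RNA fraction estimation and correction.

Each consensus record contributes sufficient statistics (n_i, y_i): uridine
sites observed and T-to-C substitutions among them.  A molecule is newly
transcribed with probability theta, in which case substitutions arise at the
labeled conversion rate p; otherwise they arise at the background rate q:

    f(theta, p, q) = theta * Binom(y_i; p, n_i) + (1 - theta) * Binom(y_i; q, n_i)

The global (theta, p, q) are fit by maximum likelihood on a random subsample
of records via multi-restart Nelder-Mead in logit space.  With (p, q) fixed,
a per-gene new fraction theta_gene is a bounded 1-D maximization.  The
per-cell detection rate

    alpha_cell = L_cell / sum_g theta_g * (L_g + U_g)

is the ratio of observed labeled molecules to model-estimated new molecules;
corrected new counts follow N_g = min(L_g / alpha_cell, L_g + U_g).

Incomplete 4sU incorporation makes p << 1, so many new molecules carry zero
substitutions and the raw labeled count underestimates new RNA; alpha_cell
corrects for exactly that.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit
from scipy.stats import binom

from .calling import ConsensusRecord, LabelMatrices

logger = logging.getLogger("slamkit")

# multi-restart initialization ranges: spans plausible 4sU incorporation
# rates and residual background/sequencing-error rates
THETA_INIT_RANGE = (0.05, 0.5)
P_INIT_RANGE = (0.005, 0.08)
Q_INIT_RANGE = (1e-4, 0.01)

NM_FATOL = 1e-8
NM_MAXITER = 2000


@dataclass
class MixtureFit:
    """Fitted global mixture parameters with diagnostics.

    Components are ordered so that p >= q (the labeled component converts
    more often than background); ``warning`` is set instead of raising on
    degenerate inputs such as an all-zero substitution sample.
    """

    theta: float
    p: float
    q: float
    loglik: float
    n_restarts_used: int
    n_records_used: int
    seed: int
    warning: Optional[str] = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MixtureFit":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class GeneTheta:
    """Per-gene new-RNA fraction at one time point."""

    gene: str
    theta_gene: float
    n_umis: int
    used_fallback: bool


@dataclass
class CellDetectionRate:
    """Per-cell labeled-molecule detection rate alpha."""

    cell_barcode: str
    alpha: float
    labeled_total: int
    estimated_new_total: float


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _collapse_counts(
    ns: np.ndarray, ys: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse records to unique (n, y) pairs with multiplicities.

    The likelihood depends on records only through (n, y), so evaluation cost
    drops from the number of records to the number of distinct pairs.
    """
    pairs = np.stack([ns, ys], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    return uniq[:, 0], uniq[:, 1], counts.astype(np.float64)


def _loglik_arrays(
    n: np.ndarray, y: np.ndarray, w: np.ndarray, theta: float, p: float, q: float
) -> float:
    la = binom.logpmf(y, n, p)
    lb = binom.logpmf(y, n, q)
    with np.errstate(divide="ignore"):
        lt = np.log(theta) if theta > 0 else -np.inf
        lt1 = np.log1p(-theta) if theta < 1 else -np.inf
    per_record = np.logaddexp(lt + la, lt1 + lb)
    return float(np.dot(w, per_record))


def _records_to_arrays(
    records: Iterable[ConsensusRecord | tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Extract (n, y) arrays, dropping n == 0 records (no likelihood info)."""
    ns, ys = [], []
    n_dropped = 0
    for rec in records:
        if isinstance(rec, ConsensusRecord):
            n_i, y_i = rec.n, rec.y
        else:
            n_i, y_i = rec
        if n_i == 0:
            n_dropped += 1
            continue
        ns.append(n_i)
        ys.append(y_i)
    if n_dropped:
        logger.info("excluded %d records with n = 0 from likelihood", n_dropped)
    return np.asarray(ns, dtype=np.int64), np.asarray(ys, dtype=np.int64), n_dropped


def mixture_loglik(
    records: Iterable[ConsensusRecord | tuple[int, int]],
    theta: float,
    p: float,
    q: float,
) -> float:
    """Mixture log-likelihood sum_i log[theta B(y_i; p, n_i) + (1-theta) B(y_i; q, n_i)].

    Computed with log-sum-exp stabilization; records with n = 0 are excluded.
    Boundary parameter values (0 or 1) are allowed and may yield -inf when the
    data are impossible under both components.
    """
    ns, ys, _ = _records_to_arrays(records)
    if ns.size == 0:
        return 0.0
    n, y, w = _collapse_counts(ns, ys)
    return _loglik_arrays(n, y, w, theta, p, q)


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

def fit_global_pq(
    records: Sequence[ConsensusRecord | tuple[int, int]],
    n_subsample: int = 100_000,
    n_restarts: int = 100,
    seed: int = 0,
) -> MixtureFit:
    """Fit (theta, p, q) by multi-restart Nelder-Mead maximum likelihood.

    ``min(n_subsample, available)`` records are drawn without replacement with
    the given seed.  Each restart starts from a random interior point and
    optimizes in logit space, which keeps all three parameters in (0, 1)
    without explicit constraints; the best restart wins and components are
    swapped if needed so that p >= q.

    A sample with no substitutions at all leaves the mixture unidentifiable;
    the boundary fit (theta = 0, p = q = 0) is returned with a warning rather
    than raising.
    """
    if len(records) == 0:
        raise ValueError("cannot fit mixture on an empty record set")
    rng = np.random.default_rng(seed)
    ns_all, ys_all, _ = _records_to_arrays(records)
    if ns_all.size == 0:
        raise ValueError("all records have n = 0; nothing to fit")

    m = min(n_subsample, ns_all.size)
    idx = rng.choice(ns_all.size, size=m, replace=False)
    ns, ys = ns_all[idx], ys_all[idx]

    if ys.sum() == 0:
        logger.warning("no substitutions in subsample; mixture unidentifiable")
        return MixtureFit(
            theta=0.0, p=0.0, q=0.0,
            loglik=0.0, n_restarts_used=0, n_records_used=m, seed=seed,
            warning="all records have y = 0; theta unidentifiable, rates at lower bound",
        )

    n, y, w = _collapse_counts(ns, ys)

    def neg_ll(x: np.ndarray) -> float:
        theta, p, q = expit(x)
        return -_loglik_arrays(n, y, w, theta, p, q)

    best_x = None
    best_val = np.inf
    for _ in range(n_restarts):
        x0 = logit(
            np.array(
                [
                    rng.uniform(*THETA_INIT_RANGE),
                    rng.uniform(*P_INIT_RANGE),
                    rng.uniform(*Q_INIT_RANGE),
                ]
            )
        )
        res = minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            options={"fatol": NM_FATOL, "xatol": 1e-8, "maxiter": NM_MAXITER},
        )
        if res.fun < best_val:
            best_val = res.fun
            best_x = res.x

    theta, p, q = (float(v) for v in expit(best_x))
    if p < q:  # break label-switching symmetry
        p, q = q, p
        theta = 1.0 - theta
    return MixtureFit(
        theta=theta, p=p, q=q,
        loglik=-float(best_val),
        n_restarts_used=n_restarts,
        n_records_used=m,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# per-gene theta and per-cell detection rate
# ---------------------------------------------------------------------------

def estimate_gene_theta(
    records_for_gene: Sequence[ConsensusRecord | tuple[int, int]],
    p: float,
    q: float,
    fallback_theta: float,
    gene: str = "",
    min_umis: int = 5,
) -> GeneTheta:
    """Maximize the mixture likelihood over theta only, for one gene.

    (p, q) come from the global fit on the same sample.  Genes with fewer
    than ``min_umis`` usable records, or a degenerate p = q, fall back to the
    sample-level theta.
    """
    ns, ys, _ = _records_to_arrays(records_for_gene)
    n_umis = int(ns.size)
    if n_umis < min_umis or p <= q:
        if p <= q:
            logger.warning("p <= q for gene %s: theta undefined, using fallback", gene)
        return GeneTheta(
            gene=gene, theta_gene=fallback_theta, n_umis=n_umis, used_fallback=True
        )
    n, y, w = _collapse_counts(ns, ys)
    res = minimize_scalar(
        lambda t: -_loglik_arrays(n, y, w, t, p, q),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    theta_hat = float(np.clip(res.x, 0.0, 1.0))
    # the bounded optimizer stays interior; check boundaries explicitly
    for t_edge in (0.0, 1.0):
        if -_loglik_arrays(n, y, w, t_edge, p, q) < res.fun:
            theta_hat = t_edge
    return GeneTheta(gene=gene, theta_gene=theta_hat, n_umis=n_umis, used_fallback=False)


def compute_detection_rate(
    cell_records: Mapping[str, tuple[int, int]],
    gene_thetas: Mapping[str, float],
    cell_barcode: str = "",
) -> CellDetectionRate:
    """Detection rate alpha = L_cell / sum_g theta_g (L_g + U_g) for one cell.

    ``cell_records`` maps gene -> (labeled, unlabeled) counts in this cell.
    alpha = 0 when the cell has no labeled molecules; a zero denominator with
    a nonzero numerator is a model inconsistency and raises.
    """
    labeled_total = sum(l for l, _u in cell_records.values())
    denom = 0.0
    for gene, (l, u) in cell_records.items():
        if l + u > 0:
            denom += gene_thetas[gene] * (l + u)
    if labeled_total == 0:
        return CellDetectionRate(
            cell_barcode=cell_barcode, alpha=0.0,
            labeled_total=0, estimated_new_total=denom,
        )
    if denom == 0.0:
        raise ValueError(
            f"cell {cell_barcode!r}: {labeled_total} labeled molecules but the "
            "estimated new total is 0 — theta estimates are inconsistent with the data"
        )
    return CellDetectionRate(
        cell_barcode=cell_barcode,
        alpha=labeled_total / denom,
        labeled_total=labeled_total,
        estimated_new_total=denom,
    )


def correct_new_counts(L_gene: float, U_gene: float, alpha: float) -> float:
    """Corrected new count N = min(L / alpha, L + U); 0 when L = 0.

    The min() clamp keeps the corrected count within the molecules actually
    observed for the gene.  alpha = 0 with L > 0 cannot occur when alpha was
    computed from the same cell's records, and raises.
    """
    if L_gene < 0 or U_gene < 0 or alpha < 0:
        raise ValueError("counts and alpha must be non-negative")
    if L_gene == 0:
        return 0.0
    if alpha == 0.0:
        raise ValueError("alpha = 0 with labeled count > 0")
    return min(L_gene / alpha, L_gene + U_gene)


# ---------------------------------------------------------------------------
# matrix-level correction
# ---------------------------------------------------------------------------

def estimate_all_gene_thetas(
    records: Iterable[ConsensusRecord],
    fit: MixtureFit,
    min_umis: int = 5,
) -> dict[str, GeneTheta]:
    """Per-gene theta for every gene present, pooled across cells."""
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append((rec.n, rec.y))
    return {
        g: estimate_gene_theta(
            pairs, fit.p, fit.q, fallback_theta=fit.theta, gene=g, min_umis=min_umis
        )
        for g, pairs in by_gene.items()
    }


def correct_matrices(
    matrices: LabelMatrices,
    gene_thetas: Mapping[str, GeneTheta | float],
) -> list[CellDetectionRate]:
    """Fill matrices.N with corrected new counts; returns per-cell alphas.

    Vectorized over the sparse L and U matrices: for each cell,
    alpha = L_cell / sum_g theta_g (L + U)[c, g], then
    N[c, g] = min(L[c, g] / alpha, (L + U)[c, g]).
    """
    theta_vec = np.array(
        [
            gene_thetas[g].theta_gene if isinstance(gene_thetas[g], GeneTheta)
            else float(gene_thetas[g])
            for g in matrices.genes
        ]
    )
    L = matrices.L.tocsr()
    total = (matrices.L + matrices.U).tocsr()
    l_cell = np.asarray(L.sum(axis=1)).ravel()
    denom = total @ theta_vec

    alphas: list[CellDetectionRate] = []
    alpha_vec = np.zeros(len(matrices.cells))
    for i, cell in enumerate(matrices.cells):
        if l_cell[i] == 0:
            alpha = 0.0
        elif denom[i] == 0.0:
            raise ValueError(
                f"cell {cell!r}: labeled molecules present but estimated new total is 0"
            )
        else:
            alpha = float(l_cell[i] / denom[i])
        alpha_vec[i] = alpha
        alphas.append(
            CellDetectionRate(
                cell_barcode=cell, alpha=alpha,
                labeled_total=int(l_cell[i]), estimated_new_total=float(denom[i]),
            )
        )

    N = L.astype(np.float64).tocoo()
    if N.nnz:
        scaled = N.data / alpha_vec[N.row]
        cap = np.asarray(total[N.row, N.col]).ravel()
        N.data = np.minimum(scaled, cap)
    matrices.N = N.tocsr()
    return alphas


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def gene_theta_table(gene_thetas: Mapping[str, GeneTheta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (gt.gene, gt.theta_gene, gt.n_umis, gt.used_fallback)
            for gt in gene_thetas.values()
        ],
        columns=["gene", "theta", "n_umis", "fallback"],
    ).sort_values("gene").reset_index(drop=True)


def alpha_table(alphas: Iterable[CellDetectionRate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (a.cell_barcode, a.alpha, a.labeled_total, a.estimated_new_total)
            for a in alphas
        ],
        columns=["cell", "alpha", "labeled_total", "estimated_new_total"],
    )
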