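"""Per-pair correlation analysis and coherency classification.

For each gene pair the expression correlation is computed within every
eligible dataset (Pearson, Spearman or Kendall tau-b).  A pair is
*homogeneous* when all nonzero per-dataset coefficients share one sign;
only homogeneous pairs enter the edge-level call.  Per-dataset results are
combined into one coefficient (sample-size-weighted mean) and one p-value
(Fisher's method), Benjamini-Hochberg adjusted within the analysis family,
and classified as positive / negative / non-significant at ``alpha``.

Coherency then compares the correlation sign against the causal edge
sign: activation with positive correlation (or inhibition with negative)
is *coherent*; a significant correlation of the opposite sign is
*incoherent*.  The same logic applies to DEG direction labels: an
activation edge is coherent when both genes move the same way, an
inhibition edge when they move oppositely.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionCollection, PairedVectors, eligible_datasets

logger = logging.getLogger(__name__)

METHODS = ("pearson", "spearman", "kendall")
AGGREGATIONS = ("weighted_mean", "max_n")
CATEGORIES = ("positive", "negative", "non_significant")
COHERENCY_CALLS = ("coherent", "incoherent", "non_significant")


class ConstantVectorError(ValueError):
    """Correlation is undefined for a zero-variance vector."""


class IneligiblePairError(ValueError):
    """The pair has no usable dataset."""


@dataclass
class CorrelationResult:
    """Correlation of one pair within one dataset."""

    dataset_id: str
    method: str
    r: float
    p: float
    n: int


@dataclass
class PairAssociation:
    """Edge-level association summary for one gene pair.

    ``q`` (the BH-adjusted p) and ``category`` are filled once the whole
    analysis family is known; see :func:`fdr_adjust` and
    :func:`classify_sign_category`.
    """

    gene_i: str
    gene_j: str
    per_dataset: list[CorrelationResult]
    homogeneous: bool
    combined_r: float
    combined_p: float
    n_constant_skipped: int = 0
    q: float | None = None
    category: str | None = None

    @property
    def n_datasets(self) -> int:
        return len(self.per_dataset)


@dataclass(frozen=True)
class CoherencyCall:
    """Coherency verdict for one signed edge."""

    sign: int
    category: str
    call: str


def correlate(pv: PairedVectors, method: str = "pearson") -> CorrelationResult:
    """Correlation coefficient and two-sided p-value for one dataset.

    Pearson's p comes from the exact t transform with n-2 df; Spearman is
    Pearson on ranks; Kendall is tau-b (tie-corrected).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if pv.n < 3:
        raise ValueError(f"correlation needs n >= 3, got n={pv.n}")
    if np.ptp(pv.x) == 0 or np.ptp(pv.y) == 0:
        raise ConstantVectorError(
            f"constant vector in dataset {pv.dataset_id!r}: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(pv.x, pv.y)
    elif method == "spearman":
        res = stats.spearmanr(pv.x, pv.y)
    else:
        res = stats.kendalltau(pv.x, pv.y, variant="b")
    r = float(res.statistic if hasattr(res, "statistic") else res.correlation)
    return CorrelationResult(pv.dataset_id, method, r, float(res.pvalue), pv.n)


def assess_pair(
    gene_i: str,
    gene_j: str,
    coll: ExpressionCollection,
    method: str = "pearson",
    min_n: int = 3,
    aggregation: str = "weighted_mean",
) -> PairAssociation:
    """Full per-pair analysis across every eligible dataset.

    Datasets where either vector is constant are skipped with a logged
    reason.  ``aggregation`` picks how per-dataset results become one
    edge-level (r, p): ``weighted_mean`` (n-weighted mean r, Fisher
    combined p; a single dataset keeps its own p) or ``max_n`` (the
    largest dataset alone, ties broken by dataset id).
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    pvs = eligible_datasets(gene_i, gene_j, coll, min_n=min_n)
    if not pvs:
        raise IneligiblePairError(f"pair ({gene_i}, {gene_j}) has no eligible dataset")
    results: list[CorrelationResult] = []
    n_skipped = 0
    for pv in pvs:
        try:
            results.append(correlate(pv, method))
        except ConstantVectorError as exc:
            n_skipped += 1
            logger.info("pair (%s, %s): %s", gene_i, gene_j, exc)
    if not results:
        raise IneligiblePairError(
            f"pair ({gene_i}, {gene_j}): all eligible datasets had constant vectors")

    signs = {int(np.sign(res.r)) for res in results if res.r != 0}
    homogeneous = len(signs) <= 1

    if aggregation == "max_n":
        best = sorted(results, key=lambda res: (-res.n, res.dataset_id))[0]
        combined_r, combined_p = best.r, best.p
    else:
        ns = np.array([res.n for res in results], dtype=float)
        rs = np.array([res.r for res in results])
        combined_r = float(np.sum(ns * rs) / np.sum(ns))
        if len(results) == 1:
            combined_p = results[0].p
        else:
            combined_p = float(stats.combine_pvalues(
                [res.p for res in results], method="fisher").pvalue)
    return PairAssociation(gene_i, gene_j, results, homogeneous,
                           combined_r, combined_p, n_constant_skipped=n_skipped)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("fdr_adjust needs a nonempty list")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_sign_category(assoc: PairAssociation, alpha: float = 0.05) -> str:
    """positive / negative if significant after FDR, else non_significant."""
    if assoc.q is None:
        raise ValueError("q not computed; run fdr_adjust over the family first")
    if assoc.q < alpha and assoc.combined_r > 0:
        return "positive"
    if assoc.q < alpha and assoc.combined_r < 0:
        return "negative"
    return "non_significant"


def classify_edge_coherency(sign: int, category: str) -> CoherencyCall:
    """Compare causal edge sign with the correlation sign category.

    Activation expects a positive correlation, inhibition a negative one;
    a significant correlation of the opposite sign is incoherent.
    """
    if sign not in (1, -1):
        raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if category == "non_significant":
        call = "non_significant"
    elif (sign == 1) == (category == "positive"):
        call = "coherent"
    else:
        call = "incoherent"
    return CoherencyCall(sign, category, call)


def classify_deg_coherency(dir_i: str, dir_j: str, sign: int) -> str:
    """Coherency of an edge from up/down DEG labels.

    Activation: coherent iff both genes move the same way; inhibition:
    coherent iff they move oppositely.  Exactly 4 of the 8 possible
    (direction, direction, sign) combinations are coherent.
    """
    for d in (dir_i, dir_j):
        if d not in ("up", "down"):
            raise ValueError(f"DEG direction must be 'up' or 'down', got {d!r}")
    if sign not in (1, -1):
        raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
    return "coherent" if (sign == 1) == (dir_i == dir_j) else "incoherent"
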