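"""Derive M(LPS)+ / M(LPS)- gene signatures from a strain panel.

Every gene's replicate-averaged LPS expression is Pearson-correlated with
the per-strain polarization factor ratio across the panel.  Genes passing
both a nominal p-value cutoff (default P < 1e-4) and a Benjamini-Hochberg
FDR cutoff (default q < 0.05) form the signatures: positively correlated
genes are M(LPS)+ (high LPS responders), negatively correlated genes are
M(LPS)-.  Within each signature genes are ordered by |r| descending so
"top N" subsets are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from polarspec.data_io import GeneSet, ValidationError
from polarspec.polarization import StrainPanel

logger = logging.getLogger(__name__)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value.

    The p-value uses ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of
    freedom; perfect correlation (|r| = 1) returns p = 0.

    Raises
    ------
    ValidationError
        If the vectors differ in length, are shorter than 3, or either is
        constant (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc * xc))
    sy = np.sqrt(np.sum(yc * yc))
    if sx == 0 or sy == 0:
        raise ValidationError("correlation undefined for a constant vector")
    r = float(np.dot(xc / sx, yc / sy))
    r = max(-1.0, min(1.0, r))
    # collinear within numerical resolution: the t statistic is unbounded
    if 1.0 - r * r < 1e-14:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(min(p, 1.0))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q-values).

    ``q_(i) = min_{j >= i}(p_(j) * m / j)`` on the ascending order
    statistics, capped at 1 and mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvals must be a 1-d vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class SignaturePair:
    """Ranked M(LPS)+ and M(LPS)- gene lists with their correlation stats.

    ``pos`` and ``neg`` are DataFrames with columns ``r``, ``p``, ``q``,
    ``n`` indexed by gene id, each sorted by |r| descending.
    """

    pos: pd.DataFrame
    neg: pd.DataFrame
    p_max: float
    fdr_max: float
    n_tested: int = 0
    n_skipped_constant: int = 0

    def __post_init__(self) -> None:
        if set(self.pos.index) & set(self.neg.index):
            raise ValidationError("M(LPS)+ and M(LPS)- lists overlap")
        if len(self.pos) and not (self.pos["r"] > 0).all():
            raise ValidationError("M(LPS)+ list contains non-positive correlations")
        if len(self.neg) and not (self.neg["r"] < 0).all():
            raise ValidationError("M(LPS)- list contains non-negative correlations")

    def top(self, n: int, which: str) -> GeneSet:
        """Top-``n`` |r| genes of one signature as a GeneSet."""
        df = self.pos if which == "pos" else self.neg
        name = "M_LPS_pos" if which == "pos" else "M_LPS_neg"
        return GeneSet(name, f"top {min(n, len(df))} by |r|", tuple(df.index[:n]))

    def as_gene_sets(self, top_n: int | None = None) -> list[GeneSet]:
        n = top_n or max(len(self.pos), len(self.neg))
        return [self.top(n, "pos"), self.top(n, "neg")]


def correlate_genes(expr_by_strain: pd.DataFrame, pfr: pd.Series) -> tuple[pd.DataFrame, int]:
    """Pearson r/p of every non-constant gene against the PFR vector.

    Vectorized over genes; p-values follow the same two-sided t-test as
    :func:`pearson_with_p`.  Returns the records plus the count of
    constant genes skipped.
    """
    strains = list(pfr.index)
    if len(strains) < 3:
        raise ValidationError("need at least 3 strains to correlate")
    X = expr_by_strain[strains].to_numpy(dtype=float)
    y = pfr.to_numpy(dtype=float)
    n = y.size
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt(np.sum(Xc * Xc, axis=1))
    sy = np.sqrt(np.sum(yc * yc))
    nonconst = sx > 0
    if sy == 0:
        raise ValidationError("PFR vector is constant")
    r = np.full(X.shape[0], np.nan)
    r[nonconst] = (Xc[nonconst] @ yc) / (sx[nonconst] * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(1.0 - r * r < 1e-14, 0.0, np.minimum(p, 1.0))
    records = pd.DataFrame({"r": r, "p": p, "n": n}, index=expr_by_strain.index)[nonconst]
    n_skipped = int((~nonconst).sum())
    if n_skipped:
        logger.info("skipped %d constant genes", n_skipped)
    return records, n_skipped


def extract_signatures(
    panel: StrainPanel,
    pfr_table: pd.DataFrame,
    p_max: float = 1e-4,
    fdr_max: float = 0.05,
    pfr_column: str = "pfr_lps",
) -> SignaturePair:
    """Select the M(LPS)+ / M(LPS)- signatures under the dual threshold.

    Correlates each gene's replicate-averaged LPS expression against the
    LPS-condition PFR across strains; BH adjustment is computed jointly
    over all testable (non-constant) genes; genes must pass BOTH
    ``p < p_max`` and ``q < fdr_max``.
    """
    expr = panel.strain_means("lps")
    pfr = pfr_table[pfr_column]
    records, n_skipped = correlate_genes(expr, pfr)
    records = records.copy()
    records["q"] = bh_adjust(records["p"].to_numpy())
    selected = records[(records["p"] < p_max) & (records["q"] < fdr_max)]
    pos = selected[selected["r"] > 0].sort_values("r", ascending=False, kind="stable")
    neg = selected[selected["r"] < 0].sort_values("r", ascending=True, kind="stable")
    pair = SignaturePair(
        pos=pos,
        neg=neg,
        p_max=p_max,
        fdr_max=fdr_max,
        n_tested=len(records),
        n_skipped_constant=n_skipped,
    )
    pair.records = records  # full per-gene table for reporting
    return pair


def signature_overlap(a: GeneSet, b: GeneSet, universe_size: int) -> dict[str, float]:
    """Overlap statistics between two gene sets within a finite universe.

    Returns the intersection size, Jaccard index, and the one-sided
    hypergeometric enrichment p-value P(X >= observed overlap).
    """
    sa, sb = a.upper_members(), b.upper_members()
    if not sa or not sb:
        raise ValidationError("gene sets must be non-empty")
    if universe_size < len(sa | sb):
        raise ValidationError("universe smaller than the union of the sets")
    k = len(sa & sb)
    jaccard = k / len(sa | sb)
    # P(X >= k) with X ~ Hypergeom(M=universe, n=|a|, N=|b|)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(sa), len(sb)))
    return {"intersection": float(k), "jaccard": jaccard, "p_hypergeom": min(p, 1.0)}
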