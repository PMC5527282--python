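"""Signature-based survival stratification.

Implements the clinical half of the pipeline: per-gene Cox survival
z-scores (a locally computed analogue of PRECOG-style gene rankings),
selection of tumour-specific gene sets from the leading edge of a
signature's enrichment on that ranking, mean-signature scoring with a
median split, Kaplan-Meier curves, the two-group log-rank test and the
binary-covariate Cox proportional-hazards fit.

Cox fits use Newton-Raphson on the partial likelihood with Breslow tie
handling (ties are rare for continuous scores); convergence is declared
at |delta beta| < 1e-8 within 50 iterations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from polarspec.data_io import GeneSet, SurvivalCohort, ValidationError, match_genes
from polarspec.enrichment import enrichment_score, leading_edge

logger = logging.getLogger(__name__)

_NR_TOL = 1e-8
_NR_MAX_ITER = 50


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed to converge (e.g. monotone likelihood)."""


@dataclass
class KMCurve:
    """Product-limit survival estimate at the observed event times."""

    event_times: np.ndarray  # distinct, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    censor_times: np.ndarray  # times of censored observations

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and (np.any(s < 0) or np.any(s > 1) or np.any(np.diff(s) > 1e-12)):
            raise ValidationError("survival curve must be non-increasing within [0, 1]")


@dataclass
class SurvivalComparison:
    """Bundled high-vs-low comparison for one signature score."""

    n_high: int
    n_low: int
    chi2: float
    p_logrank: float
    hr: float
    hr_ci: tuple[float, float]
    p_wald: float
    km_high: KMCurve
    km_low: KMCurve
    scores: pd.Series | None = None


def km_curve(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct event times
    ``t_i`` with ``d_i`` events and ``n_i`` at risk.  With no events the
    curve is flat at 1 (warned).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size != events.size or np.any(times < 0):
        raise ValidationError("invalid survival input")
    if events.sum() == 0:
        warnings.warn("no events: survival curve is flat at 1", stacklevel=2)
        return KMCurve(np.array([]), np.array([]), np.array([]), np.sort(times))
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    distinct = np.unique(t[e == 1])
    surv, risk = [], []
    s = 1.0
    for ti in distinct:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        risk.append(n_i)
    return KMCurve(distinct, np.array(surv), np.array(risk), np.sort(t[e == 0]))


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test.

    ``chi2 = (sum O_A - sum E_A)^2 / sum V`` accumulated over distinct
    event times, with the hypergeometric variance of the 2x2 risk table
    at each time; p from the chi-square distribution with df = 1.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ea.sum() + eb.sum() == 0:
        raise ValidationError("log-rank test undefined with no events")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e, var = 0.0, 0.0
    for t in event_times:
        n_a = np.sum(ta >= t)
        n_b = np.sum(tb >= t)
        d_a = np.sum((ta == t) & (ea == 1))
        d_b = np.sum((tb == t) & (eb == 1))
        n, d = n_a + n_b, d_a + d_b
        if n < 2:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _cox_fit_1d(x: np.ndarray, times: np.ndarray, events: np.ndarray) -> tuple[float, float]:
    """Newton-Raphson fit of a single-covariate Cox model (Breslow ties).

    Returns (beta, se).  The Breslow partial log-likelihood is
    ``sum_t [ sum_{i in D_t} beta x_i - d_t log(sum_{j in R_t} exp(beta x_j)) ]``
    with D_t the events at time t and R_t the risk set.
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 2:
        raise ValidationError("need at least 2 events for a Cox fit")
    order = np.argsort(times, kind="stable")
    x, times, events = x[order], times[order], events[order]
    event_times = np.unique(times[events == 1])

    # dense risk/death bookkeeping: one boolean matrix shared by all
    # Newton iterations keeps the per-iteration cost at matrix-vector level
    risk = times[None, :] >= event_times[:, None]
    death = (times[None, :] == event_times[:, None]) & (events[None, :] == 1)
    d_counts = death.sum(axis=1)
    x_death_sum = death @ x

    beta = 0.0
    for _ in range(_NR_MAX_ITER):
        w = np.exp(beta * x)
        sw = risk @ w
        m1 = (risk @ (w * x)) / sw
        m2 = (risk @ (w * x * x)) / sw
        grad = float(np.sum(x_death_sum - d_counts * m1))
        hess = float(np.sum(d_counts * (m2 - m1 * m1)))
        if hess <= 0:
            raise ConvergenceError("degenerate information (constant covariate in risk sets)")
        step = grad / hess
        beta += step
        if abs(beta) > 50:
            raise ConvergenceError(
                "Cox fit diverged (monotone likelihood, e.g. all events in one group)"
            )
        if abs(step) < _NR_TOL:
            se = 1.0 / np.sqrt(hess)
            return float(beta), float(se)
    raise ConvergenceError("Cox Newton-Raphson did not converge in 50 iterations")


def cox_fit(x: np.ndarray, times: np.ndarray, events: np.ndarray) -> tuple[float, float]:
    """Univariate Cox fit for an arbitrary (continuous or binary) covariate.

    Returns (beta, se); ``exp(beta)`` is the hazard ratio per unit of x.
    """
    return _cox_fit_1d(np.asarray(x, dtype=float), times, events)


def cox_hr_binary(
    group_labels: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
) -> tuple[float, tuple[float, float], float]:
    """Hazard ratio of the 'high' vs 'low' group from a binary Cox fit.

    ``group_labels`` holds ``"high"`` / ``"low"`` (or 1/0).  Returns
    (hr, 95% Wald CI, Wald p).
    """
    labels = np.asarray(group_labels)
    if labels.dtype.kind in "UO":
        xi = np.array([1.0 if str(l) == "high" else 0.0 for l in labels])
    else:
        xi = labels.astype(float)
    if len(np.unique(xi)) < 2:
        raise ValidationError("both groups must be represented")
    beta, se = _cox_fit_1d(xi, times, events)
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return hr, ci, p


def per_gene_survival_z(cohort: SurvivalCohort, min_events: int = 2) -> pd.Series:
    """Univariate Cox Wald z per gene, ranked descending.

    Each gene's expression is standardized and fit as the sole covariate;
    the score is ``z = beta / se``, so positive z means higher expression
    associates with higher hazard (worse survival).  Non-convergent or
    constant genes are excluded with a warning.  The result is the
    package's locally computed analogue of survival gene-rank databases.
    """
    if cohort.expression is None:
        raise ValidationError("cohort carries no expression matrix")
    if cohort.event.sum() < min_events:
        raise ValidationError("need at least 2 observed events")
    zs: dict[str, float] = {}
    skipped = 0
    X = cohort.expression
    for gene in X.index:
        v = X.loc[gene].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            skipped += 1
            continue
        try:
            beta, se = _cox_fit_1d((v - v.mean()) / sd, cohort.time, cohort.event)
        except (ConvergenceError, ValidationError):
            skipped += 1
            continue
        zs[gene] = beta / se
    if skipped:
        logger.warning("excluded %d genes (constant or non-convergent)", skipped)
    from polarspec.data_io import sort_ranked

    return sort_ranked(pd.Series(zs))


def select_tumor_gene_set(
    ranked_survival: pd.Series,
    sig: GeneSet,
    k: int = 30,
    weight_p: float = 1.0,
) -> GeneSet:
    """Tumour-specific gene set: top-k leading-edge genes of a signature.

    Runs the enrichment of ``sig`` on the per-gene survival ranking and
    keeps the ``k`` highest-ranked leading-edge members (fewer, with a
    warning, if the leading edge is smaller).
    """
    es, _, peak = enrichment_score(ranked_survival, sig, weight_p)
    le = leading_edge(ranked_survival, sig, es, peak)
    if not le:
        raise ValidationError(f"empty leading edge for {sig.name!r}")
    if len(le) < k:
        warnings.warn(
            f"leading edge of {sig.name!r} has only {len(le)} genes (< k={k})", stacklevel=2
        )
    chosen = le[:k]
    return GeneSet(f"{sig.name}_tumor_top{k}", f"leading-edge top {len(chosen)}", tuple(chosen))


def mean_signature_score(expr: pd.DataFrame, genes: GeneSet) -> pd.Series:
    """Per-sample unweighted mean RMA expression over the matched genes."""
    hits = match_genes(expr.index, genes.members)
    if not hits:
        raise ValidationError(
            f"no gene of {genes.name!r} found in the matrix; missing: {sorted(genes.members)[:10]}"
        )
    return expr.loc[hits].mean(axis=0)


def median_split(scores: pd.Series) -> pd.Series:
    """Split samples at the median score: > median -> 'high', <= -> 'low'."""
    if len(scores) < 4:
        raise ValidationError("need at least 4 samples for a median split")
    med = float(scores.median())
    labels = pd.Series(np.where(scores > med, "high", "low"), index=scores.index)
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise ValidationError("degenerate split: all scores on one side of the median")
    return labels


def survival_by_signature(cohort: SurvivalCohort, genes: GeneSet) -> SurvivalComparison:
    """Median-split survival comparison on a signature score.

    Scores every sample by mean signature expression, splits the cohort
    at the median, and reports Kaplan-Meier curves for both groups, the
    log-rank test and the binary-covariate Cox hazard ratio (high vs
    low).
    """
    if cohort.expression is None:
        raise ValidationError("cohort carries no expression matrix")
    scores = mean_signature_score(cohort.expression, genes)
    labels = median_split(scores)
    high = labels == "high"
    t, e = cohort.time, cohort.event
    hm, lm = high.to_numpy(), (~high).to_numpy()
    chi2, p = logrank_test(t[hm], e[hm], t[lm], e[lm])
    hr, ci, p_wald = cox_hr_binary(labels.to_numpy(), t, e)
    return SurvivalComparison(
        n_high=int(hm.sum()),
        n_low=int(lm.sum()),
        chi2=chi2,
        p_logrank=p,
        hr=hr,
        hr_ci=ci,
        p_wald=p_wald,
        km_high=km_curve(t[hm], e[hm]),
        km_low=km_curve(t[lm], e[lm]),
        scores=scores,
    )


def stouffer_meta_z(zs: pd.DataFrame) -> pd.Series:
    """Combine per-cohort gene z-scores by the unweighted Stouffer method.

    ``meta_z = sum_c z_c / sqrt(n_cohorts)`` per gene over the cohorts in
    which the gene was scored.
    """
    n = zs.notna().sum(axis=1)
    return zs.sum(axis=1, skipna=True) / np.sqrt(n.clip(lower=1))
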