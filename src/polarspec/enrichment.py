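"""Weighted running-sum gene set enrichment analysis (GSEA).

Implements the classic Kolmogorov-Smirnov-style enrichment statistic:
walking down a ranked gene list, members of the query set ("hits")
increment a running sum by their weighted score share, non-members
("misses") decrement it by 1/(N - N_hit); the enrichment score (ES) is
the signed maximum deviation of this walk.  Significance comes from
permutation: gene-set permutation (random same-size member sets) for
preranked lists, or phenotype permutation (label shuffles with metric
re-computation) for two-class designs.  The normalized enrichment score
(NES) divides ES by the mean magnitude of same-sign null ES values, and
the FDR q compares the observed and pooled-null NES distributions.

Also provides the activation-axis classifier: the difference between the
NES of the M(LPS)+ and M(LPS)- signatures on one ranked list, positive
values indicating an LPS-high (M1-skewed) state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from polarspec.data_io import GeneSet, ValidationError, sort_ranked
from polarspec.signatures import SignaturePair

logger = logging.getLogger(__name__)


class NoOverlapError(ValueError):
    """No member of the gene set appears in the ranked list."""


@dataclass
class EnrichmentResult:
    """One gene set scored on one ranked list."""

    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    n_matched: int
    peak_index: int
    running_scores: np.ndarray | None = None
    nes_defined: bool = True


def rank_by_signal_to_noise(
    expr: pd.DataFrame,
    labels: Sequence[str],
    positive_class: str | None = None,
    sigma_floor_abs: float = 1.0,
) -> pd.Series:
    """Rank genes by the two-class signal-to-noise ratio.

    ``s2n = (mu_A - mu_B) / (sigma_A + sigma_B)`` with each class standard
    deviation floored at ``max(0.2 * |mu|, 0.2 * sigma_floor_abs)`` — the
    shrinkage used by the standard GSEA two-class metric, which keeps
    low-variance genes from dominating.  Class A is ``positive_class``
    (default: the class of the first sample), so positive scores mean
    higher expression in that class.
    """
    labels = list(labels)
    if len(labels) != expr.shape[1]:
        raise ValidationError("label count does not match sample count")
    classes = list(dict.fromkeys(labels))
    if len(classes) != 2:
        raise ValidationError(f"need exactly two classes, got {classes}")
    pos = positive_class if positive_class is not None else classes[0]
    if pos not in classes:
        raise ValidationError(f"positive class {pos!r} not among {classes}")
    neg = classes[0] if pos == classes[1] else classes[1]
    mask = np.array([l == pos for l in labels])
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValidationError("each class needs at least 3 samples (metric unstable)")
    X = expr.to_numpy(dtype=float)
    mu_a, mu_b = X[:, mask].mean(axis=1), X[:, ~mask].mean(axis=1)
    sd_a, sd_b = X[:, mask].std(axis=1, ddof=1), X[:, ~mask].std(axis=1, ddof=1)
    floor = 0.2 * sigma_floor_abs
    sd_a = np.maximum(sd_a, np.maximum(0.2 * np.abs(mu_a), floor))
    sd_b = np.maximum(sd_b, np.maximum(0.2 * np.abs(mu_b), floor))
    s2n = (mu_a - mu_b) / (sd_a + sd_b)
    return sort_ranked(pd.Series(s2n, index=expr.index))


def rank_by_expression(expr: pd.DataFrame) -> pd.Series:
    """Rank genes by mean expression across samples (pre-weighted mode)."""
    if expr.shape[1] < 1:
        raise ValidationError("need at least one sample")
    return sort_ranked(expr.mean(axis=1))


def _hit_mask(ranked: pd.Series, gene_set: GeneSet) -> np.ndarray:
    members = gene_set.upper_members()
    return ranked.index.str.upper().isin(members)


def enrichment_score(
    ranked: pd.Series,
    gene_set: GeneSet,
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, int]:
    """Running-sum enrichment score of one gene set on a ranked list.

    Hits add ``|score_i|**weight_p / sum_hits(|score|**weight_p)``; misses
    subtract ``1 / (N - N_hit)``.  With ``weight_p = 0`` every hit adds
    ``1 / N_hit`` (classic unweighted KS statistic).  Returns the signed
    maximum-deviation ES, the full running-score curve (one value per
    rank) and the 0-based index of the peak.
    """
    hits = _hit_mask(ranked, gene_set)
    n = len(ranked)
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise NoOverlapError(f"no member of {gene_set.name!r} found in the ranked list")
    if n_hit == n:
        raise ValidationError(f"set {gene_set.name!r} covers the entire list (degenerate)")
    scores = ranked.to_numpy(dtype=float)
    weights = np.abs(scores) ** weight_p
    hit_w = np.where(hits, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit scores are exactly 0: fall back to equal increments
        hit_w = hits.astype(float)
        total = float(n_hit)
    running = np.cumsum(hit_w / total - (~hits) / (n - n_hit))
    mx, mn = running.max(), running.min()
    # sign near-ties (|max| ~ |min| within 1e-12) resolve positive so the
    # choice is stable under floating-point summation order
    if mx >= -mn - 1e-12:
        es, peak = float(mx), int(np.argmax(running))
    else:
        es, peak = float(mn), int(np.argmin(running))
    return es, running, peak


def _batch_es(ranked_scores: np.ndarray, positions: np.ndarray, weight_p: float) -> np.ndarray:
    """ES for a batch of hit-position sets on one ranked score vector.

    ``positions`` is (n_perm, k), 0-based ranks of the k hits per
    permutation.  Extrema of the running sum occur only immediately
    before or after a hit, so only 2k candidate values per permutation
    are evaluated.  Matches :func:`enrichment_score` exactly.
    """
    n = ranked_scores.size
    n_perm, k = positions.shape
    pos = np.sort(positions, axis=1)
    w = np.abs(ranked_scores[pos]) ** weight_p
    total = w.sum(axis=1, keepdims=True)
    zero = total[:, 0] == 0
    if np.any(zero):  # same all-zero-score fallback as enrichment_score
        w[zero] = 1.0
        total[zero] = k
    hit_cum = np.cumsum(w, axis=1) / total
    miss = 1.0 / (n - k)
    j = np.arange(k)[None, :]
    after = hit_cum - (pos - j) * miss  # running value at each hit index
    before = after - w / total  # value just before each hit
    cand = np.concatenate([before, after], axis=1)
    pos_max = cand.max(axis=1)
    neg_min = cand.min(axis=1)
    return np.where(pos_max >= -neg_min - 1e-12, pos_max, neg_min)


def leading_edge(
    ranked: pd.Series,
    gene_set: GeneSet,
    es: float,
    peak_index: int,
) -> tuple[str, ...]:
    """Core members driving the enrichment, ordered by rank.

    For positive ES: set members at ranks <= peak; for negative ES:
    members at ranks >= peak.  A zero ES yields an empty leading edge.
    """
    if es == 0:
        logger.warning("zero enrichment score for %s: empty leading edge", gene_set.name)
        return ()
    hits = _hit_mask(ranked, gene_set)
    idx = np.flatnonzero(hits)
    idx = idx[idx <= peak_index] if es > 0 else idx[idx >= peak_index]
    return tuple(ranked.index[idx])


def normalize_and_test(
    ranked: pd.Series,
    sets: Sequence[GeneSet],
    n_perm: int = 100,
    mode: Literal["gene_set", "phenotype"] = "gene_set",
    seed: int = 0,
    weight_p: float = 1.0,
    expr: pd.DataFrame | None = None,
    labels: Sequence[str] | None = None,
    positive_class: str | None = None,
    keep_running: bool = False,
) -> list[EnrichmentResult]:
    """Permutation-normalized enrichment of several sets on one list.

    For each set the null ES distribution comes from ``n_perm``
    permutations: random equal-size member sets (``gene_set`` mode) or
    label shuffles with signal-to-noise re-ranking (``phenotype`` mode,
    which requires ``expr`` and ``labels``).  NES divides ES by the mean
    |null ES| of matching sign; the nominal p is the one-sided add-one
    smoothed frequency among same-sign nulls; the FDR q compares the
    observed NES with the pooled null NES distribution of matching sign.
    Fixed ``seed`` gives bitwise-identical output.
    """
    if n_perm < 10:
        raise ValidationError("n_perm must be at least 10")
    if mode == "phenotype" and (expr is None or labels is None):
        raise ValidationError("phenotype mode needs expr and labels")
    rng = np.random.default_rng(seed)
    scores = ranked.to_numpy(dtype=float)
    n = scores.size

    observed = []
    for gs in sets:
        es, running, peak = enrichment_score(ranked, gs, weight_p)
        le = leading_edge(ranked, gs, es, peak)
        observed.append((gs, es, running if keep_running else None, peak, le))

    if mode == "phenotype":
        null_rankings = []
        lab = np.array(list(labels))
        for _ in range(n_perm):
            null_rankings.append(
                rank_by_signal_to_noise(
                    expr, lab[rng.permutation(lab.size)], positive_class=positive_class
                )
            )

    null_es: list[np.ndarray] = []
    for gs, es, _, _, _ in observed:
        k = int(_hit_mask(ranked, gs).sum())
        if mode == "gene_set":
            positions = np.array([rng.choice(n, size=k, replace=False) for _ in range(n_perm)])
            null_es.append(_batch_es(scores, positions, weight_p))
        else:
            vals = np.array([enrichment_score(rk, gs, weight_p)[0] for rk in null_rankings])
            null_es.append(vals)

    # sign-matched normalization of observed and null ES
    results: list[EnrichmentResult] = []
    all_null_nes: list[np.ndarray] = []
    nes_list: list[float] = []
    for (gs, es, running, peak, le), nulls in zip(observed, null_es):
        pos_mean = np.mean(nulls[nulls > 0]) if np.any(nulls > 0) else np.nan
        neg_mean = np.mean(np.abs(nulls[nulls < 0])) if np.any(nulls < 0) else np.nan
        null_nes = np.where(nulls >= 0, nulls / pos_mean, nulls / neg_mean)
        all_null_nes.append(null_nes[np.isfinite(null_nes)])
        same_sign = nulls >= 0 if es >= 0 else nulls < 0
        n_same = int(same_sign.sum())
        defined = True
        if n_same == 0:
            logger.warning("no same-sign null ES for %s: NES undefined", gs.name)
            nes, p_nom, defined = np.nan, np.nan, False
        else:
            denom = pos_mean if es >= 0 else neg_mean
            nes = es / denom
            p_nom = (1 + int(np.sum(np.abs(nulls[same_sign]) >= abs(es)))) / (1 + n_same)
        nes_list.append(nes)
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                es=es,
                nes=float(nes),
                p_nominal=float(p_nom),
                fdr_q=np.nan,
                leading_edge=le,
                n_matched=int(_hit_mask(ranked, gs).sum()),
                peak_index=peak,
                running_scores=running,
                nes_defined=defined,
            )
        )

    pooled = np.concatenate(all_null_nes) if all_null_nes else np.array([])
    obs_nes = np.array(nes_list, dtype=float)
    for res in results:
        if not res.nes_defined:
            continue
        res.fdr_q = _fdr_q(res.nes, obs_nes[np.isfinite(obs_nes)], pooled)
    return results


def _fdr_q(nes: float, observed_nes: np.ndarray, null_nes: np.ndarray) -> float:
    """Classic GSEA FDR: pooled-null vs observed NES tail ratio, capped at 1."""
    if nes >= 0:
        null_side = null_nes[null_nes >= 0]
        obs_side = observed_nes[observed_nes >= 0]
        num = np.mean(null_side >= nes) if null_side.size else 1.0
        den = np.mean(obs_side >= nes) if obs_side.size else 1.0
    else:
        null_side = null_nes[null_nes < 0]
        obs_side = observed_nes[observed_nes < 0]
        num = np.mean(null_side <= nes) if null_side.size else 1.0
        den = np.mean(obs_side <= nes) if obs_side.size else 1.0
    if den == 0:
        return 1.0
    return float(min(1.0, num / den))


@dataclass
class ActivationAxisScore:
    """Placement of one dataset on the M(LPS)+ / M(LPS)- activation axis.

    ``score = nes_pos - nes_neg``: positive values indicate an LPS-high
    (M1-skewed) state, negative values an LPS-low (M2-skewed) state.  The
    raw quotient ``nes_pos / nes_neg`` is also reported but its sign does
    not carry the axis semantics when the two NES values have opposite
    signs.
    """

    nes_pos: float
    nes_neg: float
    score: float
    ratio: float


def activation_axis(
    ranked: pd.Series,
    sigs: SignaturePair,
    top_n: int = 200,
    n_perm: int = 100,
    seed: int = 0,
    weight_p: float = 1.0,
) -> ActivationAxisScore:
    """Score a ranked list on the LPS-responsiveness activation axis.

    Runs gene-set-permutation GSEA of the top-``top_n`` (by |r|) M(LPS)+
    and M(LPS)- signature genes and combines the two NES values.
    """
    sets = [sigs.top(top_n, "pos"), sigs.top(top_n, "neg")]
    results = normalize_and_test(ranked, sets, n_perm=n_perm, mode="gene_set", seed=seed, weight_p=weight_p)
    nes_pos, nes_neg = results[0].nes, results[1].nes
    ratio = nes_pos / nes_neg if nes_neg != 0 else np.nan
    return ActivationAxisScore(
        nes_pos=nes_pos, nes_neg=nes_neg, score=nes_pos - nes_neg, ratio=float(ratio)
    )


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (one row per set) for reporting."""
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "matched": [r.n_matched for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_nominal": [r.p_nominal for r in results],
            "fdr_q": [r.fdr_q for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
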