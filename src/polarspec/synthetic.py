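"""Synthetic panels and cohorts with planted, recoverable ground truth.

Three generators mirror the three downstream analyses:

* :func:`generate_strain_panel` — a multi-strain baseline/LPS expression
  panel in which a latent per-strain LPS responsiveness drives correlated
  up/down gene programs anchored by Il12b, Nos2 and Arg1, emulating the
  continuous activation spectrum observed across inbred mouse strains.
* :func:`generate_case_control` — a two-class cohort with a planted
  expression shift on a known gene set, for enrichment testing.
* :func:`generate_survival_cohort` — patients whose exponential event
  hazard scales with a signature score, for survival stratification.

All values are generated directly on the RMA (log2) scale and clipped to
[2, 14], the typical range of RMA-normalized microarray intensities.  All
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from polarspec.data_io import SurvivalCohort
from polarspec.polarization import StrainPanel

ANCHOR_GENES = ("Il12b", "Nos2", "Arg1")

RMA_MIN, RMA_MAX = 2.0, 14.0
BASELINE_SD = 0.3  # within-population spread of per-gene baseline expression


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class PanelConfig:
    """Configuration of a synthetic strain panel.

    Defaults emulate the study design this package targets: 83 strains, a
    2000-gene chip slice with 200 positively and 200 negatively responding
    genes of one log2-unit effect per unit responsiveness, and replicate
    noise of 0.3 log2 units.
    """

    n_strains: int = 83
    n_genes: int = 2000
    n_pos_responders: int = 200
    n_neg_responders: int = 200
    beta_scale: float = 1.0
    noise_sd: float = 0.3
    baseline_mean_range: tuple[float, float] = (4.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 3:
            raise ConfigurationError("need at least 3 strains")
        if self.n_pos_responders < 0 or self.n_neg_responders < 0 or self.n_genes <= 0:
            raise ConfigurationError("gene counts must be non-negative (n_genes positive)")
        if self.n_pos_responders + self.n_neg_responders + len(ANCHOR_GENES) > self.n_genes:
            raise ConfigurationError("responders plus anchors exceed n_genes")
        if not self.noise_sd > 0:
            raise ConfigurationError("noise_sd must be positive")
        lo, hi = self.baseline_mean_range
        if not lo < hi:
            raise ConfigurationError("baseline_mean_range must be a proper interval")


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator.

    ``responsiveness`` is the latent per-strain (or per-sample) driver;
    ``pos_gene_ids`` / ``neg_gene_ids`` are the planted responder sets;
    ``beta`` maps gene id -> log2-units effect per unit responsiveness;
    ``survival_log_hr`` is set only by the survival generator.
    """

    responsiveness: pd.Series
    pos_gene_ids: frozenset[str] = frozenset()
    neg_gene_ids: frozenset[str] = frozenset()
    beta: pd.Series | None = None
    survival_log_hr: float | None = None

    def __post_init__(self) -> None:
        if self.pos_gene_ids & self.neg_gene_ids:
            raise ConfigurationError("positive and negative planted sets overlap")
        if not np.all(np.isfinite(self.responsiveness.to_numpy(dtype=float))):
            raise ConfigurationError("latent responsiveness must be finite")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_strain_panel(config: PanelConfig) -> tuple[StrainPanel, SyntheticTruth]:
    """Simulate a baseline/LPS strain panel with a latent responsiveness.

    Model (all on the RMA log2 scale):

    * latent responsiveness ``r_s ~ Uniform(0, 1)`` per strain;
    * per-gene baseline mean ``mu_g ~ Uniform(baseline_mean_range)``;
    * baseline value ``b_gs ~ Normal(mu_g, 0.3)`` (Arg1 gets doubled
      baseline variance, reflecting the large inter-strain arginase
      spread seen in real panels);
    * LPS value ``x_gs = b_gs + beta_g * r_s + eps``, with
      ``eps ~ Normal(0, noise_sd)``.

    Anchor effects: Il12b ``+4*beta_scale``, Nos2 ``+3*beta_scale``
    (strong induction in responders), Arg1 ``-2*beta_scale`` (suppressed
    in responders).  Planted responder genes get ``+-beta_scale``; all
    remaining genes have ``beta = 0``.
    """
    rng = np.random.default_rng(config.seed)
    n_body = config.n_genes - len(ANCHOR_GENES)
    genes = list(ANCHOR_GENES) + _gene_ids(n_body)
    body = np.array(_gene_ids(n_body))
    picked = rng.choice(body, size=config.n_pos_responders + config.n_neg_responders, replace=False)
    pos_ids = frozenset(picked[: config.n_pos_responders])
    neg_ids = frozenset(picked[config.n_pos_responders :])

    beta = pd.Series(0.0, index=genes)
    beta["Il12b"] = 4.0 * config.beta_scale
    beta["Nos2"] = 3.0 * config.beta_scale
    beta["Arg1"] = -2.0 * config.beta_scale
    beta[list(pos_ids)] = config.beta_scale
    beta[list(neg_ids)] = -config.beta_scale

    strains = [f"strain{i:03d}" for i in range(1, config.n_strains + 1)]
    r = rng.uniform(0.0, 1.0, size=config.n_strains)

    lo, hi = config.baseline_mean_range
    mu = rng.uniform(lo, hi, size=config.n_genes)
    # anchors follow the canonical pattern: Il12b/Nos2 low at baseline,
    # Arg1 high and variable
    mu[genes.index("Il12b")] = 4.0
    mu[genes.index("Nos2")] = 4.0
    mu[genes.index("Arg1")] = 8.0
    base_sd = np.full(config.n_genes, BASELINE_SD)
    base_sd[genes.index("Arg1")] = BASELINE_SD * np.sqrt(2.0)  # doubled variance
    b = mu[:, None] + base_sd[:, None] * rng.standard_normal((config.n_genes, config.n_strains))
    eps = config.noise_sd * rng.standard_normal((config.n_genes, config.n_strains))
    x = b + beta.to_numpy()[:, None] * r[None, :] + eps

    base_cols = [f"{s}_base" for s in strains]
    lps_cols = [f"{s}_lps" for s in strains]
    baseline = pd.DataFrame(np.clip(b, RMA_MIN, RMA_MAX), index=genes, columns=base_cols)
    lps = pd.DataFrame(np.clip(x, RMA_MIN, RMA_MAX), index=genes, columns=lps_cols)
    panel = StrainPanel(
        baseline=baseline,
        lps=lps,
        baseline_cols={s: [c] for s, c in zip(strains, base_cols)},
        lps_cols={s: [c] for s, c in zip(strains, lps_cols)},
    )
    truth = SyntheticTruth(
        responsiveness=pd.Series(r, index=strains),
        pos_gene_ids=pos_ids,
        neg_gene_ids=neg_ids,
        beta=beta,
    )
    return panel, truth


def generate_case_control(
    n_cases: int,
    n_controls: int,
    shifted_gene_ids: Sequence[str],
    shift: float,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_genes: int = 2000,
    baseline_mean_range: tuple[float, float] = (4.0, 10.0),
) -> tuple[pd.DataFrame, list[str], SyntheticTruth]:
    """Simulate a two-class cohort with a planted shift on known genes.

    Controls are drawn ``Normal(mu_g, noise_sd)``; cases additionally get
    ``+shift`` log2 units on ``shifted_gene_ids`` only.  Returns the
    expression matrix (cases first, then controls), positional two-class
    labels (``"case"`` / ``"control"``, CLS-compatible) and the truth.
    """
    if not np.isfinite(shift):
        raise ConfigurationError("shift must be finite")
    if shift != 0 and len(shifted_gene_ids) == 0:
        raise ConfigurationError("nonzero shift requires a non-empty shifted gene set")
    if n_cases < 1 or n_controls < 1 or noise_sd <= 0:
        raise ConfigurationError("cohort sizes must be positive and noise_sd > 0")
    genes = _gene_ids(n_genes)
    unknown = set(shifted_gene_ids) - set(genes)
    if unknown:
        raise ConfigurationError(f"shifted ids not in generated genes: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    lo, hi = baseline_mean_range
    mu = rng.uniform(lo, hi, size=n_genes)
    n = n_cases + n_controls
    values = mu[:, None] + noise_sd * rng.standard_normal((n_genes, n))
    shifted_mask = np.isin(np.array(genes), list(shifted_gene_ids))
    values[np.ix_(shifted_mask, np.arange(n_cases))] += shift
    samples = [f"case{i:03d}" for i in range(1, n_cases + 1)] + [
        f"ctrl{i:03d}" for i in range(1, n_controls + 1)
    ]
    expr = pd.DataFrame(np.clip(values, RMA_MIN, RMA_MAX), index=genes, columns=samples)
    labels = ["case"] * n_cases + ["control"] * n_controls
    truth = SyntheticTruth(
        responsiveness=pd.Series([1.0] * n_cases + [0.0] * n_controls, index=samples),
        pos_gene_ids=frozenset(shifted_gene_ids) if shift >= 0 else frozenset(),
        neg_gene_ids=frozenset(shifted_gene_ids) if shift < 0 else frozenset(),
        beta=pd.Series(np.where(shifted_mask, shift, 0.0), index=genes),
    )
    return expr, labels, truth


def _censor_horizon(rates: np.ndarray, censor_frac: float) -> float:
    """Upper bound tau of Uniform(0, tau) censoring hitting censor_frac.

    For exponential event times with per-patient rate lambda_i and
    C ~ Uniform(0, tau), P(censored) = mean_i (1 - exp(-lambda_i tau)) /
    (lambda_i tau), which decreases monotonically from 1 to 0 in tau.
    """

    def frac(tau: float) -> float:
        z = rates * tau
        return float(np.mean((1.0 - np.exp(-z)) / z)) - censor_frac

    lo, hi = 1e-9, 1.0
    while frac(hi) > 0:
        hi *= 10.0
        if hi > 1e12:
            break
    return brentq(frac, lo, hi)


def generate_survival_cohort(
    n_patients: int,
    signature_gene_ids: Sequence[str],
    log_hr_per_sd: float,
    censor_frac: float = 0.3,
    seed: int = 0,
    n_genes: int = 500,
    noise_sd: float = 0.5,
    baseline_hazard: float = 0.1,
    baseline_mean_range: tuple[float, float] = (4.0, 10.0),
    gene_ids: Sequence[str] | None = None,
) -> tuple[SurvivalCohort, SyntheticTruth]:
    """Simulate a cohort whose hazard scales with a signature score.

    Expression is ``Normal(mu_g, noise_sd)``; the patient score ``z`` is
    the standardized mean expression over ``signature_gene_ids``; event
    times are ``Exponential(rate = h0 * exp(log_hr_per_sd * z))``.
    Censoring is independent ``Uniform(0, tau)`` with ``tau`` solved so
    the expected censored fraction equals ``censor_frac``.
    """
    if not 0 <= censor_frac < 1:
        raise ConfigurationError("censor_frac must lie in [0, 1)")
    if n_patients < 10:
        raise ConfigurationError("need at least 10 patients")
    if not signature_gene_ids:
        raise ConfigurationError("signature gene set is empty")
    genes = list(gene_ids) if gene_ids is not None else _gene_ids(n_genes)
    n_genes = len(genes)
    unknown = set(signature_gene_ids) - set(genes)
    if unknown:
        raise ConfigurationError(f"signature ids not in generated genes: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    lo, hi = baseline_mean_range
    mu = rng.uniform(lo, hi, size=n_genes)
    values = mu[:, None] + noise_sd * rng.standard_normal((n_genes, n_patients))
    samples = [f"pt{i:04d}" for i in range(1, n_patients + 1)]
    expr = pd.DataFrame(np.clip(values, RMA_MIN, RMA_MAX), index=genes, columns=samples)

    sig = expr.loc[list(signature_gene_ids)].mean(axis=0)
    if sig.std(ddof=0) == 0:
        raise ConfigurationError("degenerate (constant) signature expression")
    z = (sig - sig.mean()) / sig.std(ddof=0)
    rates = baseline_hazard * np.exp(log_hr_per_sd * z.to_numpy())
    event_times = rng.exponential(1.0 / rates)
    if censor_frac == 0:
        times, events = event_times, np.ones(n_patients, dtype=int)
    else:
        tau = _censor_horizon(rates, censor_frac)
        censor_times = rng.uniform(0.0, tau, size=n_patients)
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)
    cohort = SurvivalCohort(tuple(samples), times, events, expression=expr)
    truth = SyntheticTruth(
        responsiveness=z,
        pos_gene_ids=frozenset(signature_gene_ids),
        survival_log_hr=log_hr_per_sd,
    )
    return cohort, truth
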