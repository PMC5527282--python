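"""Polarization factor ratios (PFR) across a strain panel.

The PFR quantifies each strain's macrophage polarization state as the
ratio of a pro-inflammatory marker (IL-12beta, gene ``Il12b``, or iNOS,
gene ``Nos2``) to arginase-1 (``Arg1``) on RMA-scale expression values,
normalized to the population's baseline mean ratio:

    ratio_s   = E[num, s] / E[den, s]          (per strain, per condition)
    pfr_s     = ratio_s / mean_s(ratio_s at baseline)

Both the baseline and the LPS-treated PFR are normalized by the *baseline*
population mean, so the LPS PFR measures shift relative to the untreated
population state.  A PFR above 1 after LPS indicates a shift toward the
M(LPS)+ (M1-like) pole, below 1 toward M(LPS)- (M2-like).

Note the ratio is taken on RMA (log2) values directly, not as a
log-difference; see docs/methods.md for discussion of this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from polarspec.data_io import ValidationError, match_genes


class GeneLookupError(KeyError):
    """A required marker gene is absent from the panel."""


@dataclass
class StrainPanel:
    """Paired baseline / LPS expression matrices over a panel of strains.

    ``baseline`` and ``lps`` are gene x sample DataFrames sharing a gene
    index; ``baseline_cols`` / ``lps_cols`` map each strain to its
    replicate columns (>=1 per condition).
    """

    baseline: pd.DataFrame
    lps: pd.DataFrame
    baseline_cols: Mapping[str, Sequence[str]]
    lps_cols: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        if not self.baseline.index.equals(self.lps.index):
            raise ValidationError("baseline and LPS matrices must share the gene index")
        if set(self.baseline_cols) != set(self.lps_cols):
            raise ValidationError("strain sets differ between conditions")
        for strain in self.baseline_cols:
            if not self.baseline_cols[strain] or not self.lps_cols[strain]:
                raise ValidationError(f"strain {strain!r} lacks replicate columns")

    @property
    def strain_ids(self) -> list[str]:
        return sorted(self.baseline_cols)

    @property
    def gene_ids(self) -> pd.Index:
        return self.baseline.index

    def strain_means(self, condition: Literal["baseline", "lps"]) -> pd.DataFrame:
        """Replicate-averaged gene x strain matrix (RMA scale)."""
        expr = self.baseline if condition == "baseline" else self.lps
        cols = self.baseline_cols if condition == "baseline" else self.lps_cols
        data = {s: expr[list(cols[s])].mean(axis=1) for s in self.strain_ids}
        return pd.DataFrame(data)

    def _marker_row(self, means: pd.DataFrame, gene: str) -> pd.Series:
        hits = match_genes(means.index, [gene])
        if not hits:
            raise GeneLookupError(f"gene {gene!r} not found in the panel")
        return means.loc[hits[0]]


def panel_from_design(expr: pd.DataFrame, design: pd.DataFrame) -> StrainPanel:
    """Assemble a StrainPanel from one matrix and a sample design table.

    ``design`` needs columns ``sample``, ``strain`` and ``condition``
    (``baseline`` or ``lps``); samples are replicate columns of ``expr``.
    """
    required = {"sample", "strain", "condition"}
    if not required.issubset(design.columns):
        raise ValidationError(f"design table needs columns {sorted(required)}")
    bad = set(design["condition"]) - {"baseline", "lps"}
    if bad:
        raise ValidationError(f"unknown conditions in design: {sorted(bad)}")
    missing = set(design["sample"]) - set(expr.columns)
    if missing:
        raise ValidationError(f"design samples absent from matrix: {sorted(missing)[:5]}")
    cols: dict[str, dict[str, list[str]]] = {"baseline": {}, "lps": {}}
    for _, row in design.iterrows():
        cols[row["condition"]].setdefault(str(row["strain"]), []).append(str(row["sample"]))
    return StrainPanel(
        baseline=expr[[s for ss in cols["baseline"].values() for s in ss]],
        lps=expr[[s for ss in cols["lps"].values() for s in ss]],
        baseline_cols=cols["baseline"],
        lps_cols=cols["lps"],
    )


def compute_pfr(
    panel: StrainPanel,
    numerator_gene: str = "Il12b",
    denominator_gene: str = "Arg1",
) -> pd.DataFrame:
    """Compute per-strain polarization factor ratios for both conditions.

    Replicates are averaged on the RMA scale before the ratio.  The ratio
    for each condition is divided by the arithmetic population mean of the
    *baseline* ratios, so ``pfr_base`` averages to exactly 1 across
    strains.

    Returns
    -------
    pandas.DataFrame
        Indexed by strain with columns ``ratio_base``, ``ratio_lps``,
        ``pfr_base``, ``pfr_lps`` and ``rank`` (1 = lowest LPS responder;
        ties broken lexicographically by strain id).
    """
    base = panel.strain_means("baseline")
    lps = panel.strain_means("lps")
    num_b = panel._marker_row(base, numerator_gene)
    den_b = panel._marker_row(base, denominator_gene)
    num_l = panel._marker_row(lps, numerator_gene)
    den_l = panel._marker_row(lps, denominator_gene)
    if np.any(den_b == 0) or np.any(den_l == 0):
        raise ValidationError(
            f"denominator gene {denominator_gene!r} has a zero RMA value; "
            "RMA intensities are strictly positive"
        )
    ratio_base = num_b / den_b
    ratio_lps = num_l / den_l
    pop_mean = ratio_base.mean()
    table = pd.DataFrame(
        {
            "ratio_base": ratio_base,
            "ratio_lps": ratio_lps,
            "pfr_base": ratio_base / pop_mean,
            "pfr_lps": ratio_lps / pop_mean,
        }
    )
    table.index.name = "strain"
    order = rank_strains(table, "lps")
    table["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    return table


def rank_strains(table: pd.DataFrame, condition: Literal["baseline", "lps"] = "lps") -> list[str]:
    """Strain ids in ascending PFR order (lowest responder first).

    Ties break lexicographically by strain id, so the ranking is a
    deterministic permutation of the strains regardless of input row
    order.
    """
    col = "pfr_base" if condition == "baseline" else "pfr_lps"
    pfr = table[col]
    order = np.lexsort((table.index.to_numpy(), pfr.to_numpy()))
    return list(table.index[order])


def fold_change(panel: StrainPanel, gene: str) -> pd.Series:
    """Per-strain linear fold change of ``gene`` under LPS: 2**(RMA_lps - RMA_base)."""
    base = panel.strain_means("baseline")
    lps = panel.strain_means("lps")
    b = panel._marker_row(base, gene)
    l = panel._marker_row(lps, gene)
    return np.power(2.0, l - b)
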