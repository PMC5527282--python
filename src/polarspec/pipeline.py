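"""End-to-end orchestration of the synthetic analysis pipeline.

Runs simulate -> PFR -> signature extraction -> enrichment /
activation-axis classification -> survival stratification, writing every
intermediate artifact plus a machine-readable run manifest.  A single
global seed fans out deterministically to per-stage seeds (seed + stage
index), so identical configs give identical manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from polarspec import data_io, enrichment, polarization, signatures, survival, synthetic

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs.

    Thresholds mirror the analysis defaults: dual signature threshold
    P < 1e-4 and BH FDR < 5%, top-200 signature subsets for enrichment,
    top-30 leading-edge genes for tumour sets.
    """

    out_dir: str = "polarspec_run"
    seed: int = 0
    # panel stage
    panel: synthetic.PanelConfig | None = None
    # thresholds
    p_max: float = 1e-4
    fdr_max: float = 0.05
    top_n: int = 200
    k_tumor: int = 30
    n_perm: int = 200
    # case/control stage
    n_cases: int = 20
    n_controls: int = 20
    case_shift: float = 1.0
    case_noise_sd: float = 0.5
    # survival stage
    n_patients: int = 200
    log_hr_per_sd: float = 0.7
    censor_frac: float = 0.3
    n_survival_genes: int = 400
    run_survival: bool = True

    def __post_init__(self) -> None:
        if self.panel is None:
            self.panel = synthetic.PanelConfig(seed=self.seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest (also written to disk).

    Artifacts written under ``config.out_dir``: ``panel.gct`` +
    ``design.tsv``, ``pfr.tsv``, ``records.tsv`` + ``sigs.gmt``,
    ``case_control.gct`` + ``labels.cls`` + ``gsea.tsv`` + ``axis.tsv``,
    ``survival.tsv`` + ``survival_report.tsv`` and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            **{k: v for k, v in asdict(config).items() if k != "panel"},
            "panel": asdict(config.panel),
        },
        "stages": {},
        "metrics": {},
    }

    def record(stage: str, files: dict[str, Path], counts: dict[str, int]) -> None:
        manifest["stages"][stage] = {
            "files": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in files.items()},
            "counts": counts,
        }

    # --- stage 0: simulate panel ----------------------------------------
    try:
        panel_cfg = synthetic.PanelConfig(**{**asdict(config.panel), "seed": config.seed})
        panel, truth = synthetic.generate_strain_panel(panel_cfg)
        expr = pd.concat([panel.baseline, panel.lps], axis=1)
        data_io.write_gct(expr, out / "panel.gct")
        design = pd.DataFrame(
            [(c, s, "baseline") for s, cs in panel.baseline_cols.items() for c in cs]
            + [(c, s, "lps") for s, cs in panel.lps_cols.items() for c in cs],
            columns=["sample", "strain", "condition"],
        )
        design.to_csv(out / "design.tsv", sep="\t", index=False)
        record(
            "simulate_panel",
            {"panel": out / "panel.gct", "design": out / "design.tsv"},
            {"n_strains": panel_cfg.n_strains, "n_genes": panel_cfg.n_genes},
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage simulate_panel failed: {exc}") from exc

    # --- stage 1: polarization factor ratios ----------------------------
    try:
        pfr = polarization.compute_pfr(panel)
        pfr.to_csv(out / "pfr.tsv", sep="\t")
        rho = _stats.spearmanr(
            pfr["pfr_lps"].reindex(truth.responsiveness.index), truth.responsiveness
        ).statistic
        manifest["metrics"]["pfr_responsiveness_spearman"] = float(rho)
        record("pfr", {"pfr": out / "pfr.tsv"}, {"n_strains": len(pfr)})
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage pfr failed: {exc}") from exc

    # --- stage 2: signature extraction ----------------------------------
    try:
        sigs = signatures.extract_signatures(panel, pfr, config.p_max, config.fdr_max)
        sigs.records.to_csv(out / "records.tsv", sep="\t")
        data_io.write_gene_sets(sigs.as_gene_sets(), out / "sigs.gmt")
        recovered = set(sigs.pos.index) - set(synthetic.ANCHOR_GENES)
        planted = set(truth.pos_gene_ids)
        precision = len(recovered & planted) / len(recovered) if recovered else 0.0
        recall = len(recovered & planted) / len(planted) if planted else 0.0
        manifest["metrics"]["signature_precision"] = precision
        manifest["metrics"]["signature_recall"] = recall
        record(
            "signatures",
            {"records": out / "records.tsv", "sigs": out / "sigs.gmt"},
            {
                "n_tested": sigs.n_tested,
                "n_skipped": sigs.n_skipped_constant,
                "n_pos": len(sigs.pos),
                "n_neg": len(sigs.neg),
            },
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage signatures failed: {exc}") from exc

    # --- stage 3: case/control enrichment + activation axis -------------
    try:
        universe = [g for g in panel.gene_ids if g not in synthetic.ANCHOR_GENES]
        shifted = [g for g in sigs.pos.index if g in set(universe)][:100]
        cc_expr, labels, _ = synthetic.generate_case_control(
            config.n_cases,
            config.n_controls,
            shifted,
            shift=config.case_shift,
            noise_sd=config.case_noise_sd,
            seed=config.seed + 3,
            n_genes=config.panel.n_genes,
        )
        data_io.write_gct(cc_expr, out / "case_control.gct")
        data_io.write_phenotype_labels(labels, out / "labels.cls")
        ranked = enrichment.rank_by_signal_to_noise(cc_expr, labels, positive_class="case")
        data_io.write_ranked_list(ranked, out / "case_control.rnk")
        results = enrichment.normalize_and_test(
            ranked,
            sigs.as_gene_sets(config.top_n),
            n_perm=config.n_perm,
            mode="gene_set",
            seed=config.seed + 3,
        )
        enrichment.results_frame(results).to_csv(out / "gsea.tsv", sep="\t", index=False)
        axis = enrichment.activation_axis(
            ranked, sigs, top_n=config.top_n, n_perm=config.n_perm, seed=config.seed + 3
        )
        pd.DataFrame([asdict(axis)]).to_csv(out / "axis.tsv", sep="\t", index=False)
        manifest["metrics"]["case_control_nes_pos"] = axis.nes_pos
        manifest["metrics"]["case_control_axis_score"] = axis.score
        manifest["metrics"]["case_control_p_pos"] = results[0].p_nominal
        record(
            "enrichment",
            {
                "expr": out / "case_control.gct",
                "labels": out / "labels.cls",
                "rnk": out / "case_control.rnk",
                "gsea": out / "gsea.tsv",
                "axis": out / "axis.tsv",
            },
            {"n_sets": len(results), "n_matched_pos": results[0].n_matched},
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage enrichment failed: {exc}") from exc

    # --- stage 4: survival stratification -------------------------------
    if config.run_survival:
        try:
            sig_genes = [g for g in sigs.neg.index if g not in synthetic.ANCHOR_GENES][:30]
            if not sig_genes:
                raise data_io.ValidationError("no M(LPS)- genes available for survival stage")
            others = [g for g in universe if g not in set(sig_genes)]
            gene_universe = sorted(set(sig_genes) | set(others[: config.n_survival_genes]))
            cohort, s_truth = synthetic.generate_survival_cohort(
                config.n_patients,
                sig_genes,
                log_hr_per_sd=config.log_hr_per_sd,
                censor_frac=config.censor_frac,
                seed=config.seed + 4,
                gene_ids=gene_universe,
            )
            data_io.write_survival_table(cohort, out / "survival.tsv")
            data_io.write_gct(cohort.expression, out / "survival_expr.gct")
            ranked_z = survival.per_gene_survival_z(cohort)
            tumor_set = survival.select_tumor_gene_set(
                ranked_z, data_io.GeneSet("M_LPS_neg", "planted", tuple(sig_genes)), k=config.k_tumor
            )
            comp = survival.survival_by_signature(cohort, tumor_set)
            report = pd.DataFrame(
                [
                    {
                        "set": tumor_set.name,
                        "k_used": len(tumor_set),
                        "n_high": comp.n_high,
                        "n_low": comp.n_low,
                        "hr": comp.hr,
                        "ci_low": comp.hr_ci[0],
                        "ci_high": comp.hr_ci[1],
                        "logrank_chi2": comp.chi2,
                        "logrank_p": comp.p_logrank,
                    }
                ]
            )
            report.to_csv(out / "survival_report.tsv", sep="\t", index=False)
            manifest["metrics"]["survival_hr_high_vs_low"] = comp.hr
            manifest["metrics"]["survival_logrank_p"] = comp.p_logrank
            manifest["metrics"]["survival_planted_log_hr"] = s_truth.survival_log_hr
            record(
                "survival",
                {
                    "table": out / "survival.tsv",
                    "expr": out / "survival_expr.gct",
                    "report": out / "survival_report.tsv",
                },
                {
                    "n_patients": cohort.n,
                    "n_events": int(cohort.event.sum()),
                    "k_tumor": len(tumor_set),
                },
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage survival failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", manifest_path)
    return manifest
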