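"""End-to-end driver chaining the analysis stages.

The pipeline mirrors the two arms of the experiment: phospho-arm PSMs
are filtered, (optionally) impurity-corrected, converted to
control-relative ratios and rolled up to unique phospho-sites;
standard-arm PSMs yield gene-level protein ratios that normalize the
sites; normalized sites are tested for regulation per condition,
compared between singly- and multiply-phosphorylated rollups, and
annotated when reference tables are available.  Row counts are logged
at every stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import differential, quantify
from .io import PipelineConfig
from .quantify import StudyDesign

logger = logging.getLogger(__name__)

SITE_KEY = differential.SITE_KEY


@dataclass
class PipelineResult:
    """Bundle of every table a full run produces."""

    sites: pd.DataFrame
    sites_singly: pd.DataFrame
    sites_multiply: pd.DataFrame
    proteins: pd.DataFrame
    calls: pd.DataFrame
    calls_singly: pd.DataFrame
    calls_multiply: pd.DataFrame
    discordance: pd.DataFrame
    annotations: pd.DataFrame | None
    dropped_sites: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "sites": self.sites,
            "sites_singly": self.sites_singly,
            "sites_multiply": self.sites_multiply,
            "proteins": self.proteins,
            "calls": self.calls,
            "calls_singly": self.calls_singly,
            "calls_multiply": self.calls_multiply,
            "discordance": self.discordance,
            "dropped_sites": self.dropped_sites,
        }
        if self.annotations is not None:
            out["annotations"] = self.annotations
        return out


def run_pipeline(
    psms_phospho: pd.DataFrame,
    psms_standard: pd.DataFrame,
    config: PipelineConfig | None = None,
    protein_sequences: dict[str, str] | None = None,
    impurity_matrix: quantify.ImpurityMatrix | None = None,
    reference_sites: pd.DataFrame | None = None,
    score_table: pd.DataFrame | None = None,
    ground_truth: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the complete quantification and analysis chain in memory.

    When ``ground_truth`` (from the simulator) is supplied, the summary
    includes parameter-recovery metrics computed on the singly
    phosphorylated rollup.
    """
    config = config or PipelineConfig()
    design: StudyDesign = config.design
    summary: dict = {"n_psms_phospho_in": len(psms_phospho),
                     "n_psms_standard_in": len(psms_standard)}

    kept_p, rejected_p = quantify.filter_psms(psms_phospho, config.min_localization)
    kept_s, rejected_s = quantify.filter_psms(psms_standard, config.min_localization)
    summary["n_psms_phospho_kept"] = len(kept_p)
    summary["n_psms_phospho_rejected"] = len(rejected_p)
    summary["n_psms_standard_kept"] = len(kept_s)
    summary["n_psms_standard_rejected"] = len(rejected_s)

    if config.correct_impurities:
        if impurity_matrix is None:
            raise ValueError("impurity correction requested without a matrix")
        kept_p = quantify.correct_impurities_table(kept_p, impurity_matrix)
        kept_s = quantify.correct_impurities_table(kept_s, impurity_matrix)

    kept_p = quantify.psm_ratios(kept_p, design)
    kept_s = quantify.psm_ratios(kept_s, design)

    proteins = quantify.rollup_proteins(kept_s[kept_s["n_phospho"] == 0], design)
    summary["n_proteins_quantified"] = len(proteins)

    rollups = {}
    calls = {}
    for subset in ("all", "singly", "multiply"):
        sites = quantify.rollup_sites(kept_p, design, subset, protein_sequences)
        sites, dropped = quantify.normalize_sites_to_protein(sites, proteins, design)
        rollups[subset] = sites
        if subset == "all":
            dropped_all = dropped
            summary["n_sites_quantified"] = len(sites)
            summary["n_sites_dropped_no_protein"] = len(dropped)
        calls[subset] = (
            differential.test_regulation(
                sites, design, config.q_threshold, config.log2fc_threshold
            )
            if len(sites)
            else pd.DataFrame(
                columns=SITE_KEY
                + ["condition", "mean_log2fc", "p_value", "q_value",
                   "degenerate", "significant"]
            )
        )

    for condition in design.treated_conditions:
        sub = calls["all"]
        summary[f"n_significant_{condition}"] = int(
            sub.loc[sub["condition"] == condition, "significant"].sum()
        )

    discordance = differential.discordance_analysis(
        calls["singly"], calls["multiply"]
    )
    summary["n_sites_in_both_rollups"] = discordance[SITE_KEY].drop_duplicates().shape[0]
    summary["n_significant_singly_only"] = int(
        discordance["significant_singly_only"].sum()
    )
    summary["n_significant_multiply_only"] = int(
        discordance["significant_multiply_only"].sum()
    )

    annotations = None
    if reference_sites is not None:
        annotations = _annotate.cross_reference(rollups["all"], reference_sites)
        if score_table is not None:
            annotations = _annotate.classify_functionality(
                annotations, score_table, config.networkin_threshold
            )
        summary["n_known_sites"] = int(annotations["is_known"].sum())
        summary["n_novel_sites"] = int((~annotations["is_known"]).sum())

    if ground_truth is not None:
        summary.update(
            recovery_metrics(rollups["singly"], calls["singly"], ground_truth, design)
        )

    return PipelineResult(
        sites=rollups["all"],
        sites_singly=rollups["singly"],
        sites_multiply=rollups["multiply"],
        proteins=proteins,
        calls=calls["all"],
        calls_singly=calls["singly"],
        calls_multiply=calls["multiply"],
        discordance=discordance,
        annotations=annotations,
        dropped_sites=dropped_all,
        summary=summary,
    )


def recovery_metrics(
    sites_singly: pd.DataFrame,
    calls_singly: pd.DataFrame,
    ground_truth: pd.DataFrame,
    design: StudyDesign,
) -> dict:
    """Score recovered fold changes against simulator ground truth.

    The estimate per site and condition is the mean normalized log2
    ratio over that condition's channels in the singly phosphorylated
    rollup (a single site's stoichiometry change).  Reports the median
    and maximum absolute error and, per condition, the fraction of
    truly regulated sites called significant (sensitivity) and of true
    nulls called significant (false-call rate).
    """
    merged = sites_singly.merge(
        ground_truth, on=["gene", "protein_id", "position", "residue"], how="inner"
    )
    out: dict = {"n_sites_scored": len(merged)}
    errors = []
    for condition in design.treated_conditions:
        cols = quantify.normalized_columns(design.channels_for(condition))
        est = merged[cols].mean(axis=1).to_numpy()
        true = merged[f"true_log2fc_{_truth_name(condition)}"].to_numpy(dtype=float)
        errors.append(np.abs(est - true))
    if errors:
        all_err = np.concatenate(errors)
        out["median_abs_error_log2fc"] = float(np.median(all_err)) if len(all_err) else np.nan
        out["max_abs_error_log2fc"] = float(all_err.max()) if len(all_err) else np.nan

    merged_calls = calls_singly.merge(
        ground_truth, on=["gene", "protein_id", "position", "residue"], how="inner"
    )
    for condition in design.treated_conditions:
        sub = merged_calls[merged_calls["condition"] == condition]
        regulated = sub[f"is_regulated_{_truth_name(condition)}"].to_numpy(dtype=bool)
        significant = sub["significant"].to_numpy(dtype=bool)
        n_reg = int(regulated.sum())
        n_null = int((~regulated).sum())
        out[f"sensitivity_{condition}"] = (
            float(significant[regulated].mean()) if n_reg else np.nan
        )
        out[f"false_call_rate_{condition}"] = (
            float(significant[~regulated].mean()) if n_null else np.nan
        )
    return out


def _truth_name(condition: str) -> str:
    return {"pervanadate": "pervanadate", "mitotic": "mitosis"}[condition]
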