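"""Regulation calling, phospho-form discordance and clustering.

A phospho-site is called significantly regulated in a treated condition
when a two-sample t-test of its normalized log2 ratios (treated
replicates versus untreated replicates) survives Benjamini-Hochberg
correction at q < 0.01 and the fold change exceeds two (|log2 FC| > 1).
The fold change is the mean of the treated replicates' normalized log2
ratios; BH correction is applied across all tested sites within a
condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from statsmodels.stats.multitest import multipletests

from .quantify import DEFAULT_DESIGN, StudyDesign, normalized_columns

logger = logging.getLogger(__name__)

SITE_KEY = ["gene", "protein_id", "position", "residue"]


def test_regulation(
    sites: pd.DataFrame,
    design: StudyDesign = DEFAULT_DESIGN,
    q_threshold: float = 0.01,
    log2fc_threshold: float = 1.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Call per-condition regulation of normalized phospho-site ratios.

    Returns one row per (site, treated condition) with ``mean_log2fc``,
    ``p_value``, BH ``q_value``, the ``significant`` flag and a
    ``degenerate`` flag for zero-variance inputs (where p is set to 1
    by convention).
    """
    control_cols = normalized_columns(design.control_channels)
    frames = []
    for condition in design.treated_conditions:
        treated_cols = normalized_columns(design.channels_for(condition))
        if len(treated_cols) < 2 or len(control_cols) < 2:
            raise ValueError("need >= 2 replicates per compared group")
        treated = sites[treated_cols].to_numpy(dtype=float)
        control = sites[control_cols].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # zero-variance sites are handled by the p = 1 convention below
            warnings.filterwarnings(
                "ignore", message="Precision loss occurred", category=RuntimeWarning
            )
            _, p = stats.ttest_ind(treated, control, axis=1, equal_var=equal_var)
        degenerate = ~np.isfinite(p)
        if degenerate.any():
            logger.warning(
                "%s: %d zero-variance sites, p set to 1", condition, degenerate.sum()
            )
        p = np.where(degenerate, 1.0, p)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        mean_fc = treated.mean(axis=1)
        out = sites[SITE_KEY].copy()
        out["condition"] = condition
        out["mean_log2fc"] = mean_fc
        out["p_value"] = p
        out["q_value"] = q
        out["degenerate"] = degenerate
        out["significant"] = (q < q_threshold) & (np.abs(mean_fc) > log2fc_threshold)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def discordance_analysis(
    calls_singly: pd.DataFrame,
    calls_multiply: pd.DataFrame,
    condition: str | None = None,
) -> pd.DataFrame:
    """Compare regulation calls between singly and multiply rollups.

    Only sites present in both restricted rollups are reported; for
    each, flags mark whether it is significant exclusively in the
    singly phosphorylated rollup or exclusively in the multiply
    phosphorylated rollup.  ``condition`` restricts the comparison to
    one treated condition; by default all conditions in the call
    tables are compared (one record per site and condition).
    """
    left, right = calls_singly, calls_multiply
    if condition is not None:
        left = left[left["condition"] == condition]
        right = right[right["condition"] == condition]
    merged = left.merge(
        right,
        on=SITE_KEY + ["condition"],
        how="inner",
        suffixes=("_singly", "_multiply"),
    )
    out = merged[SITE_KEY + ["condition"]].copy()
    s_single = merged["significant_singly"].to_numpy(dtype=bool)
    s_multi = merged["significant_multiply"].to_numpy(dtype=bool)
    out["significant_singly_only"] = s_single & ~s_multi
    out["significant_multiply_only"] = s_multi & ~s_single
    return out


@dataclass
class ClusterResult:
    """Dendrogram orderings for a sites-by-channels matrix."""

    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: np.ndarray
    col_order: np.ndarray


def cluster_sites(matrix: pd.DataFrame) -> ClusterResult:
    """Complete-linkage hierarchical clustering with Euclidean distance.

    Rows (sites) and columns (channels) are clustered independently;
    the leaf orders are deterministic given the input order (scipy's
    tie-breaking is by cluster index).  Missing values are an error.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("clustering input contains missing values")
    row_linkage = linkage(values, method="complete", metric="euclidean")
    col_linkage = linkage(values.T, method="complete", metric="euclidean")
    return ClusterResult(
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        row_order=leaves_list(row_linkage),
        col_order=leaves_list(col_linkage),
    )
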