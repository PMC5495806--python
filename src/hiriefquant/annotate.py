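"""Phospho-site annotation: novelty, functionality and class enrichment.

Sites are cross-referenced against a reference table of known
phospho-sites (PhosphoSitePlus-style, keyed by protein identifier,
1-based position and residue).  Kinase-association scores
(NetworKIN-style, proteome-normalized so that 3 marks a confident
prediction) classify sites without a reported function as putatively
functional (score >= 3) or low-scoring (< 3); sites with a reported
function are "functional" regardless of score, and sites without any
prediction are "unscored".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = ("functional", "putatively_functional", "low_scoring", "unscored")
PROTEIN_CLASSES = ("kinase", "phosphatase", "transcription_factor", "ubl_enzyme")

REFERENCE_KEY = ["protein_id", "position", "residue"]


def cross_reference(sites: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Flag sites known in (and reported functional by) the reference.

    ``reference`` needs columns ``protein_id``, ``position``,
    ``residue`` and optionally a boolean ``is_functional``.  Matching
    is by exact key; a reference entry at a matched (protein,
    position) with a different residue indicates a coordinate
    convention mismatch and is logged as a warning.
    """
    out = sites.copy()
    if reference.empty:
        out["is_known"] = False
        out["is_functional"] = False
        return out
    ref = reference.drop_duplicates(subset=REFERENCE_KEY).copy()
    if "is_functional" not in ref.columns:
        ref["is_functional"] = False
    known_keys = set(map(tuple, ref[REFERENCE_KEY].itertuples(index=False)))
    functional_keys = set(
        map(
            tuple,
            ref.loc[ref["is_functional"], REFERENCE_KEY].itertuples(index=False),
        )
    )
    keys = list(map(tuple, out[REFERENCE_KEY].itertuples(index=False)))
    out["is_known"] = [k in known_keys for k in keys]
    out["is_functional"] = [k in functional_keys for k in keys]

    ref_positions = set(
        map(tuple, ref[["protein_id", "position"]].itertuples(index=False))
    )
    mismatches = sum(
        1
        for k, known in zip(keys, out["is_known"])
        if not known and (k[0], k[1]) in ref_positions
    )
    if mismatches:
        logger.warning(
            "%d sites match a reference position but not its residue; "
            "check the coordinate convention",
            mismatches,
        )
    return out


def classify_functionality(
    annotations: pd.DataFrame,
    score_table: pd.DataFrame,
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Attach the best kinase-association score and a functional class.

    ``score_table`` has columns ``protein_id``, ``position``,
    ``residue``, ``kinase``, ``score`` (several kinases per site); the
    highest score per site represents its kinase association strength.
    """
    out = annotations.copy()
    best = (
        score_table.groupby(REFERENCE_KEY)["score"].max()
        if len(score_table)
        else pd.Series(dtype=float)
    )
    keys = pd.MultiIndex.from_frame(out[REFERENCE_KEY])
    out["networkin_score"] = (
        best.reindex(keys).to_numpy() if len(best) else np.nan
    )
    score = out["networkin_score"].to_numpy(dtype=float)
    functional = out["is_functional"].to_numpy(dtype=bool)
    cls = np.full(len(out), "unscored", dtype=object)
    cls[~np.isnan(score) & (score < threshold)] = "low_scoring"
    cls[~np.isnan(score) & (score >= threshold)] = "putatively_functional"
    cls[functional] = "functional"
    out["functional_class"] = cls
    return out


def class_enrichment(
    subset_genes,
    background_genes,
    class_membership: dict[str, set],
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher exact enrichment of protein classes in a gene subset.

    ``class_membership`` maps class label to the set of member genes.
    Genes belonging to more than one class are excluded from the
    analysis.  The 2x2 table per class is
    ``[[subset & class, subset - class], [rest & class, rest - class]]``
    where "rest" is the background outside the subset; the test is
    one-sided for enrichment by default.
    """
    subset = set(subset_genes)
    background = set(background_genes)
    if not subset:
        raise ValueError("empty gene subset")
    if not subset <= background:
        raise ValueError("subset must be contained in the background")

    multi = {
        g
        for g in background
        if sum(g in members for members in class_membership.values()) > 1
    }
    if multi:
        logger.info("%d multi-class genes excluded from enrichment", len(multi))
    subset -= multi
    background -= multi
    rest = background - subset

    rows = []
    for label, members in class_membership.items():
        a = len(subset & members)
        b = len(subset - members)
        c = len(rest & members)
        d = len(rest - members)
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append(
            {
                "protein_class": label,
                "subset_in_class": a,
                "subset_not_in_class": b,
                "rest_in_class": c,
                "rest_not_in_class": d,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def score_distribution_test(functional_scores, other_scores) -> dict:
    """Compare kinase-association scores of functional vs. other sites."""
    a = np.asarray(list(functional_scores), dtype=float)
    b = np.asarray(list(other_scores), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two scores")
    t, p = stats.ttest_ind(a, b)
    return {
        "mean_functional": float(a.mean()),
        "mean_other": float(b.mean()),
        "t_statistic": float(t),
        "p_value": float(p),
    }


def abundance_bias_test(novel_areas, known_areas) -> dict:
    """Compare precursor areas of proteins with novel vs. known sites.

    Precursor areas span orders of magnitude, so the two-sided t-test
    runs on log10 areas; medians are reported on the raw scale.
    """
    novel = np.asarray(list(novel_areas), dtype=float)
    known = np.asarray(list(known_areas), dtype=float)
    if len(novel) < 2 or len(known) < 2:
        raise ValueError("both groups need at least two areas")
    if (novel <= 0).any() or (known <= 0).any():
        raise ValueError("precursor areas must be positive")
    t, p = stats.ttest_ind(np.log10(novel), np.log10(known))
    return {
        "median_novel": float(np.median(novel)),
        "median_known": float(np.median(known)),
        "t_statistic": float(t),
        "p_value": float(p),
    }


def abundance_bias_by_residue(
    annotated_sites: pd.DataFrame, area_column: str = "precursor_area_top3"
) -> pd.DataFrame:
    """Per-residue novel-vs-known abundance comparison."""
    rows = []
    for residue, group in annotated_sites.groupby("residue"):
        novel = group.loc[~group["is_known"], area_column].dropna()
        known = group.loc[group["is_known"], area_column].dropna()
        if len(novel) < 2 or len(known) < 2:
            continue
        res = abundance_bias_test(novel, known)
        res["residue"] = residue
        rows.append(res)
    return pd.DataFrame(rows)


def summarize_counts(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-residue site counts, percentages and novelty breakdown.

    Percentages are ``100 * count / total`` rounded to one decimal.
    When the input carries an ``is_known`` column the novelty
    percentage per residue (novel / residue count) is included.
    """
    total = len(sites)
    rows = []
    for residue in ("S", "T", "Y"):
        sub = sites[sites["residue"] == residue]
        row = {
            "residue": residue,
            "n_sites": len(sub),
            "pct_of_total": round(100.0 * len(sub) / total, 1) if total else np.nan,
        }
        if "is_known" in sites.columns:
            n_novel = int((~sub["is_known"]).sum())
            row["n_novel"] = n_novel
            row["pct_novel"] = (
                round(100.0 * n_novel / len(sub), 1) if len(sub) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
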