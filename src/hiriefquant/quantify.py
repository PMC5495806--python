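"""PSM filtering, TMT reporter-ratio computation and rollups.

The quantification chain mirrors a 10-plex isobaric phosphoproteomics
experiment with two arms:

* the *phospho arm* (TiO2-enriched peptides) yields phospho-site level
  quantifications, and
* the *standard arm* (unenriched peptides) yields gene-level protein
  quantifications used to normalize the phospho-sites for changes in
  total protein abundance.

Per PSM, the intensity of each channel is divided by the arithmetic
mean of the untreated (control) channels, so control ratios average to
one by construction.  Site and protein ratios are medians over the
supporting PSM ratios; protein log2 ratios are median-centered per
channel (equal-loading assumption) and then subtracted from the site
log2 ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: 10-plex TMT channel labels in mass order.
TMT10_CHANNELS = (
    "126",
    "127N",
    "127C",
    "128N",
    "128C",
    "129N",
    "129C",
    "130N",
    "130C",
    "131",
)

CONDITIONS = ("untreated", "pervanadate", "mitotic")


def intensity_columns(channels=TMT10_CHANNELS) -> list[str]:
    return [f"tmt_{ch}" for ch in channels]


def ratio_columns(channels=TMT10_CHANNELS) -> list[str]:
    return [f"ratio_{ch}" for ch in channels]


def normalized_columns(channels=TMT10_CHANNELS) -> list[str]:
    return [f"normalized_log2_{ch}" for ch in channels]


@dataclass(frozen=True)
class StudyDesign:
    """Assignment of the ten TMT channels to experimental conditions."""

    channels: tuple[str, ...] = TMT10_CHANNELS
    conditions: tuple[str, ...] = (
        "untreated",
        "untreated",
        "untreated",
        "untreated",
        "pervanadate",
        "pervanadate",
        "pervanadate",
        "mitotic",
        "mitotic",
        "mitotic",
    )

    def __post_init__(self) -> None:
        if len(self.channels) != 10 or len(self.conditions) != 10:
            raise ValueError("a TMT 10-plex design needs exactly 10 channels")
        if "untreated" not in self.conditions:
            raise ValueError("design needs at least one untreated channel")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    @property
    def control_channels(self) -> list[str]:
        return [
            ch for ch, c in zip(self.channels, self.conditions) if c == "untreated"
        ]

    def channels_for(self, condition: str) -> list[str]:
        return [ch for ch, c in zip(self.channels, self.conditions) if c == condition]

    @property
    def treated_conditions(self) -> list[str]:
        seen = []
        for c in self.conditions:
            if c != "untreated" and c not in seen:
                seen.append(c)
        return seen


#: The study layout: four untreated replicates, three pervanadate, three mitotic.
DEFAULT_DESIGN = StudyDesign()


class ImpurityMatrix:
    """Reagent isotopic-impurity matrix for a TMT 10-plex set.

    Entry ``(i, j)`` is the proportion of reagent ``j``'s signal that
    appears in channel ``i``.  Columns must be non-negative, the
    diagonal dominant, and column sums at most ``1 + tol`` (signal may
    be lost to channels outside the plex, never created).
    """

    def __init__(self, matrix: np.ndarray, channels=TMT10_CHANNELS, tol: float = 1e-6):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (len(channels), len(channels)):
            raise ValueError(f"impurity matrix must be {len(channels)}x{len(channels)}")
        if (m < 0).any():
            raise ValueError("impurity matrix entries must be non-negative")
        if (m.sum(axis=0) > 1.0 + tol).any():
            raise ValueError("impurity matrix column sums exceed 1")
        offdiag = m.sum(axis=0) - np.diag(m)
        if (np.diag(m) <= offdiag).any():
            raise ValueError("impurity matrix must be diagonally dominant")
        self.matrix = m
        self.channels = tuple(channels)

    @classmethod
    def identity(cls, channels=TMT10_CHANNELS) -> "ImpurityMatrix":
        return cls(np.eye(len(channels)), channels)

    @classmethod
    def two_isotope(
        cls, minus2: float = 0.01, plus2: float = 0.03, channels=TMT10_CHANNELS
    ) -> "ImpurityMatrix":
        """Synthetic vendor-style matrix with -1/+1 Da isotope spill.

        In the 10-plex mass ordering, the +1 Da isotope of an N-form
        reagent lands two positions up (e.g. reagent 129N spills into
        channel 130N), hence spill at offsets of two list positions.
        """
        n = len(channels)
        m = np.zeros((n, n))
        for j in range(n):
            if j - 2 >= 0:
                m[j - 2, j] = minus2
            if j + 2 < n:
                m[j + 2, j] = plus2
            m[j, j] = 1.0 - m[:, j].sum()
        return cls(m, channels)

    def mix(self, intensities: np.ndarray) -> np.ndarray:
        """Forward-mix true intensities into observed ones."""
        return self.matrix @ np.asarray(intensities, dtype=float)


def correct_impurities(intensities, m: ImpurityMatrix) -> np.ndarray:
    """Invert reagent isotopic-impurity mixing for one reporter vector.

    Solves ``m @ x = observed`` and clamps negative components to zero.
    """
    obs = np.asarray(intensities, dtype=float)
    try:
        x = np.linalg.solve(m.matrix, obs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("impurity matrix is singular") from exc
    return np.clip(x, 0.0, None)


def correct_impurities_table(psms: pd.DataFrame, m: ImpurityMatrix) -> pd.DataFrame:
    """Apply impurity correction to every PSM's reporter intensities."""
    cols = intensity_columns(m.channels)
    out = psms.copy()
    inv = np.linalg.inv(m.matrix)
    corrected = np.clip(out[cols].to_numpy(dtype=float) @ inv.T, 0.0, None)
    out[cols] = corrected
    return out


# ---------------------------------------------------------------------------
# PSM-level operations
# ---------------------------------------------------------------------------

def filter_psms(
    psms: pd.DataFrame,
    min_localization: float = 95.0,
    channels=TMT10_CHANNELS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep PSMs with a complete reporter set and confident localization.

    A PSM is kept when all ten reporter intensities are strictly
    positive and, for phospho-PSMs only, the localization score is at
    least ``min_localization``.  Returns ``(kept, rejected)`` where the
    rejected table carries a ``reject_reason`` column.
    """
    cols = intensity_columns(channels)
    intens = psms[cols].to_numpy(dtype=float)
    complete = (intens > 0).all(axis=1) & np.isfinite(intens).all(axis=1)
    is_phospho = psms["n_phospho"].to_numpy() > 0
    loc = psms["localization_score"].to_numpy(dtype=float)
    localized = ~is_phospho | (loc >= min_localization)

    reason = np.where(
        ~complete,
        "incomplete reporter set",
        np.where(~localized, "low localization score", ""),
    )
    kept = psms[complete & localized].reset_index(drop=True)
    rejected = psms[~(complete & localized)].copy()
    rejected["reject_reason"] = reason[~(complete & localized)]
    logger.info(
        "filter_psms: %d kept, %d rejected of %d", len(kept), len(rejected), len(psms)
    )
    return kept, rejected.reset_index(drop=True)


def psm_ratios(psms: pd.DataFrame, design: StudyDesign = DEFAULT_DESIGN) -> pd.DataFrame:
    """Per-PSM channel ratios relative to the mean of the control channels."""
    out = psms.copy()
    ctrl_cols = intensity_columns(design.control_channels)
    ctrl_mean = out[ctrl_cols].mean(axis=1).to_numpy()
    if (ctrl_mean <= 0).any():
        raise ValueError("zero control-channel mean; filter PSMs first")
    for ch in design.channels:
        out[f"ratio_{ch}"] = out[f"tmt_{ch}"].to_numpy() / ctrl_mean
    return out


# ---------------------------------------------------------------------------
# Rollups
# ---------------------------------------------------------------------------

def _explode_sites(psms: pd.DataFrame) -> pd.DataFrame:
    """One row per (PSM, phospho-site), with protein coordinates."""
    rows = psms[psms["n_phospho"] > 0].copy()
    records = []
    for idx, row in rows.iterrows():
        positions = [int(p) for p in str(row["mod_positions"]).split(";") if p]
        for pep_pos in positions:
            prot_pos = int(row["peptide_start"]) + pep_pos - 1
            records.append(
                {
                    "psm_index": idx,
                    "gene": row["gene"],
                    "protein_id": row["protein_id"],
                    "position": prot_pos,
                    "residue": row["peptide"][pep_pos - 1],
                }
            )
    if not records:
        return pd.DataFrame(
            columns=["psm_index", "gene", "protein_id", "position", "residue"]
        )
    return pd.DataFrame.from_records(records)


def rollup_sites(
    psms: pd.DataFrame,
    design: StudyDesign = DEFAULT_DESIGN,
    subset: str = "all",
    protein_sequences: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Roll PSM ratios up to unique phospho-sites.

    Per site and channel, the ratio is the median over all supporting
    PSM ratios.  ``subset`` restricts support to PSMs from singly
    (``"singly"``) or multiply (``"multiply"``) phosphorylated
    peptides; ``"all"`` uses every supporting PSM.  Sites are keyed by
    ``(gene, protein_id, position, residue)`` with 1-based protein
    positions, so the same site reached through different peptides
    (missed cleavage) yields a single row.
    """
    if subset not in ("all", "singly", "multiply"):
        raise ValueError("subset must be one of 'all', 'singly', 'multiply'")
    pool = psms[psms["n_phospho"] > 0]
    if subset == "singly":
        pool = pool[pool["n_phospho"] == 1]
    elif subset == "multiply":
        pool = pool[pool["n_phospho"] > 1]
    sites = _explode_sites(pool)
    if sites.empty:
        return pd.DataFrame(
            columns=["gene", "protein_id", "position", "residue", "n_supporting_psms"]
        )
    rcols = ratio_columns(design.channels)
    merged = sites.merge(
        pool[rcols], left_on="psm_index", right_index=True, how="left"
    )
    grouped = merged.groupby(
        ["gene", "protein_id", "position", "residue"], sort=True
    )
    out = grouped[rcols].median()
    out["n_supporting_psms"] = grouped.size()
    out = out.reset_index()
    out["from_multiply_phosphorylated"] = subset == "multiply"
    if protein_sequences is not None:
        out["sequence_window"] = [
            sequence_window(protein_sequences[pid], pos)
            for pid, pos in zip(out["protein_id"], out["position"])
        ]
    return out


def rollup_proteins(
    psms: pd.DataFrame, design: StudyDesign = DEFAULT_DESIGN
) -> pd.DataFrame:
    """Gene-level protein quantification from non-phospho PSM ratios.

    Protein ratios are medians over all PSM ratios for a unique gene;
    log2 ratios are then centered by subtracting the per-channel median
    across genes (equal total protein loading assumed).  Also reports
    the mean of the top three peptide precursor areas per gene.
    """
    rcols = ratio_columns(design.channels)
    grouped = psms.groupby("gene", sort=True)
    med = grouped[rcols].median()
    log2 = np.log2(med.to_numpy())
    log2 = log2 - np.median(log2, axis=0, keepdims=True)
    out = pd.DataFrame(
        log2,
        index=med.index,
        columns=normalized_columns(design.channels),
    ).reset_index()

    # top-3 precursor areas over unique peptides, not PSMs
    pep_area = psms.groupby(["gene", "peptide"])["precursor_area"].max().reset_index()
    top3 = pep_area.groupby("gene")["precursor_area"].agg(top3_area)
    n_pep = pep_area.groupby("gene")["peptide"].nunique()
    out["precursor_area_top3"] = out["gene"].map(top3).to_numpy()
    out["n_peptides"] = out["gene"].map(n_pep).to_numpy()
    return out


def normalize_sites_to_protein(
    sites: pd.DataFrame,
    proteins: pd.DataFrame,
    design: StudyDesign = DEFAULT_DESIGN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize phospho-site ratios for total protein abundance changes.

    ``normalized_log2 = log2(site ratio) - protein normalized log2``
    per channel.  Sites whose gene is absent from the protein table are
    dropped; returns ``(normalized sites, dropped sites)``.
    """
    ncols = normalized_columns(design.channels)
    rcols = ratio_columns(design.channels)
    known = sites["gene"].isin(set(proteins["gene"]))
    dropped = sites[~known].reset_index(drop=True)
    if len(dropped):
        logger.info(
            "normalize_sites_to_protein: %d sites on genes without protein "
            "quantification dropped",
            len(dropped),
        )
    kept = sites[known].reset_index(drop=True)
    prot = proteins.set_index("gene")[ncols]
    prot_log2 = prot.loc[kept["gene"]].to_numpy()
    site_log2 = np.log2(kept[rcols].to_numpy(dtype=float))
    out = kept.copy()
    out[ncols] = site_log2 - prot_log2
    return out, dropped


def top3_area(areas) -> float:
    """Mean of the up-to-three largest peptide precursor areas."""
    arr = np.sort(np.asarray(list(areas), dtype=float))[::-1]
    if arr.size == 0:
        raise ValueError("top3_area needs at least one peptide area")
    return float(arr[:3].mean())


def assign_peptide_fraction(psms: pd.DataFrame) -> pd.Series:
    """Assign each peptide to the fraction with its largest precursor area.

    Ties are broken toward the lower (more acidic) fraction index.
    Returns a Series indexed by peptide sequence.
    """
    df = psms[["peptide", "fraction", "precursor_area"]].copy()
    df = df.sort_values(
        ["peptide", "precursor_area", "fraction"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return df.groupby("peptide", sort=True)["fraction"].first()


# ---------------------------------------------------------------------------
# Picked protein FDR
# ---------------------------------------------------------------------------

DECOY_PREFIX = "decoy_"


def picked_protein_fdr(
    scores, decoy_prefix: str = DECOY_PREFIX
) -> pd.DataFrame:
    """Protein-level q-values by target/decoy competition ("picked" FDR).

    Parameters
    ----------
    scores
        Iterable of ``(protein_id, best_score, is_decoy)``; a decoy's
        identifier is its target's identifier with ``decoy_prefix``
        prepended, and every decoy must have a target partner.

    For each target/decoy pair only the higher-scoring member is kept
    (the decoy wins ties, the conservative choice).  Kept entries are
    ranked by score; at each score threshold ``s``,
    ``FDR(s) = #decoys kept with score >= s / #targets kept with score >= s``
    and q-values are the running minimum of FDR from the bottom of the
    ranking.
    """
    df = pd.DataFrame(list(scores), columns=["protein_id", "score", "is_decoy"])
    df["pair_id"] = [
        pid[len(decoy_prefix):] if dec else pid
        for pid, dec in zip(df["protein_id"], df["is_decoy"])
    ]
    targets = set(df.loc[~df["is_decoy"], "pair_id"])
    unpaired = set(df.loc[df["is_decoy"], "pair_id"]) - targets
    if unpaired:
        raise ValueError(f"decoys without a target partner: {sorted(unpaired)}")

    picked = []
    for _, pair in df.groupby("pair_id", sort=True):
        best = pair.sort_values(
            ["score", "is_decoy"], ascending=[False, False], kind="mergesort"
        ).iloc[0]
        picked.append(best)
    kept = pd.DataFrame(picked).sort_values(
        ["score", "is_decoy"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)

    n_decoy = kept["is_decoy"].cumsum().to_numpy(dtype=float)
    n_target = (~kept["is_decoy"]).cumsum().to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_target > 0, n_decoy / n_target, np.inf)
    # entries tied on score share the worst FDR of the tie group
    for _, idx in kept.groupby("score").groups.items():
        fdr[np.asarray(idx)] = fdr[np.asarray(idx)].max()
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    kept["q_value"] = q
    return kept[["protein_id", "score", "is_decoy", "q_value"]]


# ---------------------------------------------------------------------------
# Sequence windows
# ---------------------------------------------------------------------------

def sequence_window(protein_sequence: str, position: int, pad: str = "_") -> str:
    """15-residue window centered on a 1-based protein position.

    Positions within seven residues of a terminus are padded with
    ``pad`` so the window is always 15 characters with the modified
    residue at the center.
    """
    n = len(protein_sequence)
    if not 1 <= position <= n:
        raise ValueError(f"position {position} outside protein of length {n}")
    i = position - 1
    left = protein_sequence[max(0, i - 7): i]
    right = protein_sequence[i + 1: i + 8]
    return (
        pad * (7 - len(left)) + left + protein_sequence[i] + right + pad * (7 - len(right))
    )
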