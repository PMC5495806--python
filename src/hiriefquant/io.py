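"""Tab-delimited table and FASTA readers/writers plus pipeline config.

All tables are UTF-8 tab-delimited text with a header row.  The PSM
reader validates rows (complete, numeric reporter intensities and
coordinates) and rejects malformed ones with their line numbers, which
tolerates hand-edited or truncated exports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .quantify import TMT10_CHANNELS, ImpurityMatrix, StudyDesign, intensity_columns

logger = logging.getLogger(__name__)

REQUIRED_PSM_COLUMNS = [
    "peptide",
    "protein_id",
    "gene",
    "peptide_start",
    "mod_positions",
    "n_phospho",
    "localization_score",
    "precursor_area",
    "fraction",
    *intensity_columns(),
]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_psm_table(path, channels=TMT10_CHANNELS) -> pd.DataFrame:
    """Read and validate a PSM table.

    Extra columns are preserved; a missing required column aborts with
    an error naming it.  Rows with non-numeric or missing reporter
    intensities, coordinates or precursor areas are dropped and logged
    with their 1-based file line numbers.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} lacks required columns: {missing}")

    numeric = [
        "peptide_start",
        "n_phospho",
        "precursor_area",
        "fraction",
        *intensity_columns(channels),
    ]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    # localization is only meaningful (and required) for phospho PSMs
    loc = pd.to_numeric(df["localization_score"], errors="coerce")
    bad |= (coerced["n_phospho"] > 0) & loc.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        logger.warning(
            "%s: rejected %d malformed rows (file lines %s%s)",
            path,
            int(bad.sum()),
            lines[:20],
            "..." if len(lines) > 20 else "",
        )
    out = df[~bad].copy()
    out[numeric] = coerced[~bad]
    out["localization_score"] = loc[~bad]
    out["mod_positions"] = out["mod_positions"].fillna("").astype(str)
    out["mod_positions"] = out["mod_positions"].str.replace(
        r"\.0$", "", regex=True
    )
    logger.info("%s: %d PSMs read, %d rejected", path, len(out), int(bad.sum()))
    return out.reset_index(drop=True)


def write_fasta(proteome, path) -> None:
    """Write ``(protein_id, sequence)`` pairs as FASTA."""
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteome
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into ``{protein_id: sequence}``."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_impurity_matrix(m: ImpurityMatrix, path) -> None:
    pd.DataFrame(m.matrix, index=m.channels, columns=m.channels).to_csv(
        path, sep="\t", index_label="channel"
    )


def read_impurity_matrix(path) -> ImpurityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ImpurityMatrix(df.to_numpy(dtype=float), tuple(df.columns))


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run.

    Paths may be None when the corresponding stage is skipped (e.g. no
    annotation reference) or when the run starts from simulation.
    """

    psm_phospho: str | None = None
    psm_standard: str | None = None
    fasta: str | None = None
    impurity_matrix: str | None = None
    reference_sites: str | None = None
    score_table: str | None = None
    design: StudyDesign = field(default_factory=StudyDesign)
    min_localization: float = 95.0
    q_threshold: float = 0.01
    log2fc_threshold: float = 1.0
    networkin_threshold: float = 3.0
    correct_impurities: bool = False
    clamp_unfocused: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_localization",
            "q_threshold",
            "log2fc_threshold",
            "networkin_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design_raw = raw.pop("design", None)
        config = cls(**raw)
        if design_raw is not None:
            config.design = StudyDesign(
                channels=tuple(design_raw["channels"]),
                conditions=tuple(design_raw["conditions"]),
            )
        return config

    def to_yaml(self, path) -> None:
        raw = {
            k: v
            for k, v in self.__dict__.items()
            if k != "design" and v is not None
        }
        raw["design"] = {
            "channels": list(self.design.channels),
            "conditions": list(self.design.conditions),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
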