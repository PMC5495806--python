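"""Synthetic proteome and PSM-table generator with known ground truth.

Emulates the computational inputs of a TMT 10-plex phosphoproteomics
experiment with two HiRIEF arms: a phospho arm (TiO2-enriched,
phospho-peptide PSMs) and a standard arm (unenriched, protein-level
PSMs).  The study design it mimics has four untreated replicates,
three pervanadate-treated replicates (a tyrosine-phosphatase inhibitor
that strongly raises phospho-tyrosine abundance, ~10-fold) and three
mitotic-arrest replicates (raising phospho-serine/threonine
abundance).

Every emitted phospho-site carries ground truth: its phospho-specific
log2 fold change per condition on top of the (separately recorded)
protein-level change, so downstream quantification can be scored for
exact and noisy parameter recovery.

Reporter intensities use a multiplicative lognormal noise model with a
configurable coefficient of variation, then pass through the reagent
isotopic-impurity matrix.  A configurable share of PSMs receives a
localization score below the high-confidence cutoff and a share gets
one zeroed reporter, so the downstream filters are exercised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser

from .isoelectric import (
    ULTRA_ACIDIC,
    WIDE_RANGE,
    isoelectric_point,
    map_to_fraction,
)
from .quantify import (
    DEFAULT_DESIGN,
    ImpurityMatrix,
    StudyDesign,
    intensity_columns,
)

logger = logging.getLogger(__name__)

#: Approximate human proteome amino-acid frequencies.
AA_FREQUENCIES = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.044, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}

TRYPSIN_RULE = r"[KR](?!P)"  # cleave after K/R except before proline

PSM_COLUMNS = [
    "arm",
    "peptide",
    "protein_id",
    "gene",
    "peptide_start",
    "mod_positions",
    "n_phospho",
    "localization_score",
    "precursor_area",
    "fraction",
    "strip",
    *intensity_columns(),
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    ``residue_mix`` gives the S/T/Y proportions among phospho-sites
    (default 0.79/0.15/0.06, the typical split observed in large-scale
    human phosphoproteomes).  ``effect_pervanadate`` defaults to
    ``log2(10)``: pervanadate raises phospho-tyrosine abundance about
    ten-fold.  ``leak_rate`` lets a small share of sites respond to
    the "wrong" condition (Y sites to mitosis, S/T to pervanadate).
    """

    n_proteins: int = 200
    mean_protein_length: int = 450
    phospho_site_rate: float = 0.05
    residue_mix: tuple[float, float, float] = (0.79, 0.15, 0.06)  # S, T, Y
    n_psms_per_peptide: float = 2.0
    noise_cv: float = 0.1
    missed_cleavage_max: int = 2
    impurity_matrix: ImpurityMatrix | None = None
    seed: int = 0
    # effect model
    regulated_fraction: float = 0.4
    effect_pervanadate: float = float(np.log2(10.0))
    effect_mitosis_range: tuple[float, float] = (1.2, 3.0)
    downregulated_share: float = 0.2
    leak_rate: float = 0.05
    protein_regulated_fraction: float = 0.1
    protein_effect_sd: float = 0.5
    # nuisance features exercising the filters
    frac_low_localization: float = 0.10
    frac_zero_reporter: float = 0.05
    min_peptide_length: int = 6
    max_peptide_length: int = 40

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not np.isclose(sum(self.residue_mix), 1.0):
            raise ValueError("residue_mix must sum to 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.missed_cleavage_max < 0:
            raise ValueError("missed_cleavage_max must be non-negative")
        if not 0 <= self.phospho_site_rate <= 1:
            raise ValueError("phospho_site_rate must be in [0, 1]")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def generate_proteome(config: SimConfig) -> list[tuple[str, str]]:
    """Random protein sequences with human-like residue frequencies.

    Returns ``(protein_id, sequence)`` pairs; identifiers are
    ``SYN0001``-style and deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(AA_FREQUENCIES))
    probs = np.array(list(AA_FREQUENCIES.values()))
    probs = probs / probs.sum()
    out = []
    for i in range(config.n_proteins):
        length = max(30, int(rng.gamma(shape=6.0, scale=config.mean_protein_length / 6.0)))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        out.append((f"SYN{i + 1:04d}", seq))
    return out


def tryptic_digest(
    sequence: str, missed_cleavage_max: int = 2
) -> list[tuple[str, int, int]]:
    """In-silico tryptic digest with the proline rule.

    Cleaves after K or R except when the next residue is P, allowing
    0..``missed_cleavage_max`` internal missed cleavages.  Returns
    ``(peptide, start, end)`` with 1-based inclusive coordinates,
    sorted by start then length.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seen = set()
    out = []
    for start0, pep in _pyt_parser.icleave(
        sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavage_max
    ):
        key = (start0, len(pep))
        if pep and key not in seen:
            seen.add(key)
            out.append((pep, start0 + 1, start0 + len(pep)))
    out.sort(key=lambda t: (t[1], t[2]))
    return out


# ---------------------------------------------------------------------------
# Ground-truth effect model
# ---------------------------------------------------------------------------

def _draw_site_truth(
    rng: np.random.Generator, residue: str, config: SimConfig
) -> tuple[float, float]:
    """(log2fc pervanadate, log2fc mitosis) for one phospho-site."""
    if rng.random() >= config.regulated_fraction:
        return 0.0, 0.0
    target = "pervanadate" if residue == "Y" else "mitosis"
    if rng.random() < config.leak_rate:
        target = "mitosis" if target == "pervanadate" else "pervanadate"
    if target == "pervanadate":
        return config.effect_pervanadate, 0.0
    lo, hi = config.effect_mitosis_range
    magnitude = rng.uniform(lo, hi)
    sign = -1.0 if rng.random() < config.downregulated_share else 1.0
    return 0.0, sign * magnitude


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


@dataclass
class SimResult:
    """Outputs of one synthetic experiment."""

    psms: pd.DataFrame
    ground_truth: pd.DataFrame
    protein_truth: pd.DataFrame
    proteome: list[tuple[str, str]]
    config: SimConfig = field(repr=False)

    @property
    def psms_phospho(self) -> pd.DataFrame:
        return self.psms[self.psms["arm"] == "phospho"].reset_index(drop=True)

    @property
    def psms_standard(self) -> pd.DataFrame:
        return self.psms[self.psms["arm"] == "standard"].reset_index(drop=True)


def simulate_experiment(
    config: SimConfig, design: StudyDesign = DEFAULT_DESIGN
) -> SimResult:
    """Generate PSM tables for both arms plus ground-truth tables.

    Reporter intensity for channel ``c`` of a phospho PSM is
    ``base * 2**(protein_log2fc(c) + form_log2fc(c))`` times lognormal
    noise, then mixed through the impurity matrix; a multiply
    phosphorylated form's fold change is the sum of its member sites'
    fold changes (co-dependent stoichiometry), which is what makes
    singly- versus multiply-phosphorylated rollups disagree for sites
    sharing a peptide with a regulated neighbor.
    """
    if len(design.channels) != 10:
        raise ValueError("design must have exactly 10 channels")
    rng = np.random.default_rng(config.seed)
    proteome = generate_proteome(config)
    impurity = config.impurity_matrix or ImpurityMatrix.identity()
    conditions = np.array(design.conditions)

    # per-residue phospho probabilities reproducing residue_mix overall
    counts = {"S": 0, "T": 0, "Y": 0}
    for _, seq in proteome:
        for aa in counts:
            counts[aa] += seq.count(aa)
    total_sty = sum(counts.values())
    mix = dict(zip("STY", config.residue_mix))
    p_residue = {
        aa: min(1.0, config.phospho_site_rate * total_sty * mix[aa] / max(1, counts[aa]))
        for aa in counts
    }

    truth_rows, protein_rows, psm_rows = [], [], []
    for pidx, (protein_id, seq) in enumerate(proteome):
        gene = f"GENE{pidx + 1:04d}"
        base_protein = rng.lognormal(mean=np.log(1e6), sigma=1.0)
        prot_fc_mit = 0.0
        if rng.random() < config.protein_regulated_fraction:
            prot_fc_mit = rng.normal(0.0, config.protein_effect_sd)
        prot_fc = {"untreated": 0.0, "pervanadate": 0.0, "mitotic": prot_fc_mit}
        protein_rows.append(
            {
                "protein_id": protein_id,
                "gene": gene,
                "base_abundance": base_protein,
                "true_protein_log2fc_pervanadate": 0.0,
                "true_protein_log2fc_mitosis": prot_fc_mit,
            }
        )

        site_truth: dict[int, tuple[float, float]] = {}
        for pos0, aa in enumerate(seq):
            if aa in "STY" and rng.random() < p_residue[aa]:
                site_truth[pos0 + 1] = _draw_site_truth(rng, aa, config)

        peptides = [
            p
            for p in tryptic_digest(seq, config.missed_cleavage_max)
            if config.min_peptide_length <= len(p[0]) <= config.max_peptide_length
        ]
        prot_factor = np.array([2.0 ** prot_fc[c] for c in conditions])

        emitted_sites = set()
        for pep, start, end in peptides:
            pep_sites = [p for p in site_truth if start <= p <= end]
            base_pep = base_protein * rng.lognormal(mean=0.0, sigma=0.5)

            # standard arm: unmodified peptide PSMs
            n_psm = 1 + rng.poisson(max(0.0, config.n_psms_per_peptide - 1))
            for _ in range(n_psm):
                psm_rows.append(
                    _emit_psm(
                        rng, config, impurity, design,
                        arm="standard", peptide=pep, protein_id=protein_id,
                        gene=gene, start=start, mod_positions=[],
                        channel_factor=prot_factor, base=base_pep,
                    )
                )

            if not pep_sites:
                continue
            # phospho arm: one singly phosphorylated form per site ...
            forms = [[p] for p in pep_sites]
            # ... plus one fully phosphorylated form when multiple sites
            if len(pep_sites) > 1:
                forms.append(sorted(pep_sites))
            for form in forms:
                fc_perv = sum(site_truth[p][0] for p in form)
                fc_mit = sum(site_truth[p][1] for p in form)
                form_fc = {"untreated": 0.0, "pervanadate": fc_perv, "mitotic": fc_mit}
                factor = prot_factor * np.array(
                    [2.0 ** form_fc[c] for c in conditions]
                )
                base_form = base_pep * 0.2 / len(form)  # enrichment losses
                n_psm = 1 + rng.poisson(max(0.0, config.n_psms_per_peptide - 1))
                for _ in range(n_psm):
                    psm_rows.append(
                        _emit_psm(
                            rng, config, impurity, design,
                            arm="phospho", peptide=pep, protein_id=protein_id,
                            gene=gene, start=start,
                            mod_positions=[p - start + 1 for p in form],
                            channel_factor=factor, base=base_form,
                        )
                    )
                emitted_sites.update(form)

        for pos in sorted(emitted_sites):
            fc_perv, fc_mit = site_truth[pos]
            truth_rows.append(
                {
                    "protein_id": protein_id,
                    "gene": gene,
                    "position": pos,
                    "residue": seq[pos - 1],
                    "base_abundance": base_protein,
                    "true_log2fc_pervanadate": fc_perv,
                    "true_log2fc_mitosis": fc_mit,
                    "is_regulated_pervanadate": abs(fc_perv) > 1.0,
                    "is_regulated_mitosis": abs(fc_mit) > 1.0,
                }
            )

    psms = pd.DataFrame(psm_rows, columns=PSM_COLUMNS)
    ground_truth = pd.DataFrame(
        truth_rows,
        columns=[
            "protein_id", "gene", "position", "residue", "base_abundance",
            "true_log2fc_pervanadate", "true_log2fc_mitosis",
            "is_regulated_pervanadate", "is_regulated_mitosis",
        ],
    )
    protein_truth = pd.DataFrame(protein_rows)
    logger.info(
        "simulated %d PSMs (%d phospho / %d standard), %d true sites",
        len(psms),
        (psms["arm"] == "phospho").sum(),
        (psms["arm"] == "standard").sum(),
        len(ground_truth),
    )
    return SimResult(psms, ground_truth, protein_truth, proteome, config)


@lru_cache(maxsize=200_000)
def _cached_pi(peptide: str, n_phospho: int) -> float | None:
    try:
        return isoelectric_point(peptide, n_phospho)
    except ValueError:
        return None  # no basic group left after labeling


def _emit_psm(
    rng, config, impurity, design, *,
    arm, peptide, protein_id, gene, start, mod_positions, channel_factor, base,
) -> dict:
    n_phospho = len(mod_positions)
    true_intens = base * channel_factor * _lognormal_noise(rng, config.noise_cv, 10)
    observed = impurity.mix(true_intens)
    if arm == "phospho" and rng.random() < config.frac_zero_reporter:
        observed = observed.copy()
        observed[rng.integers(0, 10)] = 0.0
    if n_phospho == 0:
        loc_score = np.nan
    elif rng.random() < config.frac_low_localization:
        loc_score = rng.uniform(50.0, 95.0 - 1e-9)
    else:
        loc_score = rng.uniform(95.0, 100.0)
    area = base * rng.lognormal(mean=0.0, sigma=0.3)

    pi = _cached_pi(peptide, n_phospho)
    if arm == "phospho" and pi is not None and map_to_fraction(pi, ULTRA_ACIDIC):
        strip = ULTRA_ACIDIC
    else:
        strip = WIDE_RANGE
    if pi is None:
        fraction = 1  # no basic group: runs to the acidic edge
    else:
        fraction = map_to_fraction(pi, strip)
        if fraction is None:
            fraction = 1 if pi < strip.ph_min else strip.n_fractions
    row = {
        "arm": arm,
        "peptide": peptide,
        "protein_id": protein_id,
        "gene": gene,
        "peptide_start": start,
        "mod_positions": ";".join(str(p) for p in mod_positions),
        "n_phospho": n_phospho,
        "localization_score": float(loc_score),
        "precursor_area": area,
        "fraction": fraction,
        "strip": strip.label,
    }
    for ch, value in zip(design.channels, observed):
        row[f"tmt_{ch}"] = value
    return row


def simulate_psm_table(
    config: SimConfig, design: StudyDesign = DEFAULT_DESIGN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper returning ``(PSM table, ground-truth table)``.

    The PSM table contains both arms, distinguished by the ``arm``
    column; ``simulate_experiment`` exposes the full result bundle.
    """
    sim = simulate_experiment(config, design)
    return sim.psms, sim.ground_truth
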