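"""Peptide isoelectric-point model and IPG-strip fraction mapping.

The model is a standard Henderson–Hasselbalch summation over ionizable
groups.  At a given pH, each basic group (free N-terminus, unlabeled
lysine, arginine, histidine) contributes a positive partial charge
``1 / (1 + 10**(pH - pKa))`` and each acidic group (C-terminus,
aspartate, glutamate, cysteine, tyrosine and each phosphate group)
contributes a negative partial charge ``-1 / (1 + 10**(pKa - pH))``.
A phosphate group carries two ionizations (pKa ~1.2 and ~6.5), which is
what drives phospho-peptides toward the acidic end of an immobilized
pH-gradient (IPG) strip.

TMT labeling chemistry targets primary amines: with ``tmt_labeled=True``
(the default, matching an isobaric-labeling experiment) the N-terminal
amine and lysine side chains lose their basic ionization.

The isoelectric point (pI) is the unique pH at which the net charge is
zero; because the net charge is continuous and strictly decreasing in
pH, bisection finds it reliably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_ACIDIC_SIDECHAINS = "DECY"
_BASIC_SIDECHAINS = "KRH"


@dataclass(frozen=True)
class PKaSet:
    """Ionization constants for peptide charge calculation.

    Side-chain defaults follow the EMBOSS pKa set; the two phosphate
    ionizations default to 1.2 and 6.5.  All values are overridable.
    """

    pka_nterm: float = 8.6
    pka_cterm: float = 3.6
    sidechain: dict[str, float] = field(
        default_factory=lambda: {
            "D": 3.9,
            "E": 4.1,
            "C": 8.5,
            "Y": 10.1,
            "H": 6.5,
            "K": 10.8,
            "R": 12.5,
        }
    )
    phospho_pka1: float = 1.2
    phospho_pka2: float = 6.5

    def __post_init__(self) -> None:
        for name, value in [
            ("pka_nterm", self.pka_nterm),
            ("pka_cterm", self.pka_cterm),
            ("phospho_pka1", self.phospho_pka1),
            ("phospho_pka2", self.phospho_pka2),
            *self.sidechain.items(),
        ]:
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa {name}={value} outside (0, 14)")
        if not self.phospho_pka1 < self.phospho_pka2:
            raise ValueError("phospho_pka1 must be below phospho_pka2")

    def with_overrides(self, **kwargs: float) -> "PKaSet":
        """Return a copy with the given fields replaced."""
        side = {k: v for k, v in kwargs.items() if k in self.sidechain}
        rest = {k: v for k, v in kwargs.items() if k not in self.sidechain}
        new = replace(self, **rest)
        if side:
            new = replace(new, sidechain={**self.sidechain, **side})
        return new


DEFAULT_PKAS = PKaSet()


@dataclass(frozen=True)
class IPGStrip:
    """Linear immobilized pH-gradient strip divided into equal fractions.

    Fraction numbering is 1-based and proceeds from the acidic end of
    the strip toward the basic end.
    """

    ph_min: float
    ph_max: float
    n_fractions: int = 72
    label: str = ""

    def __post_init__(self) -> None:
        if not self.ph_min < self.ph_max:
            raise ValueError("ph_min must be below ph_max")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def fraction_width(self) -> float:
        return (self.ph_max - self.ph_min) / self.n_fractions


#: pH 2.5-3.7 prototype strip used for multiply phosphorylated peptides.
ULTRA_ACIDIC = IPGStrip(2.5, 3.7, 72, "ultra-acidic")
#: pH 3-10 strip used for both the standard and the phospho arm.
WIDE_RANGE = IPGStrip(3.0, 10.0, 72, "wide-range")

STRIP_PRESETS = {"ultra-acidic": ULTRA_ACIDIC, "wide-range": WIDE_RANGE}


def _positive(ph: float, pka: float) -> float:
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def _negative(ph: float, pka: float) -> float:
    return -1.0 / (1.0 + 10.0 ** (pka - ph))


def _charge_from_counts(
    counts: dict[str, int],
    n_phospho: int,
    ph: float,
    pkas: PKaSet,
    tmt_labeled: bool,
) -> float:
    charge = _negative(ph, pkas.pka_cterm)
    if not tmt_labeled:
        charge += _positive(ph, pkas.pka_nterm)
        charge += counts.get("K", 0) * _positive(ph, pkas.sidechain["K"])
    for aa in _ACIDIC_SIDECHAINS:
        if counts.get(aa):
            charge += counts[aa] * _negative(ph, pkas.sidechain[aa])
    for aa in "RH":
        if counts.get(aa):
            charge += counts[aa] * _positive(ph, pkas.sidechain[aa])
    if n_phospho:
        charge += n_phospho * (
            _negative(ph, pkas.phospho_pka1) + _negative(ph, pkas.phospho_pka2)
        )
    return charge


def _ionizable_counts(peptide: str) -> dict[str, int]:
    unknown = set(peptide) - set(AMINO_ACIDS)
    if unknown:
        raise ValueError(f"unknown residues in peptide: {sorted(unknown)}")
    return {aa: peptide.count(aa) for aa in "DECYKRH"}


def net_charge(
    peptide: str,
    n_phospho: int,
    ph: float,
    pkas: PKaSet = DEFAULT_PKAS,
    tmt_labeled: bool = True,
) -> float:
    """Net charge of a peptide at a given pH.

    Parameters
    ----------
    peptide
        Amino-acid sequence (canonical one-letter codes).
    n_phospho
        Number of phosphate groups; each adds two acidic ionizations.
    ph
        The pH at which to evaluate the charge.
    pkas
        The ionization-constant set.
    tmt_labeled
        When True, the N-terminal amine and lysine side chains are
        amine-labeled and lose their basic ionization.
    """
    if n_phospho < 0:
        raise ValueError("n_phospho must be non-negative")
    return _charge_from_counts(
        _ionizable_counts(peptide), n_phospho, ph, pkas, tmt_labeled
    )


def isoelectric_point(
    peptide: str,
    n_phospho: int = 0,
    pkas: PKaSet = DEFAULT_PKAS,
    tmt_labeled: bool = True,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> float:
    """pH at which the peptide's net charge is zero, by bisection.

    Raises
    ------
    ValueError
        If the peptide carries no basic (or no acidic) ionizable group
        in the requested labeling state, so that the net charge never
        crosses zero inside (0, 14).
    """
    counts = _ionizable_counts(peptide)
    lo, hi = 0.0, 14.0
    c_lo = _charge_from_counts(counts, n_phospho, lo, pkas, tmt_labeled)
    c_hi = _charge_from_counts(counts, n_phospho, hi, pkas, tmt_labeled)
    if c_lo <= 0.0 or c_hi >= 0.0:
        raise ValueError(
            "peptide needs at least one acidic and one basic ionizable "
            "group for a defined isoelectric point"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if _charge_from_counts(counts, n_phospho, mid, pkas, tmt_labeled) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            return 0.5 * (lo + hi)
    raise RuntimeError("pI bisection did not converge")


def map_to_fraction(pi: float, strip: IPGStrip) -> int | None:
    """Map a pI to a 1-based strip fraction, or None if not focused.

    Fraction ``i`` covers the half-open interval
    ``[ph_min + (i-1)*w, ph_min + i*w)``; the last fraction is closed
    at ``ph_max``.  A pI outside ``[ph_min, ph_max]`` does not focus.
    """
    if pi < strip.ph_min or pi > strip.ph_max:
        return None
    if pi == strip.ph_max:
        return strip.n_fractions
    w = strip.fraction_width
    i = int((pi - strip.ph_min) / w) + 1
    # enforce the half-open edge definition despite float rounding
    if pi < strip.ph_min + (i - 1) * w:
        i -= 1
    elif pi >= strip.ph_min + i * w:
        i += 1
    return min(max(i, 1), strip.n_fractions)


def composition_class_labels(
    peptides: list[str], n_bins: int = 4
) -> pd.Series:
    """Bin peptides into acidity/basicity classes.

    The score is ``n_acidic - n_basic`` (counts of D+E versus K+H+R);
    peptides are split into ``n_bins`` groups at the quantiles of the
    score over the input set, labeled from most basic (class 1) to most
    acidic (class ``n_bins``).
    """
    score = pd.Series(
        [sum(aa in "DE" for aa in p) - sum(aa in "KHR" for aa in p) for p in peptides],
        index=range(len(peptides)),
    )
    # duplicate quantile edges collapse on homogeneous sets
    binned = pd.qcut(score.rank(method="first"), q=n_bins, labels=False) + 1
    return binned.astype(int)


def fraction_shift_analysis(
    peptides: list[tuple[str, int]],
    strip: IPGStrip = WIDE_RANGE,
    pkas: PKaSet = DEFAULT_PKAS,
    tmt_labeled: bool = True,
    clamp: bool = False,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Fraction shift induced by phosphorylation, by composition class.

    Parameters
    ----------
    peptides
        ``(sequence, n_phospho)`` pairs.  Each phosphorylated entry
        must have its unmodified counterpart (same sequence,
        ``n_phospho == 0``) in the list; entries without one are
        skipped and logged.
    clamp
        When True, peptides whose pI falls outside the strip are
        clamped to the edge fractions instead of being excluded.

    Returns
    -------
    DataFrame with columns ``composition_class``, ``n_acidic``,
    ``n_basic`` (class means), ``n_phospho``, ``n`` and
    ``mean_shift`` (fraction(phospho) - fraction(unmodified); negative
    values point toward the acidic end).
    """
    unmodified = {seq for seq, n in peptides if n == 0}

    def fraction_of(seq: str, n_phospho: int) -> int | None:
        try:
            pi = isoelectric_point(seq, n_phospho, pkas, tmt_labeled)
        except ValueError:
            return None
        frac = map_to_fraction(pi, strip)
        if frac is None and clamp:
            frac = 1 if pi < strip.ph_min else strip.n_fractions
        return frac

    rows = []
    for seq, n_phospho in peptides:
        if n_phospho == 0:
            continue
        if seq not in unmodified:
            logger.warning("no unmodified counterpart for %s; skipped", seq)
            continue
        f_mod = fraction_of(seq, n_phospho)
        f_ref = fraction_of(seq, 0)
        if f_mod is None or f_ref is None:
            continue
        rows.append(
            {
                "sequence": seq,
                "n_phospho": n_phospho,
                "n_acidic": sum(aa in "DE" for aa in seq),
                "n_basic": sum(aa in "KHR" for aa in seq),
                "shift": f_mod - f_ref,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "composition_class",
                "n_acidic",
                "n_basic",
                "n_phospho",
                "n",
                "mean_shift",
            ]
        )
    df = pd.DataFrame(rows)
    unique_seqs = sorted(df["sequence"].unique())
    labels = composition_class_labels(unique_seqs, n_bins=n_bins)
    class_of = dict(zip(unique_seqs, labels))
    df["composition_class"] = df["sequence"].map(class_of)
    out = (
        df.groupby(["composition_class", "n_phospho"])
        .agg(
            n_acidic=("n_acidic", "mean"),
            n_basic=("n_basic", "mean"),
            n=("shift", "size"),
            mean_shift=("shift", "mean"),
        )
        .reset_index()
    )
    return out[
        ["composition_class", "n_acidic", "n_basic", "n_phospho", "n", "mean_shift"]
    ]
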