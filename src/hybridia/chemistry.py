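"""Peptide mass arithmetic: monoisotopic m/z, heavy-label shifts, fragment
series, and averagine isotope envelopes.

Monoisotopic residue masses follow the standard table; cysteine carries a
fixed carbamidomethyl modification (the iST-style sample preparation the
simulator emulates alkylates every cysteine). Stable-isotope labels are the
SILAC-style C-terminal channels: Lys8 (6x 13C + 2x 15N, +8.014199 Da) and
Arg10 (6x 13C + 4x 15N, +10.008269 Da).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

PROTON = 1.00727646677
WATER = 18.0105646863

# 13C - 12C and 15N - 14N monoisotopic mass differences
_D13C = 13.00335483507 - 12.0
_D15N = 15.00010889888 - 14.00307400443

LYS8_SHIFT = 6 * _D13C + 2 * _D15N   # 8.014199 Da
ARG10_SHIFT = 6 * _D13C + 4 * _D15N  # 10.008269 Da

# Average spacing of isotopologue peaks, Da
NEUTRON_SPACING = 1.00335

CARBAMIDOMETHYL = 57.02146372057

# Standard monoisotopic residue masses; C includes fixed carbamidomethyl.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146372057,
    "A": 71.03711378471,
    "S": 87.03202840427,
    "P": 97.05276384885,
    "V": 99.06841391299,
    "T": 101.04767846841,
    "C": 103.00918478471 + CARBAMIDOMETHYL,
    "L": 113.08406397713,
    "I": 113.08406397713,
    "N": 114.04292744114,
    "D": 115.02694302383,
    "Q": 128.05857750528,
    "K": 128.09496301399,
    "E": 129.04259308797,
    "M": 131.04048491299,
    "H": 137.05891185845,
    "F": 147.06841391299,
    "R": 156.10111102359,
    "Y": 163.06332853255,
    "W": 186.07931294985,
}


class Label(str, Enum):
    """Isotope-label channel of a peptide species."""

    LIGHT = "light"
    HEAVY_K8 = "heavy_K8"
    HEAVY_R10 = "heavy_R10"

    @property
    def mass_shift(self) -> float:
        if self is Label.HEAVY_K8:
            return LYS8_SHIFT
        if self is Label.HEAVY_R10:
            return ARG10_SHIFT
        return 0.0


def heavy_label_for(sequence: str) -> Label:
    """Heavy channel implied by the tryptic C-terminal residue."""
    if sequence.endswith("K"):
        return Label.HEAVY_K8
    if sequence.endswith("R"):
        return Label.HEAVY_R10
    raise ValueError(
        f"sequence {sequence!r} does not end in K or R; only tryptic peptides "
        "can carry a C-terminal Lys8/Arg10 label"
    )


def _residue_sum(sequence: str) -> float:
    try:
        return sum(RESIDUE_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from None


def peptide_neutral_mass(sequence: str, label: Label = Label.LIGHT) -> float:
    """Monoisotopic neutral mass of the peptide, including the label shift."""
    return _residue_sum(sequence) + WATER + label.mass_shift


def precursor_mz(sequence: str, charge: int, label: Label = Label.LIGHT) -> float:
    """Monoisotopic precursor m/z of [M + charge*H]^charge."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (peptide_neutral_mass(sequence, label) + charge * PROTON) / charge


def fragment_mz(
    sequence: str,
    series: str,
    ordinal: int,
    charge: int = 1,
    label: Label = Label.LIGHT,
) -> float:
    """Monoisotopic m/z of a b- or y-series fragment ion.

    The heavy label sits on the C-terminal residue, so it shifts every y ion
    by the full label mass and no b ion at all.
    """
    if series not in ("b", "y"):
        raise ValueError(f"fragment series must be 'b' or 'y', got {series!r}")
    if not 1 <= ordinal < len(sequence):
        raise ValueError(
            f"ordinal {ordinal} out of range for {len(sequence)}-residue peptide"
        )
    if charge < 1:
        raise ValueError("fragment charge must be >= 1")
    if series == "b":
        neutral = _residue_sum(sequence[:ordinal])
    else:
        neutral = _residue_sum(sequence[-ordinal:]) + WATER + label.mass_shift
    return (neutral + charge * PROTON) / charge


# ---------------------------------------------------------------------------
# Averagine isotope envelopes
# ---------------------------------------------------------------------------

# Averagine monomer: C4.9384 H7.7583 N1.3577 O1.4773 S0.0417, 111.1254 Da
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254

# Isotopic abundance vectors indexed by neutron number offset.
_ELEMENT_ISOTOPES = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "S": np.array([0.9499, 0.0075, 0.0425, 0.0]),
}


def averagine_composition(neutral_mass: float) -> dict[str, int]:
    """Integer elemental composition of the averagine model peptide closest
    in mass to ``neutral_mass`` (hydrogen takes up the rounding remainder)."""
    n_units = neutral_mass / _AVERAGINE_MASS
    comp = {el: int(round(n * n_units)) for el, n in _AVERAGINE.items() if el != "H"}
    mass_so_far = sum(
        count * _monoisotopic_mass(el) for el, count in comp.items()
    )
    comp["H"] = max(0, int(round((neutral_mass - mass_so_far) / 1.00782503)))
    return comp


def _monoisotopic_mass(element: str) -> float:
    return {"C": 12.0, "H": 1.00782503, "N": 14.00307400, "O": 15.99491462,
            "S": 31.97207117}[element]


def aggregated_isotope_distribution(composition: dict[str, int], n_peaks: int) -> np.ndarray:
    """Relative abundances of the first ``n_peaks`` aggregated isotopologue
    peaks (grouped by neutron count) via polynomial convolution of the
    per-element isotope vectors."""
    dist = np.array([1.0])
    for element, count in composition.items():
        base = _ELEMENT_ISOTOPES[element]
        # exponentiation by squaring on the abundance polynomial
        power = count
        factor = base
        while power:
            if power & 1:
                dist = np.convolve(dist, factor)[: n_peaks + 8]
            factor = np.convolve(factor, factor)[: n_peaks + 8]
            power >>= 1
    out = dist[:n_peaks]
    return out / out.sum()
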