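"""Ground-truth synthetic samples: heavy/light peptide pairs, dilution
series, and a complex background matrix with known abundances.

Every species is defined at the peptide level with an exact on-column amount,
a Gaussian elution profile, and a deterministic fragment panel, so downstream
acquisition and quantification claims can be checked against truth.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chemistry import (
    NEUTRON_SPACING,
    Label,
    aggregated_isotope_distribution,
    averagine_composition,
    fragment_mz,
    heavy_label_for,
    peptide_neutral_mass,
    precursor_mz,
)

__all__ = [
    "IONS_PER_FMOL",
    "PeptideSpecies",
    "IsotopeEnvelope",
    "SampleDefinition",
    "make_pair",
    "dilution_series",
    "generate_background",
    "isotope_envelope",
    "elution_flux",
    "fragment_panel",
]

# Detected charge yield per femtomole on column (ionization, transmission and
# detection efficiency folded into one constant). Sets the absolute intensity
# scale against which AGC targets and trigger thresholds are interpreted.
IONS_PER_FMOL = 5e6

_SQRT2PI = float(np.sqrt(2.0 * np.pi))

#: number of fragment ions declared per peptide
N_FRAGMENTS = 6

#: isotopologue peaks simulated per precursor
N_ISOTOPE_PEAKS = 4


@dataclass(frozen=True)
class PeptideSpecies:
    """One ionizable analyte with its ground-truth amount and elution."""

    id: str
    sequence: str
    charge: int
    label: Label
    amount_fmol: float
    rt_apex_s: float
    peak_sigma_s: float

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        if self.amount_fmol < 0:
            raise ValueError("amount_fmol must be >= 0")
        if self.peak_sigma_s <= 0:
            raise ValueError("peak_sigma_s must be > 0")

    @property
    def precursor_mz(self) -> float:
        return precursor_mz(self.sequence, self.charge, self.label)

    @property
    def neutral_mass(self) -> float:
        return peptide_neutral_mass(self.sequence, self.label)

    def fragment_mzs(self) -> np.ndarray:
        """Declared fragment panel m/z values (singly charged y ions)."""
        return fragment_panel(self.sequence, self.label)[0]

    def fragment_fractions(self) -> np.ndarray:
        """Relative intensity share of each declared fragment; identical for
        the heavy and light members of a pair."""
        return fragment_panel(self.sequence, self.label)[1]


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Aggregated isotopologue peaks of one precursor."""

    peaks: tuple[tuple[float, float], ...]

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def abundance(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


@dataclass
class SampleDefinition:
    """A named collection of species, reproducible from its parameters."""

    name: str
    species: list[PeptideSpecies]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate species ids in sample {self.name!r}")

    def to_tsv(self, path_or_buf) -> None:
        df = pd.DataFrame(
            {
                "id": [s.id for s in self.species],
                "sequence": [s.sequence for s in self.species],
                "charge": [s.charge for s in self.species],
                "label": [s.label.value for s in self.species],
                "amount_fmol": [repr(s.amount_fmol) for s in self.species],
                "rt_s": [repr(s.rt_apex_s) for s in self.species],
                "sigma_s": [repr(s.peak_sigma_s) for s in self.species],
            }
        )
        df.to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf, name: str = "sample", seed: int = 0) -> "SampleDefinition":
        df = pd.read_csv(
            path_or_buf, sep="\t", dtype={"sequence": str},
            float_precision="round_trip",
        )
        species = [
            PeptideSpecies(
                id=str(r.id),
                sequence=r.sequence,
                charge=int(r.charge),
                label=Label(r.label),
                amount_fmol=float(r.amount_fmol),
                rt_apex_s=float(r.rt_s),
                peak_sigma_s=float(r.sigma_s),
            )
            for r in df.itertuples()
        ]
        return cls(name=name, species=species, seed=seed)


def make_pair(
    sequence: str,
    charge: int,
    light_amount_fmol: float,
    heavy_amount_fmol: float,
    rt_apex_s: float,
    peak_sigma_s: float = 6.0,
    id_prefix: str | None = None,
) -> tuple[PeptideSpecies, PeptideSpecies]:
    """Build a (light, heavy) spike-in pair sharing sequence, charge and
    elution; the heavy channel is Lys8 or Arg10 by the C-terminal residue."""
    if charge not in (2, 3, 4):
        raise ValueError(f"charge must be 2, 3 or 4 for a tryptic pair, got {charge}")
    if light_amount_fmol < 0 or heavy_amount_fmol < 0:
        raise ValueError("amounts must be >= 0")
    heavy_label = heavy_label_for(sequence)  # raises for non-K/R C-terminus
    prefix = id_prefix or sequence
    light = PeptideSpecies(
        id=f"{prefix}/{charge}.light",
        sequence=sequence,
        charge=charge,
        label=Label.LIGHT,
        amount_fmol=light_amount_fmol,
        rt_apex_s=rt_apex_s,
        peak_sigma_s=peak_sigma_s,
    )
    heavy = replace(
        light,
        id=f"{prefix}/{charge}.heavy",
        label=heavy_label,
        amount_fmol=heavy_amount_fmol,
    )
    return light, heavy


def dilution_series(
    pairs: list[tuple[PeptideSpecies, PeptideSpecies]],
    light_levels_fmol: list[float],
    heavy_level_fmol: float,
    background: list[PeptideSpecies],
    seed: int = 0,
    name: str = "dilution",
) -> list[SampleDefinition]:
    """One sample per light level; the heavy channel and the background
    matrix are identical across all samples."""
    if any(level < 0 for level in light_levels_fmol):
        raise ValueError("dilution levels must be >= 0")
    if list(light_levels_fmol) != sorted(light_levels_fmol, reverse=True):
        raise ValueError("light levels must be sorted descending")
    samples = []
    for i, level in enumerate(light_levels_fmol):
        species: list[PeptideSpecies] = []
        for light, heavy in pairs:
            species.append(replace(light, amount_fmol=level))
            species.append(replace(heavy, amount_fmol=heavy_level_fmol))
        species.extend(background)
        samples.append(
            SampleDefinition(name=f"{name}_L{i}_{level:g}fmol", species=species, seed=seed)
        )
    return samples


_AA_ALPHABET = np.array(list("GASPVTCLINDQEMHFYW"))


def generate_background(
    n_peptides: int,
    seed: int,
    rt_range_s: tuple[float, float] = (0.0, 7200.0),
    mz_range_th: tuple[float, float] = (400.0, 1210.0),
    median_fmol: float = 0.5,
    sigma_decades: float = 1.5,
    peak_sigma_s: float = 6.0,
) -> list[PeptideSpecies]:
    """Random tryptic-like background peptides emulating a complex digest.

    Abundances are log-normal (``sigma_decades`` decades, truncated at
    +/- 2 sigma) so the matrix spans >= 4 orders of magnitude; retention
    apexes are uniform over the gradient.
    """
    if n_peptides < 0:
        raise ValueError("n_peptides must be >= 0")
    rng = np.random.default_rng(seed)
    species: list[PeptideSpecies] = []
    k = 0
    while len(species) < n_peptides:
        length = int(rng.integers(7, 16))
        seq = "".join(rng.choice(_AA_ALPHABET, size=length)) + ("K" if rng.random() < 0.5 else "R")
        charge = 2 if rng.random() < 0.7 else 3
        mz = precursor_mz(seq, charge)
        if not mz_range_th[0] <= mz <= mz_range_th[1]:
            continue
        z = np.clip(rng.standard_normal(), -2.0, 2.0)
        amount = median_fmol * 10.0 ** (sigma_decades * z)
        rt = rng.uniform(*rt_range_s)
        species.append(
            PeptideSpecies(
                id=f"bg{k:05d}",
                sequence=seq,
                charge=charge,
                label=Label.LIGHT,
                amount_fmol=float(amount),
                rt_apex_s=float(rt),
                peak_sigma_s=peak_sigma_s,
            )
        )
        k += 1
    return species


def isotope_envelope(species: PeptideSpecies, n_peaks: int = N_ISOTOPE_PEAKS) -> IsotopeEnvelope:
    """Averagine-model isotope envelope centered on the monoisotopic m/z."""
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    comp = averagine_composition(species.neutral_mass)
    abund = aggregated_isotope_distribution(comp, n_peaks)
    mono = species.precursor_mz
    spacing = NEUTRON_SPACING / species.charge
    peaks = tuple((mono + i * spacing, float(a)) for i, a in enumerate(abund))
    return IsotopeEnvelope(peaks=peaks)


def elution_flux(species: PeptideSpecies, t) -> np.ndarray | float:
    """Ion flux (charges/s) of the species at chromatographic time ``t``.

    Gaussian profile; the integral over time equals
    ``amount_fmol * IONS_PER_FMOL``.
    """
    amp = species.amount_fmol * IONS_PER_FMOL / (species.peak_sigma_s * _SQRT2PI)
    return amp * np.exp(-((np.asarray(t, dtype=float) - species.rt_apex_s) ** 2)
                        / (2.0 * species.peak_sigma_s**2))


def fragment_panel(sequence: str, label: Label = Label.LIGHT) -> tuple[np.ndarray, np.ndarray]:
    """Declared fragment panel: up to six singly charged y ions (y3 upward)
    with relative intensities drawn once per sequence from a Dirichlet and
    fixed thereafter (identical across label channels).

    Label-bearing y ions keep the heavy/light fragment shift well defined,
    which trigger validation and light-channel quantification both rely on.
    """
    n_res = len(sequence)
    lo = 3 if n_res > N_FRAGMENTS + 2 else max(1, n_res - 1 - N_FRAGMENTS + 1)
    ordinals = list(range(lo, min(lo + N_FRAGMENTS, n_res)))
    mzs = np.array([fragment_mz(sequence, "y", k, 1, label) for k in ordinals])
    rng = np.random.default_rng(zlib.crc32(sequence.encode()) & 0x7FFFFFFF)
    fracs = rng.dirichlet(np.full(len(ordinals), 2.0))
    return mzs, fracs


def sample_to_tsv_string(sample: SampleDefinition) -> str:
    buf = io.StringIO()
    sample.to_tsv(buf)
    return buf.getvalue()
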