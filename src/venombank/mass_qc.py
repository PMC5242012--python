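"""Masses, oxidation-state ladders, isotope patterns and quantification.

Each disulphide bridge removes two hydrogen atoms, so a peptide with up to
``n_bridges_max = floor(n_cys / 2)`` bridges shows a mass ladder

    mass(n) = mass(0) - n * 2 * m_H        n = 0 .. n_bridges_max

in both monoisotopic (m_H = 1.007825 Da) and average (m_H = 1.00794 Da)
modes.  An observed deconvoluted mass is called against this ladder: the
species minimising |observed - mass| within tolerance wins, ties broken
toward the more oxidized species (reduced forms are not expected to survive
the purification chemistry).  Matching defaults to average masses with a
1.0 Da tolerance, appropriate for quadrupole-class deconvolution.

The theoretical isotope pattern is computed by convolving per-element
isotopologue distributions (indexed by nominal mass offset from the
monoisotopic peak) from the peptide's elemental composition, minus 2 H per
bridge.  Extinction coefficients at 280 nm follow the Gill-von Hippel
composition rule: 5500 per Trp + 1490 per Tyr + 125 per cystine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from pyteomics import mass as pmass

from .peptide_io import AMINO_ACIDS

M_H_MONO = 1.007825
M_H_AVG = 1.00794

_VALID = frozenset(AMINO_ACIDS)


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - _VALID
    if bad or not sequence:
        raise ValueError(f"invalid peptide sequence (bad residues: {sorted(bad)})")


def peptide_mass(sequence: str, mode: str = "mono") -> float:
    """Reduced (free-thiol) peptide mass in Da: residue masses + water."""
    _check_sequence(sequence)
    if mode == "mono":
        return pmass.calculate_mass(sequence=sequence)
    if mode == "average":
        return pmass.calculate_mass(sequence=sequence, average=True)
    raise ValueError(f"unknown mass mode {mode!r}")


class Species(NamedTuple):
    n_bridges: int
    mono: float
    average: float


def oxidized_species(mono_reduced: float, average_reduced: float,
                     n_bridges_max: int) -> list[Species]:
    """Oxidation-state ladder: each bridge removes 2 H from both modes."""
    if n_bridges_max < 0:
        raise ValueError("n_bridges_max must be >= 0")
    return [
        Species(n, mono_reduced - 2 * n * M_H_MONO,
                average_reduced - 2 * n * M_H_AVG)
        for n in range(n_bridges_max + 1)
    ]


@dataclass(frozen=True)
class MassProfile:
    """Reduced and per-bridge oxidized masses for one peptide."""

    peptide_id: str
    monoisotopic_reduced: float
    average_reduced: float
    species: tuple[Species, ...]
    epsilon_280: float
    composition: Mapping[str, int]
    n_bridges_max: int

    @classmethod
    def from_sequence(cls, sequence: str, peptide_id: str = "peptide",
                      n_bridges_max: int | None = None) -> "MassProfile":
        _check_sequence(sequence)
        if n_bridges_max is None:
            n_bridges_max = sequence.count("C") // 2
        mono = peptide_mass(sequence, "mono")
        avg = peptide_mass(sequence, "average")
        comp = dict(pmass.Composition(sequence=sequence))
        eps = extinction_coeff(sequence).epsilon
        return cls(
            peptide_id=peptide_id,
            monoisotopic_reduced=mono,
            average_reduced=avg,
            species=tuple(oxidized_species(mono, avg, n_bridges_max)),
            epsilon_280=eps,
            composition=comp,
            n_bridges_max=n_bridges_max,
        )


def _element_isotopes(element: str) -> list[tuple[int, float]]:
    """(nominal offset from lightest isotope, abundance) pairs, abundance > 0."""
    data = pmass.nist_mass[element]
    isos = [(num, ab) for num, (m, ab) in data.items() if num != 0 and ab > 0]
    base = min(num for num, _ in isos)
    return [(num - base, ab) for num, ab in sorted(isos)]


def _power_convolve(dist: np.ndarray, n: int, trim: float = 1e-12) -> np.ndarray:
    """Distribution of the sum of ``n`` iid copies, by binary exponentiation."""
    result = np.array([1.0])
    base = dist.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)
            result = _trim(result, trim)
        n >>= 1
        if n:
            base = np.convolve(base, base)
            base = _trim(base, trim)
    return result


def _trim(arr: np.ndarray, rel: float) -> np.ndarray:
    keep = np.nonzero(arr > arr.max() * rel)[0]
    return arr[: keep[-1] + 1] if keep.size else arr[:1]


def theoretical_isotope_pattern(
    sequence: str,
    n_bridges: int = 0,
    threshold: float = 1e-4,
    normalize: str = "max",
) -> list[tuple[int, float]]:
    """Aggregated isotope pattern of a peptide with ``n_bridges`` bridges.

    Returns (nominal offset from the monoisotopic peak, relative abundance)
    pairs; abundances are normalized to the tallest peak (``normalize='max'``)
    or to unit sum (``'sum'``), then truncated below ``threshold``.
    """
    _check_sequence(sequence)
    comp = dict(pmass.Composition(sequence=sequence))
    comp["H"] = comp.get("H", 0) - 2 * n_bridges
    if comp["H"] < 0:
        raise ValueError("composition has fewer H atoms than bridges remove")
    return composition_isotope_pattern(comp, threshold, normalize)


def composition_isotope_pattern(
    composition: Mapping[str, int],
    threshold: float = 1e-4,
    normalize: str = "max",
) -> list[tuple[int, float]]:
    """Isotope pattern from an elemental composition, e.g. {'C': 6, 'H': 12}."""
    pattern = np.array([1.0])
    for element, count in composition.items():
        if count == 0:
            continue
        if count < 0:
            raise ValueError(f"negative atom count for {element}")
        isos = _element_isotopes(element)
        per_atom = np.zeros(max(off for off, _ in isos) + 1)
        for off, ab in isos:
            per_atom[off] = ab
        per_atom /= per_atom.sum()
        pattern = np.convolve(pattern, _power_convolve(per_atom, count))
    if normalize == "max":
        pattern = pattern / pattern.max()
    elif normalize == "sum":
        pattern = pattern / pattern.sum()
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return [(i, float(a)) for i, a in enumerate(pattern) if a >= threshold]


@dataclass(frozen=True)
class QCResult:
    peptide_id: str
    observed: float
    matched_n_bridges: int | None
    delta: float | None
    status: str  # fully_oxidized | partially_oxidized | reduced | no_match
    tolerance: float


def match_observed(profile: MassProfile, observed: float,
                   tolerance: float = 1.0, mode: str = "average") -> QCResult:
    """Call the oxidation state of an observed deconvoluted mass.

    Picks the ladder species minimising |observed - mass|; ties go to the
    more oxidized species.  No species within ``tolerance`` -> ``no_match``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    attr = {"average": "average", "mono": "mono"}[mode]
    best_n, best_delta = None, None
    for sp in profile.species:
        delta = observed - getattr(sp, attr)
        if (best_delta is None or abs(delta) < abs(best_delta)
                or (abs(delta) == abs(best_delta) and sp.n_bridges > best_n)):
            best_n, best_delta = sp.n_bridges, delta
    if best_delta is None or abs(best_delta) > tolerance:
        return QCResult(profile.peptide_id, observed, None, None,
                        "no_match", tolerance)
    if best_n == profile.n_bridges_max:
        status = "fully_oxidized"
    elif best_n == 0:
        status = "reduced"
    else:
        status = "partially_oxidized"
    return QCResult(profile.peptide_id, observed, best_n, best_delta,
                    status, tolerance)


class Extinction(NamedTuple):
    epsilon: float  # per M per cm at 280 nm
    low_confidence: bool


def extinction_coeff(sequence: str, assume_cystine: bool = True) -> Extinction:
    """Gill-von Hippel A280 coefficient: 5500*W + 1490*Y + 125*cystine."""
    _check_sequence(sequence)
    n_trp = sequence.count("W")
    n_tyr = sequence.count("Y")
    n_cystine = sequence.count("C") // 2 if assume_cystine else 0
    eps = 5500.0 * n_trp + 1490.0 * n_tyr + 125.0 * n_cystine
    return Extinction(eps, eps == 0.0)


class Quantification(NamedTuple):
    conc_um: float
    amount_nmol: float
    amount_ug: float
    yield_mg_per_l: float


def concentration_and_yield(
    mass_da: float,
    volume_ul: float,
    culture_ml: float,
    conc_um: float | None = None,
    a280: float | None = None,
    epsilon: float | None = None,
) -> Quantification:
    """Convert a concentration (or A280) to molar amount and culture yield.

    Exact arithmetic: amount = conc * volume; yield scales the recovered mass
    to one litre of culture.
    """
    if mass_da <= 0 or volume_ul <= 0 or culture_ml <= 0:
        raise ValueError("mass, volume and culture volume must be positive")
    if conc_um is None:
        if a280 is None:
            raise ValueError("provide either conc_um or a280")
        if not epsilon:
            raise ValueError(
                "extinction coefficient is zero: A280 quantification is "
                "impossible, use peak-area quantification instead"
            )
        conc_um = a280 / epsilon * 1e6
    amount_nmol = conc_um * volume_ul / 1000.0  # uM * uL = pmol; /1000 -> nmol
    amount_ug = amount_nmol * mass_da / 1000.0
    yield_mg_per_l = amount_ug / culture_ml  # ug/mL == mg/L
    return Quantification(conc_um, amount_nmol, amount_ug, yield_mg_per_l)


def molar_recovery(fusion_yield_mg_per_l: float, fusion_mass_da: float,
                   peptide_yield_mg_per_l: float,
                   peptide_mass_da: float) -> float:
    """Percent of fusion-protein moles recovered as cleaved peptide."""
    if min(fusion_yield_mg_per_l, fusion_mass_da,
           peptide_yield_mg_per_l, peptide_mass_da) <= 0:
        raise ValueError("all inputs must be positive")
    return 100.0 * (peptide_yield_mg_per_l / peptide_mass_da) / (
        fusion_yield_mg_per_l / fusion_mass_da
    )
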