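"""Peptide mass and transition arithmetic for triple-quadrupole assays.

A transition pairs a doubly charged precursor with one singly charged
y-fragment. The monitored y-series runs from y3 to the terminal y-ion
y(n-1) — y_n is never monitored because it is just the precursor at a
different charge. Collision energy follows the instrument's linear ramp
CE = slope * precursor_mz + intercept, per precursor charge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .constants import (
    CANONICAL_RESIDUES,
    CARBAMIDOMETHYL,
    MONOISOTOPIC_RESIDUE_MASSES,
    PROTON,
    WATER_MONO,
)

logger = logging.getLogger(__name__)

MIN_FRAGMENT_INDEX = 3


def _default_residues() -> dict[str, float]:
    return dict(MONOISOTOPIC_RESIDUE_MASSES)


def _default_mods() -> dict[str, float]:
    return {"C": CARBAMIDOMETHYL}


@dataclass
class MassConstants:
    """Residue mass table plus fixed modifications.

    ``fixed_mods`` maps residue letter to a Da offset applied to every
    occurrence; the default is carbamidomethyl on cysteine (the discovery
    workflow alkylates cysteines with iodoacetamide). Pass ``fixed_mods={}``
    to compute unmodified masses.
    """

    residue_masses: dict[str, float] = field(default_factory=_default_residues)
    water: float = WATER_MONO
    proton: float = PROTON
    fixed_mods: dict[str, float] = field(default_factory=_default_mods)

    def __post_init__(self) -> None:
        missing = CANONICAL_RESIDUES - set(self.residue_masses)
        if missing:
            raise ValueError(f"residue table missing letters: {sorted(missing)}")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be positive")

    def residue(self, letter: str) -> float:
        try:
            base = self.residue_masses[letter]
        except KeyError:
            raise ValueError(f"unknown residue letter {letter!r}") from None
        return base + self.fixed_mods.get(letter, 0.0)


@dataclass(frozen=True)
class CEParams:
    """Per-charge linear collision-energy ramp: CE = slope*mz + intercept.

    The defaults are the generic Thermo triple-quadrupole ramp shipped by
    common transition-list tools; instrument-specific constants should be
    supplied via configuration.
    """

    per_charge: tuple[tuple[int, float, float], ...] = (
        (2, 0.034, 3.314),
        (3, 0.044, 3.314),
    )

    def coefficients(self, charge: int) -> tuple[float, float]:
        for z, slope, intercept in self.per_charge:
            if z == charge:
                return slope, intercept
        raise ValueError(f"no collision-energy coefficients for charge {charge}+")


@dataclass(frozen=True)
class Transition:
    """One monitored precursor -> product ion pair."""

    peptide: str
    precursor_charge: int
    precursor_mz: float
    fragment: int  # y-index
    product_charge: int
    product_mz: float
    collision_energy: float

    @property
    def fragment_label(self) -> str:
        return f"y{self.fragment}"

    def __post_init__(self) -> None:
        n = len(self.peptide)
        if not (MIN_FRAGMENT_INDEX <= self.fragment <= n - 1):
            raise ValueError(
                f"fragment y{self.fragment} outside y{MIN_FRAGMENT_INDEX}..y{n - 1} "
                f"for {self.peptide}"
            )
        if self.product_mz >= self.precursor_mz * self.precursor_charge:
            raise ValueError("product m/z must fall below the precursor neutral+proton mass")
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("m/z values must be positive")


def monoisotopic_mass(peptide: str, constants: MassConstants | None = None) -> float:
    """Neutral monoisotopic mass in Da (residues + fixed mods + water)."""
    constants = constants or MassConstants()
    if not peptide:
        raise ValueError("empty peptide")
    return sum(constants.residue(c) for c in peptide) + constants.water


def precursor_mz(peptide: str, charge: int = 2, constants: MassConstants | None = None) -> float:
    """(M + z*proton) / z for the protonated peptide."""
    constants = constants or MassConstants()
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (monoisotopic_mass(peptide, constants) + charge * constants.proton) / charge


def y_ion_mz(peptide: str, index: int, constants: MassConstants | None = None) -> float:
    """Singly charged y-ion m/z: C-terminal ``index`` residues + water + proton."""
    constants = constants or MassConstants()
    if not (1 <= index <= len(peptide)):
        raise ValueError(f"y-index {index} out of range for {len(peptide)}-mer")
    tail = peptide[len(peptide) - index :]
    return sum(constants.residue(c) for c in tail) + constants.water + constants.proton


def apply_ce(precursor_mz_value: float, charge: int, ce_params: CEParams | None = None) -> float:
    """Collision energy (eV) from the per-charge linear ramp."""
    ce_params = ce_params or CEParams()
    slope, intercept = ce_params.coefficients(charge)
    return slope * precursor_mz_value + intercept


def enumerate_transitions(
    peptide: str,
    constants: MassConstants | None = None,
    ce_params: CEParams | None = None,
    precursor_charge: int = 2,
    mz_range: tuple[float, float] = (10.0, 2000.0),
) -> list[Transition]:
    """All candidate transitions for one peptide: y3..y(n-1), ascending.

    Product ions outside ``mz_range`` (instrument transmission limits) are
    dropped with a log message rather than silently.
    """
    constants = constants or MassConstants()
    ce_params = ce_params or CEParams()
    n = len(peptide)
    if n < MIN_FRAGMENT_INDEX + 1:
        raise ValueError(
            f"peptide {peptide!r} too short for a y{MIN_FRAGMENT_INDEX}..y{n - 1} series"
        )
    prec = precursor_mz(peptide, precursor_charge, constants)
    ce = apply_ce(prec, precursor_charge, ce_params)
    lo, hi = mz_range
    out: list[Transition] = []
    for idx in range(MIN_FRAGMENT_INDEX, n):
        prod = y_ion_mz(peptide, idx, constants)
        if not (lo <= prod <= hi):
            logger.warning(
                "dropping %s y%d: product m/z %.4f outside instrument range [%g, %g]",
                peptide, idx, prod, lo, hi,
            )
            continue
        out.append(
            Transition(
                peptide=peptide,
                precursor_charge=precursor_charge,
                precursor_mz=prec,
                fragment=idx,
                product_charge=1,
                product_mz=prod,
                collision_energy=ce,
            )
        )
    return out


def b_ion_mass(peptide: str, index: int, constants: MassConstants | None = None) -> float:
    """Neutral-plus-proton b-ion m/z; internal consistency checks only."""
    constants = constants or MassConstants()
    if not (1 <= index <= len(peptide)):
        raise ValueError(f"b-index {index} out of range")
    head = peptide[:index]
    return sum(constants.residue(c) for c in head) + constants.proton
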