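"""Candidate GAG compositions, neutral losses, and theoretical ions.

A composition is a 7-tuple of residue counts
``[dHexA, HexA, GlcN, Ac, SO3, Levoglucosan, Anhydromannitol]`` describing
one oligosaccharide component of an LMWH-type mixture: an alternating
chain of uronic acids (dHexA is the 4,5-unsaturated lyase product, HexA a
saturated glucuronic/iduronic residue) and glucosamines, with acetyl and
sulfate substituents counted separately and two possible reducing-end
artifact residues (1,6-anhydro levoglucosan; 2,5-anhydromannitol from
nitrous-acid depolymerization).  Residue masses follow the
residues-plus-one-water convention: the neutral monoisotopic mass is the
sum of residue formulas plus H2O.

During electrospray, components shed labile neutral groups; the four loss
groups modeled are SO3, NH, NHSO3 and COO (CO2), at most ``max_losses``
groups in total per ion (default 2).  Ions are plain deprotonated species
[M - zH]z-.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .isotopes import (
    NEUTRON_SPACING,
    PROTON_MASS,
    ElementalFormula,
    isotope_distribution,
)

__all__ = [
    "Composition",
    "LossVector",
    "CompositionRules",
    "TheoreticalIon",
    "formula_of",
    "neutral_mass",
    "ion_mz",
    "valid_losses",
    "enumerate_by_mass",
    "enumerate_compositions",
    "expand_ions",
]

NO_LOSS: "LossVector"

# Residue elemental formulas (already minus water, chain convention)
_RESIDUE_FORMULAS = (
    ElementalFormula(C=6, H=6, O=5),            # dHexA, 158.02152 Da
    ElementalFormula(C=6, H=8, O=6),            # HexA, 176.03209 Da
    ElementalFormula(C=6, H=11, N=1, O=4),      # GlcN, 161.06881 Da
    ElementalFormula(C=2, H=2, O=1),            # acetyl substituent, 42.01057 Da
    ElementalFormula(S=1, O=3),                 # sulfate substituent, 79.95682 Da
    ElementalFormula(C=6, H=8, O=4),            # levoglucosan residue, 144.04226 Da
    ElementalFormula(C=6, H=10, O=4),           # anhydromannitol residue, 146.05791 Da
)

_WATER = ElementalFormula(H=2, O=1)

_LOSS_FORMULAS = (
    ElementalFormula(S=1, O=3),                 # SO3
    ElementalFormula(N=1, H=1),                 # NH
    ElementalFormula(N=1, H=1, S=1, O=3),       # NHSO3
    ElementalFormula(C=1, O=2),                 # COO (CO2)
)


class Composition(NamedTuple):
    """Residue counts of one GAG component."""

    dhexa: int = 0
    hexa: int = 0
    glcn: int = 0
    ac: int = 0
    so3: int = 0
    levoglucosan: int = 0
    anhydromannitol: int = 0

    def __str__(self) -> str:
        return "[" + ", ".join(str(c) for c in self) + "]"


class LossVector(NamedTuple):
    """Counts of neutral groups lost from an intact component."""

    so3: int = 0
    nh: int = 0
    nhso3: int = 0
    coo: int = 0

    @property
    def total(self) -> int:
        return sum(self)

    def __str__(self) -> str:
        return "[" + ", ".join(str(c) for c in self) + "]"


NO_LOSS = LossVector()


@dataclass(frozen=True)
class CompositionRules:
    """Chain-chemistry constraints for enumeration.

    A linear GAG chain alternates uronic acid and hexosamine-type
    residues, so the two counts differ by at most one; at most one
    unsaturated end; reducing-end artifacts are mutually exclusive;
    sulfation is capped at 3 sites per GlcN, 1 per uronic acid and 2 per
    anhydromannitol.
    """

    allow_levoglucosan: bool = True
    allow_anhydromannitol: bool = True
    max_sulfo_per_glcn: int = 3

    def max_so3(self, comp: Composition) -> int:
        return (
            self.max_sulfo_per_glcn * comp.glcn
            + comp.dhexa
            + comp.hexa
            + 2 * comp.anhydromannitol
        )

    def is_valid(self, comp: Composition) -> bool:
        if any(c < 0 for c in comp) or not any(c > 0 for c in comp):
            return False
        if comp.dhexa > 1:
            return False
        if comp.levoglucosan + comp.anhydromannitol > 1:
            return False
        if not self.allow_levoglucosan and comp.levoglucosan:
            return False
        if not self.allow_anhydromannitol and comp.anhydromannitol:
            return False
        uronic = comp.dhexa + comp.hexa
        amine = comp.glcn + comp.anhydromannitol
        if abs(uronic - amine) > 1:
            return False
        if comp.ac > comp.glcn:
            return False
        if comp.so3 > self.max_so3(comp):
            return False
        return True


DEFAULT_RULES = CompositionRules()


def formula_of(composition: Composition, loss: LossVector = NO_LOSS) -> ElementalFormula:
    """Elemental formula of a component after the given neutral losses."""
    composition = Composition(*composition)
    loss = LossVector(*loss)
    formula = _WATER
    for count, residue in zip(composition, _RESIDUE_FORMULAS):
        formula = formula + residue.scaled(count)
    for count, group in zip(loss, _LOSS_FORMULAS):
        formula = formula - group.scaled(count)
    if any(n < 0 for n in formula):
        raise ValueError(f"loss {loss} not available for composition {composition}")
    return formula


def neutral_mass(composition: Composition, loss: LossVector = NO_LOSS) -> float:
    """Neutral monoisotopic mass (Da) of a component after losses."""
    return formula_of(composition, loss).monoisotopic_mass


def ion_mz(neutral: float, charge: int) -> float:
    """m/z of the [M - zH]z- deprotonated anion of a neutral mass."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral - charge * PROTON_MASS) / charge


def valid_losses(
    composition: Composition, max_losses: int = 2
) -> list[LossVector]:
    """All chemically available loss vectors with total count <= max_losses.

    SO3-containing losses are limited by the sulfate count, NH-containing
    losses by free (non-acetylated) amines, and CO2 loss by carboxylate
    (uronic acid) count.  The zero vector is always included.
    """
    composition = Composition(*composition)
    free_amine = composition.glcn - composition.ac
    out: list[LossVector] = []
    for so3, nh, nhso3, coo in product(range(max_losses + 1), repeat=4):
        lv = LossVector(so3, nh, nhso3, coo)
        if lv.total > max_losses:
            continue
        if so3 + nhso3 > composition.so3:
            continue
        if nh + nhso3 > free_amine:
            continue
        if coo > composition.dhexa + composition.hexa:
            continue
        out.append(lv)
    return out


def enumerate_by_mass(
    mass_lo: float,
    mass_hi: float,
    rules: CompositionRules | None = None,
) -> list[Composition]:
    """All rule-valid compositions with intact neutral mass in the window.

    Deterministic lexicographic order.
    """
    rules = rules or DEFAULT_RULES
    water = _WATER.monoisotopic_mass
    m_dhexa, m_hexa, m_glcn, m_ac, m_so3, m_lev, m_anh = (
        f.monoisotopic_mass for f in _RESIDUE_FORMULAS
    )
    out: list[Composition] = []
    ends = [(0, 0)]
    if rules.allow_levoglucosan:
        ends.append((1, 0))
    if rules.allow_anhydromannitol:
        ends.append((0, 1))
    for dhexa in (0, 1):
        for lev, anh in ends:
            base_end = water + dhexa * m_dhexa + lev * m_lev + anh * m_anh
            if base_end > mass_hi:
                continue
            hexa = 0
            while True:
                base_u = base_end + hexa * m_hexa
                uronic = dhexa + hexa
                glcn_lo = max(0, uronic - 1 - anh)
                if base_u + glcn_lo * m_glcn > mass_hi:
                    break
                for glcn in range(glcn_lo, uronic + 2 - anh):
                    base_g = base_u + glcn * m_glcn
                    if base_g > mass_hi:
                        continue
                    for ac in range(glcn + 1):
                        base_a = base_g + ac * m_ac
                        if base_a > mass_hi:
                            break
                        comp0 = Composition(dhexa, hexa, glcn, ac, 0, lev, anh)
                        so3_cap = rules.max_so3(comp0)
                        for so3 in range(so3_cap + 1):
                            mass = base_a + so3 * m_so3
                            if mass > mass_hi:
                                break
                            if mass < mass_lo:
                                continue
                            comp = Composition(dhexa, hexa, glcn, ac, so3, lev, anh)
                            if rules.is_valid(comp):
                                out.append(comp)
                hexa += 1
    return sorted(set(out))


def enumerate_compositions(
    mz_lo: float,
    mz_hi: float,
    max_charge: int = 5,
    rules: CompositionRules | None = None,
    max_losses: int = 2,
) -> list[Composition]:
    """Compositions with at least one ion (any valid loss, z <= max_charge)
    whose monoisotopic m/z falls in [mz_lo, mz_hi].

    Deduplicated, lexicographically ordered.
    """
    if not mz_lo < mz_hi:
        raise ValueError("mz_lo must be < mz_hi")
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    max_loss_mass = max_losses * max(f.monoisotopic_mass for f in _LOSS_FORMULAS)
    mass_hi = mz_hi * max_charge + max_charge * PROTON_MASS + max_loss_mass
    mass_lo = max(0.0, mz_lo * 1 + PROTON_MASS)
    candidates = enumerate_by_mass(mass_lo, mass_hi, rules=rules)
    out = []
    for comp in candidates:
        hit = False
        for loss in valid_losses(comp, max_losses):
            neutral = neutral_mass(comp, loss)
            for z in range(1, max_charge + 1):
                if neutral <= z * PROTON_MASS:
                    continue
                if mz_lo <= ion_mz(neutral, z) <= mz_hi:
                    hit = True
                    break
            if hit:
                break
        if hit:
            out.append(comp)
    return out


@dataclass(frozen=True)
class TheoreticalIon:
    """A deprotonated (possibly loss-derived) ion with its isotope ladder."""

    composition: Composition
    loss: LossVector
    charge: int
    mono_mz: float
    isotope_mzs: np.ndarray
    distribution: np.ndarray

    @property
    def is_derived(self) -> bool:
        return self.loss.total > 0

    @property
    def neutral_mass(self) -> float:
        return self.mono_mz * self.charge + self.charge * PROTON_MASS


def expand_ions(
    composition: Composition,
    max_charge: int = 5,
    max_losses: int = 2,
    n_isotopes: int = 5,
) -> list[TheoreticalIon]:
    """All theoretical ions of a component: every valid loss vector with
    total <= max_losses crossed with every charge 1..max_charge."""
    composition = Composition(*composition)
    ions: list[TheoreticalIon] = []
    for loss in valid_losses(composition, max_losses):
        formula = formula_of(composition, loss)
        neutral = formula.monoisotopic_mass
        dist = isotope_distribution(formula, n_isotopes)
        for z in range(1, max_charge + 1):
            if neutral <= z * PROTON_MASS:
                continue
            mono = ion_mz(neutral, z)
            ladder = mono + np.arange(n_isotopes) * NEUTRON_SPACING / z
            ions.append(
                TheoreticalIon(
                    composition=composition,
                    loss=loss,
                    charge=z,
                    mono_mz=mono,
                    isotope_mzs=ladder,
                    distribution=dist,
                )
            )
    return ions
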