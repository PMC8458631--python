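"""Isotopic peak cluster detection and intensity-model filtering.

For every charge state up to ``max_charge`` and every seed peak, a
candidate cluster is grown rightward (toward heavier isotopes) at the
expected spacing 1.0033548/z, accepting the nearest peak within a ppm
tolerance at each step.  Runs of at least ``min_members`` peaks become
candidates; overlapping candidates at different charges are all kept and
disambiguated downstream by matching and scoring.

Candidates are then screened by the similarity between their normalized
intensity distribution and the theoretical distribution predicted by the
polynomial intensity model at the candidate's neutral mass (exact BRAIN
values are used outside the model's fitted range).  Similarity is
1 - JS divergence; the default threshold 0.9 keeps only envelopes with
plausible isotope patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .isotopes import (
    NEUTRON_SPACING,
    PROTON_MASS,
    ElementalFormula,
    IntensityModel,
    isotope_distribution,
    js_divergence,
)
from .spectrum_io import Spectrum

__all__ = ["IsotopicCluster", "extract_candidates", "filter_clusters"]

# crude CHOS-average elemental composition per Da of GAG chain, used only
# for exact-distribution fallback outside the model's fitted mass range
_ATOMS_PER_DA = {"C": 0.0224, "H": 0.0354, "N": 0.0019, "O": 0.0326, "S": 0.0047}


@dataclass
class IsotopicCluster:
    """A detected run of isotope peaks sharing one charge state."""

    mzs: np.ndarray
    intensities: np.ndarray
    charge: int
    similarity: float | None = None
    cluster_id: int = -1

    def __post_init__(self) -> None:
        self.mzs = np.asarray(self.mzs, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)

    def __len__(self) -> int:
        return int(self.mzs.size)

    @property
    def mono_mz(self) -> float:
        return float(self.mzs[0])

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())

    @property
    def distribution(self) -> np.ndarray:
        return self.intensities / self.intensities.sum()

    @property
    def neutral_mass(self) -> float:
        return self.mono_mz * self.charge + self.charge * PROTON_MASS


def extract_candidates(
    spectrum: Spectrum,
    max_charge: int = 5,
    max_peaks: int = 5,
    ppm: float = 20.0,
    min_members: int = 3,
    suppress_nested: bool = True,
) -> list[IsotopicCluster]:
    """Extract isotopic cluster candidates at every charge state.

    A seed peak starts a candidate only if no peak sits one isotope
    spacing to its left at the same charge (the monoisotopic peak is the
    leftmost member), which suppresses duplicate sub-clusters.

    Every even-charge envelope contains a valid lower-charge ladder (the
    alternating peaks of a z=2 envelope are spaced exactly 1.0033548),
    so with ``suppress_nested`` a candidate whose members are all members
    of a higher-charge candidate is dropped; genuinely overlapping
    envelopes of different species are unaffected because they never
    nest completely.
    """
    mz = spectrum.mz
    inten = spectrum.intensity
    out: list[IsotopicCluster] = []
    member_sets: list[frozenset[int]] = []
    cid = 0
    for z in range(1, max_charge + 1):
        spacing = NEUTRON_SPACING / z
        for i in range(len(mz)):
            # leftmost-member check
            expected_left = mz[i] - spacing
            tol = ppm * 1e-6 * expected_left
            j = np.searchsorted(mz, expected_left)
            has_left = any(
                0 <= k < len(mz) and abs(mz[k] - expected_left) <= tol
                for k in (j - 1, j)
            )
            if has_left:
                continue
            members = [i]
            while len(members) < max_peaks:
                expected = mz[members[-1]] + spacing
                tol = ppm * 1e-6 * expected
                j = np.searchsorted(mz, expected)
                best = None
                for k in (j - 1, j):
                    if 0 <= k < len(mz):
                        d = abs(mz[k] - expected)
                        if d <= tol and (best is None or d < abs(mz[best] - expected)):
                            best = k
                if best is None:
                    break
                members.append(best)
            if len(members) >= min_members:
                out.append(
                    IsotopicCluster(
                        mzs=mz[members],
                        intensities=inten[members],
                        charge=z,
                        cluster_id=cid,
                    )
                )
                member_sets.append(frozenset(members))
                cid += 1
    if suppress_nested:
        keep = [
            i
            for i, (cand, mem) in enumerate(zip(out, member_sets))
            if not any(
                other.charge > cand.charge and mem <= other_mem
                for other, other_mem in zip(out, member_sets)
            )
        ]
        out = [out[i] for i in keep]
    return out


def _exact_distribution(neutral_mass: float, n_peaks: int) -> np.ndarray:
    """Approximate exact distribution for an unknown analyte of given mass,
    from a GAG-averaged elemental composition."""
    formula = ElementalFormula(
        *(max(1, round(neutral_mass * f)) for f in _ATOMS_PER_DA.values())
    )
    return isotope_distribution(formula, n_peaks)


def filter_clusters(
    candidates: list[IsotopicCluster],
    model: IntensityModel,
    min_similarity: float = 0.9,
) -> list[IsotopicCluster]:
    """Keep candidates whose intensity distribution resembles theory.

    The model's predicted first-five-peak fractions at the candidate's
    neutral mass are truncated to the candidate's member count and
    renormalized; similarity = 1 - JS divergence against the candidate's
    normalized intensities.  Candidates with similarity strictly above
    ``min_similarity`` pass.
    """
    kept: list[IsotopicCluster] = []
    for cand in candidates:
        mass = cand.neutral_mass
        if model is not None and model.in_range(mass):
            theo = model.predict(mass)
        else:
            theo = _exact_distribution(mass, 5)
        theo = theo[: len(cand)]
        if theo.sum() <= 0:
            continue
        sim = 1.0 - js_divergence(cand.distribution, theo)
        cand.similarity = sim
        if sim > min_similarity:
            kept.append(cand)
    return kept
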