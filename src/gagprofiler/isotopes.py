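"""Aggregated isotopic distributions and spectral similarity.

Theoretical isotope envelopes for CHNOS ions are computed with the BRAIN
polynomial-recurrence: the aggregated-isotopologue abundances are the
coefficients of the product polynomial ``prod_e Q_e(x)**n_e``, where
``Q_e`` is the isotope-abundance polynomial of element ``e`` (indexed by
nominal mass shift) and ``n_e`` the atom count.  The coefficients are
obtained by a Newton-Girard recursion over the power sums of the inverse
roots of the elemental polynomials, which costs O(k^2) for the first k
peaks independently of molecule size.

A degree-4 polynomial intensity model maps neutral monoisotopic mass to
the relative intensities of the first five isotopic peaks; it is fitted
once over the mass range of interest and used to screen experimental
isotope clusters cheaply, with exact BRAIN values available on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon

__all__ = [
    "ElementalFormula",
    "isotope_distribution",
    "isotope_distributions",
    "max_isotope_shift",
    "IntensityModel",
    "fit_intensity_model",
    "js_divergence",
    "js_similarity",
]

# IUPAC isotopic compositions; tuples of (mass, abundance) per nominal
# mass shift relative to the lightest isotope.  S-36 sits at shift +4.
_ELEMENTS = ("C", "H", "N", "O", "S")

_ISOTOPES: dict[str, list[tuple[int, float, float]]] = {
    # element -> [(shift, mass, abundance), ...]
    "C": [(0, 12.0, 0.9893), (1, 13.00335484, 0.0107)],
    "H": [(0, 1.00782503, 0.999885), (1, 2.01410178, 0.000115)],
    "N": [(0, 14.00307401, 0.99636), (1, 15.00010890, 0.00364)],
    "O": [(0, 15.99491462, 0.99757), (1, 16.99913176, 0.00038), (2, 17.99915961, 0.00205)],
    "S": [
        (0, 31.97207117, 0.9499),
        (1, 32.97145891, 0.0075),
        (2, 33.96786701, 0.0425),
        (4, 35.96708071, 0.0001),
    ],
}

MONOISOTOPIC_MASS = {el: iso[0][1] for el, iso in _ISOTOPES.items()}

#: Mass of a proton (Da); deprotonation removes H and one electron's worth
#: is retained by the anion, so m/z arithmetic uses this value.
PROTON_MASS = 1.00727646

#: Average spacing between aggregated isotopic peaks (Da), the C13-C12
#: mass difference conventionally used for envelope ladders.
NEUTRON_SPACING = 1.0033548


class ElementalFormula(NamedTuple):
    """Atom counts of a CHNOS molecule or ion (neutral composition)."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":  # type: ignore[override]
        return ElementalFormula(*(a + b for a, b in zip(self, other)))

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(*(a - b for a, b in zip(self, other)))

    def scaled(self, k: int) -> "ElementalFormula":
        return ElementalFormula(*(k * a for a in self))

    @property
    def monoisotopic_mass(self) -> float:
        return sum(n * MONOISOTOPIC_MASS[el] for el, n in zip(_ELEMENTS, self))

    def is_valid(self) -> bool:
        return all(n >= 0 for n in self) and any(n > 0 for n in self)


def _abundance_polynomial(element: str) -> np.ndarray:
    isotopes = _ISOTOPES[element]
    deg = max(shift for shift, _, _ in isotopes)
    coeffs = np.zeros(deg + 1)
    for shift, _, abundance in isotopes:
        coeffs[shift] = abundance
    return coeffs


def _inverse_root_power_sums(max_order: int) -> np.ndarray:
    """Power sums of inverse roots of each elemental polynomial.

    Returns an array of shape (max_order, 5): entry [l-1, e] is
    ``sum_j r_{e,j}^{-l}`` over the roots of element e's polynomial.
    """
    out = np.zeros((max_order, len(_ELEMENTS)))
    for col, el in enumerate(_ELEMENTS):
        coeffs = _abundance_polynomial(el)
        roots = np.roots(coeffs[::-1])  # np.roots wants descending order
        inv = 1.0 / roots
        acc = np.ones_like(inv)
        for l in range(max_order):
            acc = acc * inv
            out[l, col] = np.sum(acc).real
    return out


_PSI_CACHE: dict[int, np.ndarray] = {}


def _psi(max_order: int) -> np.ndarray:
    if max_order not in _PSI_CACHE:
        _PSI_CACHE[max_order] = _inverse_root_power_sums(max_order)
    return _PSI_CACHE[max_order]


def max_isotope_shift(formula: ElementalFormula) -> int:
    """Largest nominal mass shift of the full aggregated distribution."""
    return sum(
        n * max(s for s, _, _ in _ISOTOPES[el]) for el, n in zip(_ELEMENTS, formula)
    )


def isotope_distributions(formulas: Sequence[ElementalFormula], n_peaks: int) -> np.ndarray:
    """First ``n_peaks`` aggregated-isotopologue abundances, vectorized.

    Returns an array of shape (len(formulas), n_peaks).  Abundances are
    absolute probabilities (the full distribution sums to 1), not
    renormalized over the truncation.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    counts = np.asarray(formulas, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != len(_ELEMENTS):
        raise ValueError("formulas must be a sequence of 5-element CHNOS counts")
    if np.any(counts < 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("formulas must have non-negative counts and at least one atom")

    log_a0 = np.array(
        [np.log(_abundance_polynomial(el)[0]) for el in _ELEMENTS]
    )
    c = np.zeros((counts.shape[0], n_peaks))
    c[:, 0] = np.exp(counts @ log_a0)
    if n_peaks > 1:
        psi = counts @ _psi(n_peaks - 1).T  # (m, n_peaks-1); psi[:, l-1] = psi_l
        for j in range(1, n_peaks):
            acc = np.zeros(counts.shape[0])
            for l in range(1, j + 1):
                acc += psi[:, l - 1] * c[:, j - l]
            c[:, j] = -acc / j
    return np.clip(c, 0.0, None)


def isotope_distribution(formula: ElementalFormula, n_peaks: int) -> np.ndarray:
    """Aggregated isotopic distribution of one formula (first ``n_peaks``)."""
    formula = ElementalFormula(*formula)
    if not formula.is_valid():
        raise ValueError(f"invalid elemental formula: {formula}")
    return isotope_distributions([formula], n_peaks)[0]


def js_divergence(p: Iterable[float], q: Iterable[float]) -> float:
    """Jensen-Shannon divergence with base-2 logarithm, bounded in [0, 1].

    Inputs are renormalized to sum 1 before comparison.
    """
    p = np.asarray(list(p), dtype=float)
    q = np.asarray(list(q), dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("zero-sum distribution")
    # scipy returns the JS *distance* (sqrt of the divergence); identical
    # inputs can produce a tiny negative radicand from rounding
    with np.errstate(invalid="ignore"):
        d = jensenshannon(p, q, base=2.0)
    return float(np.nan_to_num(d, nan=0.0) ** 2)


def js_similarity(p: Iterable[float], q: Iterable[float]) -> float:
    """Similarity score 1 - JS divergence, in [0, 1]."""
    return 1.0 - js_divergence(p, q)


@dataclass
class IntensityModel:
    """Polynomial curves mapping neutral mass -> isotope-peak fractions.

    One degree-``degree`` polynomial per isotopic peak index (1st..n-th),
    fitted by least squares against neutral monoisotopic mass.  Masses are
    rescaled by 1/1000 before fitting for conditioning.  Predictions are
    clipped to [0, 1]; the model is defined only inside ``mass_lo`` ..
    ``mass_hi`` and callers should fall back to exact distributions
    outside it.
    """

    coeffs: np.ndarray  # shape (n_peaks, degree + 1), np.polyval order
    mass_lo: float
    mass_hi: float
    degree: int
    r_squared: np.ndarray  # per-curve goodness of fit
    n_samples: int
    fitted_masses: np.ndarray = field(repr=False, default=None)

    @property
    def n_peaks(self) -> int:
        return self.coeffs.shape[0]

    @property
    def mean_r_squared(self) -> float:
        return float(np.mean(self.r_squared))

    def in_range(self, mass: float) -> bool:
        return self.mass_lo <= mass <= self.mass_hi

    def predict(self, mass: float) -> np.ndarray:
        """Predicted fractions of the first ``n_peaks`` isotopic peaks."""
        x = mass / 1000.0
        vals = np.array([np.polyval(c, x) for c in self.coeffs])
        return np.clip(vals, 0.0, 1.0)


def fit_intensity_model(
    mass_lo: float = 200.0,
    mass_hi: float = 4000.0,
    n_samples: int = 70,
    degree: int = 4,
    seed: int | None = None,
    n_peaks: int = 5,
    rules=None,
) -> IntensityModel:
    """Fit the isotope-intensity model on enumerated GAG compositions.

    Compositions in [mass_lo, mass_hi] are enumerated under the chain
    rules, ``n_samples`` of them are sampled evenly by mass (stratified
    over equal-width mass bins; one draw per non-empty bin, topped up at
    random), and each sample's first ``n_peaks`` aggregated isotope
    abundances (renormalized to sum 1) are fitted per peak index by one
    polynomial of the given degree.
    """
    from . import compositions as _comp

    if n_samples < degree + 1:
        raise ValueError("n_samples must exceed the polynomial degree")
    universe = _comp.enumerate_by_mass(mass_lo, mass_hi, rules=rules)
    if len(universe) < n_samples:
        raise ValueError(
            f"only {len(universe)} compositions in [{mass_lo}, {mass_hi}]; "
            f"need at least {n_samples}"
        )
    masses = np.array([_comp.neutral_mass(c) for c in universe])
    rng = np.random.default_rng(seed)

    # stratified even-by-mass sampling: one composition per occupied bin
    edges = np.linspace(mass_lo, mass_hi, n_samples + 1)
    order = np.argsort(masses)
    chosen: list[int] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = order[(masses[order] >= lo) & (masses[order] < hi)]
        if members.size:
            chosen.append(int(rng.choice(members)))
    remaining = np.setdiff1d(np.arange(len(universe)), chosen)
    if len(chosen) < n_samples and remaining.size:
        extra = rng.choice(remaining, size=min(n_samples - len(chosen), remaining.size), replace=False)
        chosen.extend(int(i) for i in extra)
    chosen = sorted(chosen)

    sample_masses = masses[chosen]
    formulas = [_comp.formula_of(universe[i]) for i in chosen]
    dists = isotope_distributions(formulas, n_peaks)
    dists = dists / dists.sum(axis=1, keepdims=True)

    x = sample_masses / 1000.0
    coeffs = np.empty((n_peaks, degree + 1))
    r2 = np.empty(n_peaks)
    for k in range(n_peaks):
        y = dists[:, k]
        coeffs[k] = np.polyfit(x, y, degree)
        resid = y - np.polyval(coeffs[k], x)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2[k] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return IntensityModel(
        coeffs=coeffs,
        mass_lo=mass_lo,
        mass_hi=mass_hi,
        degree=degree,
        r_squared=r2,
        n_samples=len(chosen),
        fitted_masses=sample_masses,
    )
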