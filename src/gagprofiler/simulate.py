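"""Ground-truth synthetic spectra for testing the full pipeline.

The generator emits what the annotation problem actually has to cope
with: multi-charge isotope envelopes of known GAG compositions (with
BRAIN-exact intensities), loss-derived satellite envelopes, uniform
random noise peaks with log-uniform intensities, instrumental noise (one
exact intensity value repeated many times), a constant m/z shift, and
optional over-segmentation of every peak into a rise-then-fall group of
sub-peaks that conserves intensity and centroid.

It does not emulate chromatographic elution, detector saturation, or
overlapping-envelope interference beyond what random placement produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .compositions import (
    NO_LOSS,
    Composition,
    LossVector,
    formula_of,
    ion_mz,
    valid_losses,
)
from .isotopes import NEUTRON_SPACING, isotope_distribution
from .spectrum_io import Spectrum, write_mzml

__all__ = ["FixtureSpec", "generate_spectrum", "end_to_end_truth"]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic spectrum with known ground truth."""

    components: list[tuple[Composition, float]]
    charges: Sequence[int] = (2, 3)
    losses: list[LossVector] = field(default_factory=list)
    loss_intensity_factor: float = 0.3
    emit_intact: bool = True
    n_isotopes: int = 5
    noise_peak_count: int = 0
    noise_intensity_range: tuple[float, float] = (600.0, 50_000.0)
    repeated_noise_intensity: float | None = None
    repeated_noise_count: int = 0
    mz_shift: float = 0.0
    oversegment: bool = False
    seed: int = 0
    mz_window_pad: float = 20.0

    def charges_for(self, index: int) -> Sequence[int]:
        if self.charges and isinstance(self.charges[0], (list, tuple)):
            return self.charges[index]
        return self.charges


def _oversegment(
    mzs: np.ndarray, intensities: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Split each peak into 2-4 sub-peaks forming a rise-then-fall group
    within +-0.003 Th, conserving total intensity and centroid."""
    out_mz: list[float] = []
    out_int: list[float] = []
    for mz, inten in zip(mzs, intensities):
        k = int(rng.integers(2, 5))
        offsets = np.sort(rng.uniform(-0.003, 0.003, size=k))
        weights = rng.dirichlet(np.ones(k))
        # arrange weights unimodally: smallest at the edges
        order = np.argsort(weights)
        left: list[float] = []
        right: list[float] = []
        for pos, idx in enumerate(order):
            (left if pos % 2 == 0 else right).append(weights[idx])
        arranged = np.array(left + right[::-1])
        offsets = offsets - float(np.sum(arranged * offsets))  # keep centroid
        out_mz.extend(mz + offsets)
        out_int.extend(inten * arranged)
    return np.array(out_mz), np.array(out_int)


def generate_spectrum(spec: FixtureSpec, mzml_path=None) -> Spectrum:
    """Generate the spectrum described by ``spec`` (optionally writing mzML).

    Identical specs (same seed) produce identical spectra.
    """
    rng = np.random.default_rng(spec.seed)
    mzs: list[float] = []
    intensities: list[float] = []
    for index, (comp, abundance) in enumerate(spec.components):
        comp = Composition(*comp)
        if abundance <= 0:
            raise ValueError("component abundances must be positive")
        available = set(valid_losses(comp, max_losses=4))
        emit = [(NO_LOSS, 1.0)] if spec.emit_intact else []
        if not spec.emit_intact and not spec.losses:
            raise ValueError("emit_intact=False requires at least one loss")
        for loss in spec.losses:
            loss = LossVector(*loss)
            if loss not in available:
                raise ValueError(f"loss {loss} not available for {comp}")
            emit.append((loss, spec.loss_intensity_factor))
        for loss, factor in emit:
            formula = formula_of(comp, loss)
            dist = isotope_distribution(formula, spec.n_isotopes)
            neutral = formula.monoisotopic_mass
            for z in spec.charges_for(index):
                mono = ion_mz(neutral, z)
                ladder = mono + np.arange(spec.n_isotopes) * NEUTRON_SPACING / z
                mzs.extend(ladder)
                intensities.extend(abundance * factor * dist)
    signal_mz = np.array(mzs)
    signal_int = np.array(intensities)

    if signal_mz.size:
        lo = signal_mz.min() - spec.mz_window_pad
        hi = signal_mz.max() + spec.mz_window_pad
    else:
        lo, hi = 200.0, 1200.0
    lo = max(lo, 50.0)

    noise_mz = rng.uniform(lo, hi, size=spec.noise_peak_count)
    nlo, nhi = spec.noise_intensity_range
    noise_int = np.exp(rng.uniform(np.log(nlo), np.log(nhi), size=spec.noise_peak_count))

    rep_mz = np.empty(0)
    rep_int = np.empty(0)
    if spec.repeated_noise_intensity is not None and spec.repeated_noise_count > 0:
        rep_mz = rng.uniform(lo, hi, size=spec.repeated_noise_count)
        rep_int = np.full(spec.repeated_noise_count, float(spec.repeated_noise_intensity))

    all_mz = np.concatenate([signal_mz, noise_mz, rep_mz])
    all_int = np.concatenate([signal_int, noise_int, rep_int])
    if spec.oversegment:
        all_mz, all_int = _oversegment(all_mz, all_int, rng)
    all_mz = all_mz + spec.mz_shift

    spectrum = Spectrum(mz=all_mz, intensity=all_int, scan_id="scan=1")
    if mzml_path is not None:
        write_mzml([spectrum], mzml_path)
    return spectrum


def end_to_end_truth(spec: FixtureSpec) -> list[Composition]:
    """The generating component set, as the expected pipeline selection."""
    return sorted({Composition(*comp) for comp, _ in spec.components})
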