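"""Spectrum preprocessing: peak merging, denoising, and m/z calibration.

Conversion of profile data to centroids can over-segment a single peak
into several close sub-peaks, shifting the apparent peak center and
inflating spurious matches.  ``merge_peaks`` undoes this by grouping
adjacent peaks into rise-then-fall intensity runs and collapsing each run
to its intensity-weighted centroid.

``denoise`` removes instrumental noise (one exact intensity value
repeated many times across the spectrum) and low peaks (absolute and
relative thresholds).  ``calibrate`` estimates a constant additive m/z
shift from the five most intense peaks pre-matched against the
theoretical ion index and applies it to the whole spectrum.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .spectrum_io import Spectrum

__all__ = ["CalibrationResult", "merge_peaks", "denoise", "calibrate"]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationResult:
    """Outcome of constant-offset m/z calibration.

    ``shift`` is the signed additive offset (Th) applied to all peaks;
    ``residuals`` are the signed theoretical-minus-observed differences of
    the anchor peaks that pre-matched.
    """

    shift: float
    n_anchor_peaks: int
    residuals: list[float] = field(default_factory=list)


def merge_peaks(spectrum: Spectrum, max_gap: float = 0.01) -> Spectrum:
    """Merge over-segmented peaks into rise-then-fall groups.

    Scanning by ascending m/z, a group accumulates while intensity first
    rises and then falls; a new group starts whenever intensity rises
    again after having fallen (the local minimum closes the previous
    group) or the spacing to the previous peak exceeds ``max_gap``.  Each
    group becomes one peak at the intensity-weighted centroid m/z with
    the summed intensity, so total intensity is conserved exactly.
    """
    n = len(spectrum)
    if n <= 1:
        return spectrum
    mz, inten = spectrum.mz, spectrum.intensity
    group_id = np.zeros(n, dtype=int)
    gid = 0
    falling = False
    for i in range(1, n):
        if mz[i] - mz[i - 1] > max_gap or (falling and inten[i] > inten[i - 1]):
            gid += 1
            falling = False
        elif inten[i] < inten[i - 1]:
            falling = True
        group_id[i] = gid
    n_groups = gid + 1
    sums = np.zeros(n_groups)
    weighted = np.zeros(n_groups)
    np.add.at(sums, group_id, inten)
    np.add.at(weighted, group_id, inten * mz)
    # an all-zero-intensity group keeps its plain mean m/z
    counts = np.bincount(group_id, minlength=n_groups)
    plain = np.zeros(n_groups)
    np.add.at(plain, group_id, mz)
    with np.errstate(invalid="ignore", divide="ignore"):
        centroids = np.where(sums > 0, weighted / np.where(sums > 0, sums, 1.0), plain / counts)
    return spectrum.replace_peaks(centroids, sums)


def denoise(
    spectrum: Spectrum,
    abs_threshold: float = 500.0,
    rel_threshold: float = 0.001,
    repeat_count: int = 1000,
) -> Spectrum:
    """Remove instrumental and low-intensity noise peaks.

    Removes (a) every peak whose exact intensity value occurs at least
    ``repeat_count`` times in the spectrum (instrumental noise), then,
    against the maximum of the remaining peaks (relative intensity of the
    highest peak = 1), (b) peaks below ``abs_threshold`` counts and (c)
    peaks below ``rel_threshold`` relative intensity.
    """
    if not len(spectrum):
        return spectrum
    inten = spectrum.intensity
    freq = Counter(inten.tolist())
    repeated = np.array([freq[v] >= repeat_count for v in inten.tolist()])
    keep = ~repeated
    if not keep.any():
        return spectrum.replace_peaks(spectrum.mz[keep], inten[keep])
    base = inten[keep].max()
    keep &= inten >= abs_threshold
    keep &= inten / base >= rel_threshold
    return spectrum.replace_peaks(spectrum.mz[keep], spectrum.intensity[keep])


def calibrate(
    spectrum: Spectrum,
    ion_index: np.ndarray,
    prematch_window: float = 0.05,
    n_anchors: int = 5,
    consensus_window: float = 0.002,
) -> tuple[Spectrum, CalibrationResult]:
    """Constant-offset m/z calibration against the theoretical ion index.

    The ``n_anchors`` most intense peaks are pre-matched against the ion
    index: every theoretical m/z within ``prematch_window`` of an anchor
    yields a candidate signed difference (theoretical minus observed).
    Because a candidate ion can sit near an anchor by coincidence, the
    shift is not the plain nearest-match median: the candidate difference
    supported by the largest number of anchors (each contributing its
    closest difference within ``consensus_window``) wins, and the shift
    minimizing the sum of absolute differences over that consensus set is
    its median.  With no anchor match the spectrum is returned unchanged
    (shift 0).
    """
    ion_index = np.sort(np.asarray(ion_index, dtype=float))
    if ion_index.size == 0:
        raise ValueError("ion index is empty")
    if not len(spectrum):
        return spectrum, CalibrationResult(shift=0.0, n_anchor_peaks=0)
    top = np.argsort(spectrum.intensity)[::-1][:n_anchors]
    per_anchor: list[np.ndarray] = []
    for i in top:
        mz = spectrum.mz[i]
        lo = np.searchsorted(ion_index, mz - prematch_window)
        hi = np.searchsorted(ion_index, mz + prematch_window)
        if hi > lo:
            per_anchor.append(ion_index[lo:hi] - mz)
    if not per_anchor:
        logger.warning("calibration: no anchor peak pre-matched; shift set to 0")
        return spectrum, CalibrationResult(shift=0.0, n_anchor_peaks=0)

    candidates = np.concatenate(per_anchor)
    best_support: list[float] = []
    best_cost = np.inf
    for d in candidates:
        support = []
        cost = 0.0
        for diffs in per_anchor:
            resid = np.abs(diffs - d)
            j = int(np.argmin(resid))
            if resid[j] <= consensus_window:
                support.append(float(diffs[j]))
                cost += float(resid[j])
        if len(support) > len(best_support) or (
            len(support) == len(best_support) and cost < best_cost
        ):
            best_support, best_cost = support, cost
    shift = float(np.median(best_support))
    calibrated = spectrum.replace_peaks(spectrum.mz + shift, spectrum.intensity)
    return calibrated, CalibrationResult(
        shift=shift, n_anchor_peaks=len(best_support), residuals=best_support
    )
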