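"""End-to-end profiling pipeline.

read -> merge -> denoise -> calibrate -> extract clusters -> filter ->
enumerate compositions -> expand ions -> match -> score -> greedy select
-> significance -> export.

The theoretical ion space is held in an :class:`IonIndex` (sorted
monoisotopic m/z arrays per charge state with vectorized BRAIN
distributions), so matching a few dozen experimental clusters against
hundreds of thousands of candidate ions is a handful of binary searches
per cluster rather than a quadratic scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import preprocess
from .clusters import IsotopicCluster, extract_candidates, filter_clusters
from .compositions import (
    Composition,
    CompositionRules,
    LossVector,
    TheoreticalIon,
    formula_of,
    valid_losses,
)
from .isotopes import (
    NEUTRON_SPACING,
    PROTON_MASS,
    IntensityModel,
    fit_intensity_model,
    isotope_distributions,
    js_divergence,
)
from .scoring import (
    ClusterMatch,
    ComponentResult,
    Selection,
    greedy_select,
    group_matches_by_composition,
)
from .significance import SignificanceResult, assess_components
from .spectrum_io import (
    Spectrum,
    write_profile_table,
    write_report_json,
)

__all__ = ["PipelineConfig", "IonIndex", "run_pipeline", "ProfileReport"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable knobs of the profiling workflow, with field defaults."""

    # preprocessing
    merge_max_gap: float = 0.01
    denoise_abs_threshold: float = 500.0
    denoise_rel_threshold: float = 0.001
    denoise_repeat_count: int = 1000
    calibrate_prematch_window: float = 0.05
    # cluster detection
    max_charge: int = 5
    max_peaks: int = 5
    ppm: float = 20.0
    min_similarity: float = 0.9
    min_members: int = 3
    # theoretical ion space
    max_losses: int = 2
    n_isotopes: int = 5
    allow_levoglucosan: bool = True
    allow_anhydromannitol: bool = True
    max_sulfo_per_glcn: int = 3
    # scoring / selection
    alpha: float = 0.99
    beta_derived: float = 0.9
    # significance
    reliable_threshold: float = 3.0
    # intensity model
    model_mass_lo: float = 200.0
    model_mass_hi: float = 4000.0
    model_n_samples: int = 70
    model_degree: int = 4
    model_seed: int = 0

    def rules(self) -> CompositionRules:
        return CompositionRules(
            allow_levoglucosan=self.allow_levoglucosan,
            allow_anhydromannitol=self.allow_anhydromannitol,
            max_sulfo_per_glcn=self.max_sulfo_per_glcn,
        )


class IonIndex:
    """Sorted per-charge index over all theoretical ions of a candidate set."""

    def __init__(
        self,
        compositions: list[Composition],
        max_charge: int = 5,
        max_losses: int = 2,
        n_isotopes: int = 5,
    ):
        self.n_isotopes = n_isotopes
        self.pairs: list[tuple[Composition, LossVector]] = [
            (comp, loss)
            for comp in compositions
            for loss in valid_losses(comp, max_losses)
        ]
        if self.pairs:
            formulas = [formula_of(c, l) for c, l in self.pairs]
            self.neutral = np.array([f.monoisotopic_mass for f in formulas])
            self.dists = isotope_distributions(formulas, n_isotopes)
        else:
            self.neutral = np.empty(0)
            self.dists = np.empty((0, n_isotopes))
        self._by_charge: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for z in range(1, max_charge + 1):
            ok = self.neutral > z * PROTON_MASS
            mono = (self.neutral[ok] - z * PROTON_MASS) / z
            idx = np.nonzero(ok)[0]
            order = np.argsort(mono)
            self._by_charge[z] = (mono[order], idx[order])

    def __len__(self) -> int:
        return sum(v[0].size for v in self._by_charge.values())

    @property
    def charges(self) -> list[int]:
        return sorted(self._by_charge)

    def all_mono_mzs(self) -> np.ndarray:
        if not self._by_charge:
            return np.empty(0)
        return np.concatenate([v[0] for v in self._by_charge.values()])

    def intact_mono_mzs(self) -> np.ndarray:
        """Monoisotopic m/z of loss-free ions only (calibration anchors).

        Loss derivatives replicate their parent's ladder at a constant
        mass offset and only densify the index, so calibration pre-matches
        against intact components.
        """
        intact = np.array(
            [loss.total == 0 for _, loss in self.pairs], dtype=bool
        )
        out = []
        for z, (mono, idx) in self._by_charge.items():
            out.append(mono[intact[idx]])
        return np.concatenate(out) if out else np.empty(0)

    def make_ion(self, pair_index: int, charge: int) -> TheoreticalIon:
        comp, loss = self.pairs[pair_index]
        neutral = self.neutral[pair_index]
        mono = (neutral - charge * PROTON_MASS) / charge
        ladder = mono + np.arange(self.n_isotopes) * NEUTRON_SPACING / charge
        return TheoreticalIon(
            composition=comp,
            loss=loss,
            charge=charge,
            mono_mz=mono,
            isotope_mzs=ladder,
            distribution=self.dists[pair_index],
        )

    def query(self, mz: float, charge: int, ppm: float) -> list[tuple[int, int]]:
        """(pair_index, isotope_offset) of ions whose k-th isotopic peak
        lies within ppm of ``mz``; smallest offset per pair."""
        if charge not in self._by_charge:
            return []
        mono, idx = self._by_charge[charge]
        hits: dict[int, int] = {}
        spacing = NEUTRON_SPACING / charge
        tol = ppm * 1e-6 * mz
        for k in range(self.n_isotopes):
            target = mz - k * spacing
            lo = np.searchsorted(mono, target - tol)
            hi = np.searchsorted(mono, target + tol)
            for j in range(lo, hi):
                pair = int(idx[j])
                if pair not in hits:
                    hits[pair] = k
        return sorted(hits.items())

    def pair_indices_of(self, composition: Composition) -> list[int]:
        return [i for i, (c, _) in enumerate(self.pairs) if c == composition]

    def theoretical_peaks(
        self, composition: Composition, range_lo: float, range_hi: float
    ) -> np.ndarray:
        """All isotope-peak m/z of a component's ions inside the range."""
        out = []
        for i in self.pair_indices_of(composition):
            neutral = self.neutral[i]
            for z in self.charges:
                if neutral <= z * PROTON_MASS:
                    continue
                mono = (neutral - z * PROTON_MASS) / z
                ladder = mono + np.arange(self.n_isotopes) * NEUTRON_SPACING / z
                out.append(ladder[(ladder >= range_lo) & (ladder <= range_hi)])
        if not out:
            return np.empty(0)
        return np.concatenate(out)


def _match_against_index(
    index: IonIndex,
    clusters: list[IsotopicCluster],
    ppm: float,
    base_intensity: float,
    beta_derived: float,
) -> list[ClusterMatch]:
    import math

    matches: list[ClusterMatch] = []
    for cluster in clusters:
        for pair_index, k in index.query(cluster.mono_mz, cluster.charge, ppm):
            ion = index.make_ion(pair_index, cluster.charge)
            theo = ion.distribution[k:]
            n = min(len(theo), len(cluster))
            if n < 1 or theo[:n].sum() <= 0:
                continue
            js = js_divergence(cluster.distribution[:n], theo[:n])
            beta = beta_derived if ion.is_derived else 1.0
            rel = cluster.total_intensity / base_intensity
            matches.append(
                ClusterMatch(
                    cluster=cluster,
                    ion=ion,
                    isotope_order=k + 1,
                    js=js,
                    contribution=beta * math.log(rel + 1.0) * (1.0 - js),
                )
            )
    return matches


@dataclass
class ProfileReport:
    """Everything the pipeline produced for one spectrum."""

    config: PipelineConfig
    calibration: preprocess.CalibrationResult
    stage_counts: dict[str, int]
    candidates: list[ComponentResult]
    significance: dict[Composition, SignificanceResult]
    selection: Selection

    def selected_rows(self) -> list[ClusterMatch]:
        rows: list[ClusterMatch] = []
        for comp in self.selection.selected:
            rows.extend(comp.matches)
        rows.sort(key=lambda m: (m.mz, tuple(m.composition), tuple(m.loss)))
        return rows

    def reliable_components(self) -> list[Composition]:
        return [
            comp
            for comp, sig in self.significance.items()
            if sig.reliable and comp in {c.composition for c in self.selection.selected}
        ]

    def to_json_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "calibration": {
                "shift": self.calibration.shift,
                "n_anchor_peaks": self.calibration.n_anchor_peaks,
                "residuals": self.calibration.residuals,
            },
            "stage_counts": self.stage_counts,
            "selection": {
                "compositions": [list(c) for c in self.selection.compositions],
                "global_score": self.selection.global_score,
                "n_explained_clusters": len(self.selection.explained),
            },
            "components": [
                {
                    "composition": list(res.composition),
                    "score": res.score,
                    "n_matches": len(res.matches),
                    "selected": res.composition in set(self.selection.compositions),
                    "p_value": self.significance[res.composition].p_value,
                    "p_adj": self.significance[res.composition].p_adj,
                    "neg_log10_padj": self.significance[res.composition].neg_log10_padj,
                    "reliable": self.significance[res.composition].reliable,
                }
                for res in self.candidates
            ],
            "rows": [
                {
                    "mz": row.mz,
                    "charge": row.charge,
                    "isotope_order": row.isotope_order,
                    "composition": list(row.composition),
                    "loss": list(row.loss),
                }
                for row in self.selected_rows()
            ],
        }


def run_pipeline(
    spectrum: Spectrum,
    config: PipelineConfig | None = None,
    output_dir: str | Path | None = None,
    component: Composition | None = None,
    model: IntensityModel | None = None,
) -> ProfileReport:
    """Run the full profiling workflow on one spectrum.

    ``component`` restricts the candidate space to a single composition
    (single-component annotation mode).  A prefitted intensity ``model``
    may be supplied to skip refitting.  When ``output_dir`` is given the
    Table-style CSV and the JSON report are written there.
    """
    from .compositions import enumerate_compositions

    config = config or PipelineConfig()
    counts: dict[str, int] = {"input_peaks": len(spectrum)}

    merged = preprocess.merge_peaks(spectrum, config.merge_max_gap)
    counts["merged_peaks"] = len(merged)
    clean = preprocess.denoise(
        merged,
        abs_threshold=config.denoise_abs_threshold,
        rel_threshold=config.denoise_rel_threshold,
        repeat_count=config.denoise_repeat_count,
    )
    counts["denoised_peaks"] = len(clean)

    if not len(clean):
        logger.info("pipeline: spectrum empty after preprocessing")
        empty = ProfileReport(
            config=config,
            calibration=preprocess.CalibrationResult(shift=0.0, n_anchor_peaks=0),
            stage_counts=counts,
            candidates=[],
            significance={},
            selection=Selection(),
        )
        if output_dir is not None:
            _write_outputs(empty, output_dir)
        return empty

    lo, hi = clean.mz_range()
    if component is not None:
        comps = [Composition(*component)]
    else:
        comps = enumerate_compositions(
            lo - 1.0,
            hi + 1.0,
            max_charge=config.max_charge,
            rules=config.rules(),
            max_losses=config.max_losses,
        )
    counts["candidate_compositions"] = len(comps)
    index = IonIndex(
        comps,
        max_charge=config.max_charge,
        max_losses=config.max_losses,
        n_isotopes=config.n_isotopes,
    )
    counts["theoretical_ions"] = len(index)

    calibrated, calibration = preprocess.calibrate(
        clean,
        index.intact_mono_mzs(),
        prematch_window=config.calibrate_prematch_window,
    )
    candidates = extract_candidates(
        calibrated,
        max_charge=config.max_charge,
        max_peaks=config.max_peaks,
        ppm=config.ppm,
        min_members=config.min_members,
    )
    counts["cluster_candidates"] = len(candidates)

    if model is None:
        model = fit_intensity_model(
            config.model_mass_lo,
            config.model_mass_hi,
            n_samples=config.model_n_samples,
            degree=config.model_degree,
            seed=config.model_seed,
            rules=config.rules(),
        )
    reliable_clusters = filter_clusters(candidates, model, config.min_similarity)
    counts["reliable_clusters"] = len(reliable_clusters)

    matches = _match_against_index(
        index,
        reliable_clusters,
        ppm=config.ppm,
        base_intensity=calibrated.base_intensity,
        beta_derived=config.beta_derived,
    )
    counts["cluster_matches"] = len(matches)
    scored = group_matches_by_composition(matches)
    selection = greedy_select(scored, alpha=config.alpha)
    counts["selected_components"] = len(selection.selected)

    significance = _significance_of(scored, index, calibrated, config)

    report = ProfileReport(
        config=config,
        calibration=calibration,
        stage_counts=counts,
        candidates=scored,
        significance=significance,
        selection=selection,
    )
    for stage, value in counts.items():
        logger.info("pipeline: %s = %d", stage, value)
    if output_dir is not None:
        _write_outputs(report, output_dir)
    return report


def _significance_of(
    scored: list[ComponentResult],
    index: IonIndex,
    spectrum: Spectrum,
    config: PipelineConfig,
) -> dict[Composition, SignificanceResult]:
    from .significance import random_match_prob

    if not scored:
        return {}
    lo, hi = spectrum.mz_range()
    per_component: list[tuple[int, int]] = []
    p_randoms: list[float] = []
    for res in scored:
        theo = index.theoretical_peaks(res.composition, lo, hi)
        matched: set[tuple] = set()
        for m in res.matches:
            for step in range(len(m.cluster)):
                iso = m.isotope_order - 1 + step
                if iso < config.n_isotopes:
                    matched.add((tuple(m.loss), m.charge, iso))
        n = int(theo.size)
        k = min(len(matched), n)
        per_component.append((n, k))
        if hi > lo:
            p_randoms.append(random_match_prob(theo, config.ppm, lo, hi))
        else:
            p_randoms.append(0.0)
    results = assess_components(per_component, p_randoms)
    return {res.composition: sig for res, sig in zip(scored, results)}


def _write_outputs(report: ProfileReport, output_dir: str | Path) -> None:
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    write_profile_table(report.selected_rows(), output_dir / "profile.csv")
    write_report_json(report.to_json_dict(), output_dir / "report.json")
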