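"""Component scoring and greedy spectrum-explanation selection.

Each candidate component is scored by summing, over its matched
(experimental cluster, theoretical ion) pairs,

    Sc = sum  beta * ln(I_pe + 1) * (1 - JS(pe, pt))

where I_pe is the cluster's total relative intensity (highest spectrum
peak = 1), JS the Jensen-Shannon divergence between the cluster's and
ion's aligned intensity distributions, and beta a down-weight (default
0.9) for loss-derived ions.

Selection is greedy set-cover style: the next component is the one with
the largest marginal score over still-unexplained clusters, and the
global score of a selection of n components is alpha**n times the summed
first-explanation contributions; the returned selection is the greedy
prefix maximizing that global score (alpha < 1 penalizes large
selections).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clusters import IsotopicCluster
from .compositions import Composition, LossVector, TheoreticalIon
from .isotopes import js_divergence

__all__ = [
    "ClusterMatch",
    "ComponentResult",
    "Selection",
    "match_clusters",
    "score_component",
    "greedy_select",
    "group_matches_by_composition",
]

BETA_DERIVED = 0.9


@dataclass
class ClusterMatch:
    """One experimental cluster explained by one theoretical ion.

    ``isotope_order`` is 1-based: order k means the experimental
    monoisotopic peak sits on the k-th isotopic peak of the theoretical
    envelope (weak monoisotopic peaks of larger ions can fall below the
    detection floor, so the observed run may start mid-envelope).
    """

    cluster: IsotopicCluster
    ion: TheoreticalIon
    isotope_order: int
    js: float
    contribution: float

    @property
    def composition(self) -> Composition:
        return self.ion.composition

    @property
    def loss(self) -> LossVector:
        return self.ion.loss

    @property
    def charge(self) -> int:
        return self.ion.charge

    @property
    def mz(self) -> float:
        return self.cluster.mono_mz


@dataclass
class ComponentResult:
    """All matches of one candidate composition, with its score Sc."""

    composition: Composition
    matches: list[ClusterMatch]

    @property
    def score(self) -> float:
        return float(sum(m.contribution for m in self.matches))


@dataclass
class Selection:
    """Greedily selected component set explaining the spectrum."""

    selected: list[ComponentResult] = field(default_factory=list)
    gains: list[float] = field(default_factory=list)
    global_score: float = 0.0
    explained: set[int] = field(default_factory=set)

    @property
    def compositions(self) -> list[Composition]:
        return [c.composition for c in self.selected]


def _cluster_key(cluster: IsotopicCluster) -> int:
    return cluster.cluster_id if cluster.cluster_id >= 0 else id(cluster)


def _peak_keys(cluster: IsotopicCluster) -> set[float]:
    return set(float(m) for m in cluster.mzs)


def _is_explained(cluster: IsotopicCluster, explained_peaks: set[float]) -> bool:
    """A cluster is explained once all its member peaks are explained.

    Candidates at different charge states can share member peaks (the
    alternating peaks of a z=2 envelope also form a valid z=1 ladder);
    tracking explanation at the peak level keeps such shadow clusters
    from rewarding spurious components after the true component has
    claimed the peaks.
    """
    return all(float(m) in explained_peaks for m in cluster.mzs)


def match_clusters(
    ions: list[TheoreticalIon],
    clusters: list[IsotopicCluster],
    ppm: float = 20.0,
    base_intensity: float = 1.0,
    beta_derived: float = BETA_DERIVED,
) -> list[ClusterMatch]:
    """Pair theoretical ions with experimental clusters of equal charge.

    A pair matches if the cluster's monoisotopic m/z lands within ppm on
    the ion's k-th isotopic peak for some offset k >= 0 (smallest k
    wins); the ion's distribution is aligned at that offset before
    computing JS.  ``base_intensity`` converts raw cluster intensities to
    the relative scale used in the score.
    """
    out: list[ClusterMatch] = []
    for ion in ions:
        for cluster in clusters:
            if cluster.charge != ion.charge:
                continue
            match_k = None
            for k in range(len(ion.isotope_mzs)):
                expected = ion.isotope_mzs[k]
                if abs(cluster.mono_mz - expected) <= ppm * 1e-6 * expected:
                    match_k = k
                    break
            if match_k is None:
                continue
            theo = ion.distribution[match_k:]
            n = min(len(theo), len(cluster))
            if n < 1 or theo[:n].sum() <= 0:
                continue
            js = js_divergence(cluster.distribution[:n], theo[:n])
            beta = beta_derived if ion.is_derived else 1.0
            rel_intensity = cluster.total_intensity / base_intensity
            contribution = beta * math.log(rel_intensity + 1.0) * (1.0 - js)
            out.append(
                ClusterMatch(
                    cluster=cluster,
                    ion=ion,
                    isotope_order=match_k + 1,
                    js=js,
                    contribution=contribution,
                )
            )
    return out


def group_matches_by_composition(matches: list[ClusterMatch]) -> list[ComponentResult]:
    """Bundle matches into one ComponentResult per composition."""
    by_comp: dict[Composition, list[ClusterMatch]] = {}
    for m in matches:
        by_comp.setdefault(m.composition, []).append(m)
    return [
        ComponentResult(composition=comp, matches=ms)
        for comp, ms in sorted(by_comp.items())
    ]


def score_component(matches: list[ClusterMatch]) -> ComponentResult:
    """Score one component from its matches (Sc = sum of contributions)."""
    if not matches:
        return ComponentResult(composition=Composition(), matches=[])
    comps = {m.composition for m in matches}
    if len(comps) > 1:
        raise ValueError("matches reference more than one composition")
    return ComponentResult(composition=comps.pop(), matches=list(matches))


def _marginal_gain(candidate: ComponentResult, explained_peaks: set[float]) -> float:
    return float(
        sum(
            m.contribution
            for m in candidate.matches
            if not _is_explained(m.cluster, explained_peaks)
        )
    )


def greedy_select(candidates: list[ComponentResult], alpha: float = 0.99) -> Selection:
    """Greedy selection maximizing the alpha-penalized global score.

    Components are added in order of marginal contribution over
    still-unexplained clusters (ties broken by lexicographically smaller
    composition); the greedy sequence stops when no candidate has
    positive marginal gain, and the returned selection is the prefix with
    the highest global score alpha**n * sum(gains).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    remaining = list(candidates)
    explained_peaks: set[float] = set()
    sequence: list[ComponentResult] = []
    gains: list[float] = []
    while remaining:
        best = None
        best_gain = 0.0
        for cand in remaining:
            gain = _marginal_gain(cand, explained_peaks)
            if gain > best_gain or (
                best is not None
                and gain == best_gain
                and gain > 0.0
                and tuple(cand.composition) < tuple(best.composition)
            ):
                best, best_gain = cand, gain
        if best is None or best_gain <= 0.0:
            break
        sequence.append(best)
        gains.append(best_gain)
        remaining.remove(best)
        for m in best.matches:
            explained_peaks |= _peak_keys(m.cluster)
    if not sequence:
        return Selection()
    cumulative = np.cumsum(gains)
    sg = np.array([alpha**n * cumulative[n - 1] for n in range(1, len(gains) + 1)])
    n_best = int(np.argmax(sg)) + 1
    chosen = sequence[:n_best]
    explained_best: set[int] = set()
    for cand in chosen:
        explained_best |= {_cluster_key(m.cluster) for m in cand.matches}
    return Selection(
        selected=chosen,
        gains=gains[:n_best],
        global_score=float(sg[n_best - 1]),
        explained=explained_best,
    )
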