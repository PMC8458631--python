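import itertools
import math

import numpy as np
import pytest

from gagprofiler import Composition, LossVector, greedy_select, match_clusters, score_component
from gagprofiler.clusters import IsotopicCluster
from gagprofiler.compositions import TheoreticalIon, expand_ions
from gagprofiler.scoring import ClusterMatch, ComponentResult

PENTA = Composition(1, 1, 2, 0, 5, 0, 0)


def intact_ion(comp, charge):
    return [
        i for i in expand_ions(comp, max_charge=charge, max_losses=0) if i.charge == charge
    ][0]


def cluster_from(ion, start=0, n=5, scale=1.0, cluster_id=-1):
    dist = ion.distribution[start : start + n]
    return IsotopicCluster(
        mzs=ion.isotope_mzs[start : start + n],
        intensities=scale * dist,
        charge=ion.charge,
        cluster_id=cluster_id,
    )


class TestMatching:
    def test_self_match_has_order_1_and_zero_divergence(self):
        ion = intact_ion(PENTA, 3)
        cluster = cluster_from(ion)
        (m,) = match_clusters([ion], [cluster])
        assert m.isotope_order == 1
        assert m.js == pytest.approx(0.0, abs=1e-9)

    def test_cluster_starting_on_third_isotope_matches_with_order_3(self):
        ion = intact_ion(PENTA, 2)
        cluster = cluster_from(ion, start=2, n=3)
        (m,) = match_clusters([ion], [cluster])
        assert m.isotope_order == 3
        assert m.js == pytest.approx(0.0, abs=1e-9)

    def test_charge_mismatch_never_matches(self):
        ion2 = intact_ion(PENTA, 2)
        ion3 = intact_ion(PENTA, 3)
        cluster = cluster_from(ion2)
        assert match_clusters([ion3], [cluster]) == []

    def test_out_of_tolerance_never_matches(self):
        ion = intact_ion(PENTA, 2)
        cluster = cluster_from(ion)
        cluster.mzs = cluster.mzs + 0.1
        assert match_clusters([ion], [cluster]) == []


class TestComponentScore:
    def unit_match(self, contribution=1.0, derived=False, cluster_id=-1):
        ion = intact_ion(PENTA, 2)
        if derived:
            ion = TheoreticalIon(
                composition=ion.composition,
                loss=LossVector(1, 0, 0, 0),
                charge=ion.charge,
                mono_mz=ion.mono_mz,
                isotope_mzs=ion.isotope_mzs,
                distribution=ion.distribution,
            )
        cluster = cluster_from(ion, cluster_id=cluster_id)
        return ClusterMatch(
            cluster=cluster, ion=ion, isotope_order=1, js=0.0, contribution=contribution
        )

    def test_log_intensity_weighting(self):
        ion = intact_ion(PENTA, 2)
        scale = (math.e - 1) / ion.distribution.sum()
        cluster = cluster_from(ion, scale=scale)
        (m,) = match_clusters([ion], [cluster], base_intensity=1.0)
        assert m.contribution == pytest.approx(1.0, abs=1e-6)
        assert score_component([m]).score == pytest.approx(1.0, abs=1e-6)

    def test_derived_ion_down_weighted(self):
        ion = intact_ion(PENTA, 2)
        derived = TheoreticalIon(
            composition=ion.composition,
            loss=LossVector(1, 0, 0, 0),
            charge=ion.charge,
            mono_mz=ion.mono_mz,
            isotope_mzs=ion.isotope_mzs,
            distribution=ion.distribution,
        )
        scale = (math.e - 1) / derived.distribution.sum()
        cluster = cluster_from(derived, scale=scale)
        (m,) = match_clusters([derived], [cluster], base_intensity=1.0)
        assert m.contribution == pytest.approx(0.9, abs=1e-6)

    def test_score_is_additive_and_order_invariant(self):
        a = self.unit_match(1.0, cluster_id=1)
        b = self.unit_match(0.9, cluster_id=2)
        assert score_component([a, b]).score == pytest.approx(1.9)
        assert score_component([b, a]).score == pytest.approx(1.9)

    def test_no_matches_scores_zero(self):
        assert score_component([]).score == 0.0

    def test_mixed_compositions_rejected(self):
        a = self.unit_match()
        b = self.unit_match()
        object.__setattr__(b.ion, "composition", Composition(0, 2, 2, 0, 3, 0, 0))
        with pytest.raises(ValueError):
            score_component([a, b])


def toy_candidate(comp, cluster_contribs, clusters):
    """ComponentResult matching the given clusters with given contributions."""
    matches = []
    for cid, contribution in cluster_contribs.items():
        ion = intact_ion(comp, clusters[cid].charge)
        matches.append(
            ClusterMatch(
                cluster=clusters[cid],
                ion=ion,
                isotope_order=1,
                js=0.0,
                contribution=contribution,
            )
        )
    return ComponentResult(composition=comp, matches=matches)


def make_clusters(n, charge=2):
    out = {}
    for cid in range(n):
        mzs = 300.0 + 10 * cid + np.arange(3) * 0.5017
        out[cid] = IsotopicCluster(
            mzs=mzs, intensities=np.array([5.0, 3.0, 1.0]), charge=charge, cluster_id=cid
        )
    return out


def brute_force_best_sg(candidates, alpha):
    """Exhaustive max of the global score over all ordered selections."""
    best = 0.0
    for r in range(1, len(candidates) + 1):
        for order in itertools.permutations(candidates, r):
            explained = set()
            total = 0.0
            for cand in order:
                gain = sum(
                    m.contribution
                    for m in cand.matches
                    if any(float(x) not in explained for x in m.cluster.mzs)
                )
                total += gain
                for m in cand.matches:
                    explained |= {float(x) for x in m.cluster.mzs}
            best = max(best, alpha ** r * total)
    return best


COMPS = [
    Composition(1, 1, 2, 0, 5, 0, 0),
    Composition(0, 2, 2, 0, 3, 0, 0),
    Composition(0, 2, 2, 1, 3, 0, 0),
]


class TestGreedySelection:
    def test_dominating_candidate_selected_alone(self):
        clusters = make_clusters(3)
        big = toy_candidate(COMPS[0], {0: 1.0, 1: 1.0, 2: 1.0}, clusters)
        small1 = toy_candidate(COMPS[1], {0: 1.0}, clusters)
        small2 = toy_candidate(COMPS[2], {1: 1.0, 2: 1.0}, clusters)
        sel = greedy_select([big, small1, small2], alpha=0.99)
        assert sel.compositions == [COMPS[0]]
        assert sel.global_score == pytest.approx(0.99 * 3.0)

    def test_four_cluster_three_candidate_instance_matches_exhaustive(self):
        clusters = make_clusters(4)
        cands = [
            toy_candidate(COMPS[0], {0: 1.2, 1: 0.7}, clusters),
            toy_candidate(COMPS[1], {1: 0.7, 2: 0.9}, clusters),
            toy_candidate(COMPS[2], {3: 0.4}, clusters),
        ]
        sel = greedy_select(cands, alpha=0.99)
        assert sel.global_score == pytest.approx(
            brute_force_best_sg(cands, 0.99), abs=1e-12
        )

    def test_random_instances_match_exhaustive_search(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n_clusters = int(rng.integers(2, 6))
            clusters = make_clusters(n_clusters)
            # cluster-intrinsic contributions: every matching candidate
            # earns the same amount for a given cluster
            values = rng.uniform(0.1, 2.0, size=n_clusters)
            cands = []
            for comp in COMPS:
                covered = rng.random(n_clusters) < 0.6
                contribs = {c: float(values[c]) for c in range(n_clusters) if covered[c]}
                if contribs:
                    cands.append(toy_candidate(comp, contribs, clusters))
            if not cands:
                continue
            sel = greedy_select(cands, alpha=0.99)
            assert sel.global_score == pytest.approx(
                brute_force_best_sg(cands, 0.99), abs=1e-12
            )

    def test_alpha_one_returns_full_positive_gain_sequence(self):
        clusters = make_clusters(3)
        cands = [
            toy_candidate(COMPS[0], {0: 1.0}, clusters),
            toy_candidate(COMPS[1], {1: 0.5}, clusters),
            toy_candidate(COMPS[2], {2: 0.2}, clusters),
        ]
        sel = greedy_select(cands, alpha=1.0)
        assert len(sel.selected) == 3
        assert sel.global_score == pytest.approx(1.7)
        # global score is nondecreasing along the greedy sequence
        assert sorted(sel.gains, reverse=True) == sel.gains

    def test_shared_cluster_credited_once(self):
        clusters = make_clusters(2)
        a = toy_candidate(COMPS[0], {0: 1.0, 1: 0.8}, clusters)
        b = toy_candidate(COMPS[1], {1: 0.8}, clusters)
        sel = greedy_select([a, b], alpha=1.0)
        # cluster 1 is claimed by the first component; b adds nothing
        assert sel.compositions == [COMPS[0]]
        assert sel.global_score == pytest.approx(1.8)

    def test_empty_candidates_empty_selection(self):
        sel = greedy_select([], alpha=0.99)
        assert sel.selected == [] and sel.global_score == 0.0

    def test_tie_broken_by_lexicographic_composition(self):
        clusters = make_clusters(2)
        a = toy_candidate(COMPS[1], {0: 1.0}, clusters)
        b = toy_candidate(COMPS[2], {1: 1.0}, clusters)
        sel = greedy_select([b, a], alpha=0.99)
        assert sel.compositions[0] == COMPS[1]
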