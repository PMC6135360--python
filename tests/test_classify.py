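from itertools import product

import numpy as np
import pandas as pd
import pytest

from orchardkin.classify import (
    Thresholds,
    classify_pairs,
    collapse_clones,
    find_close_groups,
    tier_summaries,
)

from orchardkin.similarity import SimilarityMatrix, pairwise_matrix
from orchardkin.simulate import (
    SimConfig,
    cross,
    make_clone,
    render_collection,
    simulate_founders,
)
from conftest import ssr


def sim_from_scores(scores: dict[tuple[str, str], float]) -> SimilarityMatrix:
    ids = sorted({a for p in scores for a in p})
    S = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    N = pd.DataFrame(100, index=ids, columns=ids)
    for (a, b), v in scores.items():
        S.at[a, b] = S.at[b, a] = v
    return SimilarityMatrix(S, N)


class TestThresholds:
    def test_defaults_valid(self):
        t = Thresholds()
        assert (t.close, t.borderline, t.clone) == (0.80, 0.88, 0.90)

    @pytest.mark.parametrize("kw", [
        {"clone": 0.7, "borderline": 0.88},       # clone below borderline
        {"close": 0.95},                           # close above borderline
        {"clone": 1.5},
    ])
    def test_invalid_orderings_rejected(self, kw):
        with pytest.raises(ValueError):
            Thresholds(**kw)


class TestClassifyPairs:
    @pytest.mark.parametrize(
        "score, category",
        [
            (0.902, "clone_or_duplicate"),   # the clone-band minimum case
            (0.95, "clone_or_duplicate"),
            (0.88, "borderline_clone"),      # review band
            (0.85, "close_relation"),
            (0.80, "close_relation"),
            (0.79, "standard"),
        ],
    )
    def test_band_assignment(self, score, category):
        sim = sim_from_scores({("X", "Y"): score})
        calls = classify_pairs(sim, include_standard=True)
        (call,) = [c for c in calls if set(c.pair) == {"X", "Y"}]
        assert call.category == category

    def test_standard_pairs_omitted_by_default(self):
        sim = sim_from_scores({("X", "Y"): 0.5, ("X", "Z"): 0.85})
        calls = classify_pairs(sim)
        assert {tuple(sorted(c.pair)) for c in calls} == {("X", "Z")}


class TestCollapseClones:
    def test_planted_clone_group_collapses_to_one_component(self):
        cfg = SimConfig(seed=11, n_founders=10, missing_rate=0.0,
                        clone_flip_rate=0.0)
        truth = simulate_founders(cfg)
        src = truth.ids[0]
        for c in range(4):
            make_clone(truth, src, clone_id=f"{src}.s{c}")
        coll = render_collection(truth)
        res = collapse_clones(pairwise_matrix(coll.marker_matrix))
        comp = res.component_of(src)
        assert len(comp) == 5
        assert res.representative_of(f"{src}.s0") == src  # lowest id wins

    def test_no_clone_edges_leaves_everything_separate(self):
        sim = sim_from_scores({("A", "B"): 0.5, ("B", "C"): 0.7})
        res = collapse_clones(sim)
        assert sorted(res.representatives) == ["A", "B", "C"]
        assert all(len(c) == 1 for c in res.components)

    def test_partition_covers_every_accession_once(self, default_collection):
        sim = pairwise_matrix(default_collection.marker_matrix)
        res = collapse_clones(sim)
        flat = [a for comp in res.components for a in comp]
        assert sorted(flat) == sorted(sim.accession_ids)
        assert len(res.representatives) == len(res.components)

    def test_ssr_conflict_keeps_both_genotypes_with_flags(self):
        sim = sim_from_scores({("A", "B"): 0.99})
        profiles = {
            "A": ssr("A", L1=(100, 104), L2=(118, 120), L3=(130,)),
            "B": ssr("B", L1=(100, 106), L2=(118, 122), L3=(132,)),
        }
        res = collapse_clones(sim, ssr_profiles=profiles)
        assert sorted(res.representatives) == ["A", "B"]
        (conflict,) = res.conflicts
        assert conflict.flags >= {"collecting_error_suspect", "ssr_conflict"}

    def test_matching_ssr_still_collapses(self):
        sim = sim_from_scores({("A", "B"): 0.99})
        profiles = {
            "A": ssr("A", L1=(100, 104), L2=(118, 120)),
            "B": ssr("B", L1=(100, 104), L2=(118, 122)),  # 1 locus differs
        }
        res = collapse_clones(sim, ssr_profiles=profiles)
        assert res.representatives == ["A"]
        assert res.conflicts == []

    def test_keep_list_overrides_representative(self):
        sim = sim_from_scores({("A", "B"): 0.95})
        res = collapse_clones(sim, keep_list=["B"])
        assert res.representatives == ["B"]

    @pytest.mark.parametrize("seed", range(5))
    def test_error_free_clones_always_collapse_unrelated_never(self, seed):
        cfg = SimConfig(seed=seed, n_founders=12, missing_rate=0.0,
                        clone_flip_rate=0.0)
        truth = simulate_founders(cfg)
        for src in truth.ids[:3]:
            make_clone(truth, src, clone_id=f"{src}.s0")
        coll = render_collection(truth)
        res = collapse_clones(pairwise_matrix(coll.marker_matrix))
        for comp in res.components:
            roots = {coll.truth.individuals[a].clone_of or a for a in comp}
            assert len(roots) == 1  # never merges unrelated accessions
        assert sum(len(c) > 1 for c in res.components) == 3


class TestFindCloseGroups:
    def test_independent_accessions_form_no_groups(self):
        sim = sim_from_scores({("A", "B"): 0.55, ("A", "C"): 0.6})
        assert find_close_groups(sim) == []

    def test_chain_linkage_spans_subthreshold_pairs(self):
        # parent links two offspring that score only 0.75 with each other
        sim = sim_from_scores({("P", "O1"): 0.85, ("P", "O2"): 0.84,
                               ("O1", "O2"): 0.75})
        (grp,) = find_close_groups(sim)
        assert grp.members == ["O1", "O2", "P"]

    def test_ploidy_partition(self, default_collection):
        coll = default_collection
        sim = pairwise_matrix(coll.marker_matrix)
        collapse = collapse_clones(sim)
        reduced = sim.subset(sorted(collapse.representatives))
        groups = find_close_groups(reduced, meta=coll.meta)
        het = [g for g in groups if g.group_class == "heteroploid_group"]
        assert het, "expected the planted triploid family to form a group"
        members = set().union(*(g.members for g in het))
        planted_triploids = {
            i for i, ind in coll.truth.individuals.items() if ind.ploidy == 3
        }
        assert members & planted_triploids

    def test_no_group_edge_reaches_clone_band(self, default_collection):
        sim = pairwise_matrix(default_collection.marker_matrix)
        collapse = collapse_clones(sim)
        reduced = sim.subset(sorted(collapse.representatives))
        for grp in find_close_groups(reduced):
            assert all(s < 0.90 for _, _, s in grp.edges)


# exact enumeration of the dominant-band joint distribution under
# Hardy-Weinberg transmission: the genotype-sharing oracle for tier means
def _expected_full_sib_jaccard(freqs: np.ndarray) -> float:
    a_sum = u_sum = 0.0
    for p in freqs:
        hw = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
        tab = np.zeros((2, 2))
        for c1, pc1 in enumerate(hw):
            for c2, pc2 in enumerate(hw):
                for t1a, t1b, t2a, t2b in product(range(2), repeat=4):
                    pr = pc1 * pc2
                    pr *= [1 - c1 / 2, c1 / 2][t1a] * [1 - c1 / 2, c1 / 2][t1b]
                    pr *= [1 - c2 / 2, c2 / 2][t2a] * [1 - c2 / 2, c2 / 2][t2b]
                    tab[int(t1a + t2a > 0), int(t1b + t2b > 0)] += pr
        a_sum += tab[1, 1]
        u_sum += tab[1, 1] + tab[0, 1] + tab[1, 0]
    return a_sum / u_sum


class TestTierSummaries:
    def test_tier_ordering_on_default_study(self, default_collection):
        coll = default_collection
        sim = pairwise_matrix(coll.marker_matrix)
        collapse = collapse_clones(sim)
        reduced = sim.subset(sorted(collapse.representatives))
        table = tier_summaries(reduced, coll.meta).set_index("tier")["mean"]
        assert (table["population"] < table["documented_siblings"]
                < table["documented_parent_offspring"]
                < table["documented_full_sibs"])

    def test_no_documented_parents_leaves_only_population(self):
        cfg = SimConfig(seed=2, n_founders=8)
        coll = render_collection(simulate_founders(cfg))
        sim = pairwise_matrix(coll.marker_matrix)
        table = tier_summaries(sim, coll.meta).set_index("tier")
        assert table.loc["population", "n"] > 0
        assert table.loc["documented_siblings", "n"] == 0
        assert table.loc["documented_full_sibs", "n"] == 0

    def test_full_sib_mean_matches_enumeration_oracle(self):
        cfg = SimConfig(seed=21, n_founders=42, missing_rate=0.0)
        truth = simulate_founders(cfg)
        rng = np.random.default_rng(21)
        pairs = []
        for f in range(100):  # 100 families x 1 sib pair = 200 sibs
            pa, pb = truth.ids[2 * f % 40], truth.ids[(2 * f + 1) % 40]
            a = cross(truth, pa, pb, child_id=f"S{f}a", rng=rng)
            b = cross(truth, pa, pb, child_id=f"S{f}b", rng=rng)
            pairs.append((a.id, b.id))
        coll = render_collection(truth)
        sim = pairwise_matrix(coll.marker_matrix)
        observed = np.mean([sim.value(a, b) for a, b in pairs])
        expected = _expected_full_sib_jaccard(truth.dart_freqs)
        assert observed == pytest.approx(expected, abs=0.03)
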