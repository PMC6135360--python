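import numpy as np
import pytest

from orchardkin.io import AccessionMeta, SSRProfile
from orchardkin.pedigree import (
    ExcludedParentError,
    IndeterminateError,
    PloidyContractError,
    diploid_complement_in_triploid,
    full_sib_plausible,
    infer_missing_parent,
    min_required_alleles,
    po_compatible,
    repeat_shift_annotations,
    timeline_check,
    triploid_complement_in_tetraploid,
)
from orchardkin.simulate import SimConfig, cross, render_collection, simulate_founders
from conftest import ssr


class TestPoCompatible:
    def test_shared_allele_is_consistent_with_residual(self):
        ass = po_compatible(ssr("P", L1=(118, 120)), ssr("O", L1=(120, 124)))
        assert ass.overall == "plausible"
        v = ass.verdicts["L1"]
        assert v.status == "consistent"
        assert v.residual_alleles == (124,)

    def test_no_shared_allele_excludes(self):
        ass = po_compatible(ssr("P", L1=(118, 120), L2=(100, 102)),
                            ssr("O", L1=(122, 124), L2=(100, 104)))
        assert ass.overall == "excluded"
        assert ass.n_inconsistent == 1

    def test_missing_locus_is_no_data_not_wildcard(self):
        ass = po_compatible(ssr("P", L1=(118, 120), L2=(100, 102)),
                            ssr("O", L1=(120, 124)))
        assert ass.verdicts["L2"].status == "no_data"

    def test_no_common_locus_is_indeterminate(self):
        with pytest.raises(IndeterminateError):
            po_compatible(ssr("P", L1=(118, 120)), ssr("O", L2=(100, 102)))

    def test_single_size_offspring_requires_allele_from_both(self):
        # offspring reported {120} only: possibly homozygous, so the other
        # parent owes a 120 as well
        ass = po_compatible(ssr("P", L1=(118, 120)), ssr("O", L1=(120,)))
        v = ass.verdicts["L1"]
        assert v.status == "consistent_homozygous_ambiguous"
        assert v.residual_alleles == (120,)

    def test_triploid_profile_violates_diploid_contract(self):
        with pytest.raises(PloidyContractError):
            po_compatible(ssr("P", L1=(118, 120)),
                          ssr("O", ploidy=2, L1=(100, 104, 110)))


class TestDiploidComplementInTriploid:
    def test_full_complement_contained(self):
        ass = diploid_complement_in_triploid(
            ssr("P", L1=(118, 120)), ssr("O", ploidy=3, L1=(118, 120, 126)))
        assert ass.overall == "plausible"
        v = ass.verdicts["L1"]
        assert v.status == "consistent"
        assert v.residual_alleles == (126,)

    def test_single_missing_allele_tolerated_once(self):
        loci_p = {f"L{i}": (100 + 2 * i, 120 + 2 * i) for i in range(12)}
        loci_o = {
            f"L{i}": tuple(sorted((100 + 2 * i, 120 + 2 * i, 150)))
            for i in range(12)
        }
        loci_o["L5"] = (100 + 10, 150, 152)  # drops parent allele 130
        parent = SSRProfile("P", loci_p, ploidy=2)
        off = SSRProfile("O", loci_o, ploidy=3)
        ass = diploid_complement_in_triploid(parent, off, tolerance=1)
        assert ass.overall == "plausible_with_tolerance"
        assert ass.n_tolerated == 1
        assert ass.verdicts["L5"].status == "tolerated_missing"

    def test_tolerance_zero_strictly_stricter(self):
        parent = ssr("P", L1=(118, 120), L2=(100, 102))
        off = ssr("O", ploidy=3, L1=(118, 120, 126), L2=(100, 104, 106))
        lenient = diploid_complement_in_triploid(parent, off, tolerance=1)
        strict = diploid_complement_in_triploid(parent, off, tolerance=0)
        assert lenient.overall == "plausible_with_tolerance"
        assert strict.overall == "excluded"

    def test_homozygous_parent_ambiguity_statuses(self):
        # 3 distinct offspring alleles incl. A: consistent (unreported
        # second parent allele may be among them)
        a1 = diploid_complement_in_triploid(
            ssr("P", L1=(118,)), ssr("O", ploidy=3, L1=(118, 124, 126)))
        assert a1.verdicts["L1"].status == "consistent"
        # <3 distinct: indistinguishable from homozygosity
        a2 = diploid_complement_in_triploid(
            ssr("P", L1=(118,)), ssr("O", ploidy=3, L1=(118, 124)))
        assert a2.verdicts["L1"].status == "consistent_homozygous_ambiguous"

    def test_both_alleles_absent_excludes(self):
        ass = diploid_complement_in_triploid(
            ssr("P", L1=(118, 120)), ssr("O", ploidy=3, L1=(122, 124, 126)),
            tolerance=1)
        assert ass.overall == "excluded"

    def test_containment_monotone_in_offspring_alleles(self):
        parent = ssr("P", L1=(118, 120))
        small = ssr("O", ploidy=3, L1=(118, 126))
        grown = ssr("O", ploidy=3, L1=(118, 120, 126))
        rank = {"inconsistent": 0, "tolerated_missing": 1,
                "consistent_homozygous_ambiguous": 2, "consistent": 2}
        s1 = diploid_complement_in_triploid(parent, small).verdicts["L1"].status
        s2 = diploid_complement_in_triploid(parent, grown).verdicts["L1"].status
        assert rank[s2] >= rank[s1]


class TestInferMissingParent:
    def test_forced_unique_survivor_in_toy_panel(self):
        off = ssr("O", L1=(120, 124), L2=(100, 104))
        known = ssr("P", L1=(118, 120), L2=(100, 102))
        panel = [
            ssr("C1", L1=(124, 126), L2=(104, 108)),  # carries both residuals
            ssr("C2", L1=(118, 126), L2=(104, 108)),  # lacks 124 at L1
        ]
        survivors, unique = infer_missing_parent(off, known, panel)
        assert unique
        assert survivors[0].candidate_id == "C1"

    def test_removing_true_parent_leaves_no_candidate(self):
        off = ssr("O", L1=(120, 124))
        known = ssr("P", L1=(118, 120))
        panel = [ssr("C2", L1=(118, 126))]
        survivors, unique = infer_missing_parent(off, known, panel)
        assert survivors == [] and not unique

    def test_excluded_known_parent_refused(self):
        off = ssr("O", L1=(120, 124))
        not_parent = ssr("P", L1=(110, 112))
        with pytest.raises(ExcludedParentError):
            infer_missing_parent(off, not_parent, [ssr("C", L1=(120, 124))])

    def test_survivor_set_shrinks_as_loci_added(self):
        rng = np.random.default_rng(0)
        sizes = [100 + 2 * k for k in range(8)]
        panel = [
            SSRProfile(f"C{i:03d}",
                       {f"L{j}": tuple(sorted(rng.choice(sizes, 2)))
                        for j in range(6)})
            for i in range(60)
        ]
        known = SSRProfile("P", {f"L{j}": (100, 102) for j in range(6)})
        off = SSRProfile("O", {f"L{j}": (102, 108) for j in range(6)})
        prev = None
        for n_loci in (1, 2, 4, 6):
            sub = SSRProfile("O", {f"L{j}": off.genotype[f"L{j}"]
                                   for j in range(n_loci)})
            survivors, _ = infer_missing_parent(sub, known, panel)
            ids = {s.candidate_id for s in survivors}
            if prev is not None:
                assert ids <= prev
            prev = ids


class TestTriploidComplementInTetraploid:
    def test_full_complement(self):
        ass = triploid_complement_in_tetraploid(
            ssr("P", ploidy=3, L1=(100, 104, 110)),
            ssr("O", ploidy=4, L1=(100, 104, 110, 114)))
        assert ass.locus_categories["full_complement"] == 1
        assert ass.overall in ("plausible", "plausible_with_tolerance")

    def test_two_distinct_parent_sizes_indistinguishable(self):
        ass = triploid_complement_in_tetraploid(
            ssr("P", ploidy=3, L1=(100, 104)),  # third allele hidden
            ssr("O", ploidy=4, L1=(100, 104, 114, 118)))
        assert ass.locus_categories["indistinguishable"] == 1

    def test_crafted_twelve_locus_category_split(self):
        # 5 full-complement / 4 indistinguishable / 3 partial
        geno_p, geno_o = {}, {}
        for i in range(5):
            geno_p[f"F{i}"] = (100, 104, 110)
            geno_o[f"F{i}"] = (100, 104, 110, 120)
        for i in range(4):
            geno_p[f"I{i}"] = (100, 104)
            geno_o[f"I{i}"] = (100, 104, 120, 124)
        for i in range(3):
            geno_p[f"P{i}"] = (100, 104, 110)
            geno_o[f"P{i}"] = (100, 104, 120, 124)  # 110 missing
        ass = triploid_complement_in_tetraploid(
            SSRProfile("G", geno_p, ploidy=3), SSRProfile("S", geno_o, ploidy=4))
        cats = ass.locus_categories
        assert (cats["full_complement"], cats["indistinguishable"],
                cats["partial"], cats["inconsistent"]) == (5, 4, 3, 0)
        assert ass.overall != "excluded"

    def test_two_absent_alleles_inconsistent(self):
        ass = triploid_complement_in_tetraploid(
            ssr("P", ploidy=3, L1=(100, 104, 110)),
            ssr("O", ploidy=4, L1=(100, 120, 124, 128)))
        assert ass.locus_categories["inconsistent"] == 1
        assert ass.overall == "excluded"


class TestFullSibPlausible:
    def test_matching_residuals_plausible(self):
        shared = ssr("M", L1=(118, 120))
        a = ssr("A", L1=(118, 124))
        b = ssr("B", L1=(120, 124))
        res = full_sib_plausible(a, b, shared)
        assert res["plausible"]
        assert res["required_alleles_per_locus"]["L1"] <= 2

    def test_counting_rule_three_required_alleles_fails(self):
        # abstract counting rule: residuals {124} and {126,128} need a
        # co-parent carrying three distinct alleles — impossible for 2x
        assert min_required_alleles(((124,),), ((126, 128),)) == 3
        assert min_required_alleles(((124,),), ((124,),)) == 1

    def test_excluded_shared_parent_refused(self):
        shared = ssr("M", L1=(100, 102))
        a = ssr("A", L1=(118, 124))
        b = ssr("B", L1=(100, 124))
        with pytest.raises(ExcludedParentError):
            full_sib_plausible(a, b, shared)

    def test_joint_panel_search(self):
        shared = ssr("M", L1=(118, 120), L2=(100, 102))
        a = ssr("A", L1=(118, 124), L2=(100, 108))
        b = ssr("B", L1=(120, 124), L2=(102, 108))
        panel = [ssr("F", L1=(124, 126), L2=(108, 110)),
                 ssr("G", L1=(126, 128), L2=(108, 110))]
        res = full_sib_plausible(a, b, shared, panel=panel)
        assert res["joint_candidates"] == ["F"]
        assert res["unique_joint_candidate"]


class TestTimelineCheck:
    def _meta(self, acc, date):
        from orchardkin.io import parse_origin_date
        return AccessionMeta(accession_id=acc,
                             date_of_origin=parse_origin_date(date))

    def test_older_parent_ok(self):
        assert timeline_check(self._meta("P", "pre 1750"),
                              self._meta("O", "1897")) == "ok"

    def test_later_parent_conflicts_but_is_a_flag(self):
        assert timeline_check(self._meta("P", "1920"),
                              self._meta("O", "1700")) == "conflict"

    def test_missing_dates_unknown(self):
        assert timeline_check(self._meta("P", ""),
                              self._meta("O", "1900")) == "unknown"


def test_repeat_shift_annotation_is_advisory():
    parent = ssr("P", L1=(118, 120), L2=(100, 104))
    off = ssr("O", L1=(120, 122), L2=(100, 106))
    notes = repeat_shift_annotations(parent, off, shift=2)
    assert (118, 120) in notes["L1"] or (120, 122) in notes["L1"]
    assert "L2" in notes


class TestExclusionSoundnessOnSimulatedTrios:
    """A true simulated parent is never excluded at zero error rates."""

    def test_diploid_and_triploid_trios(self):
        cfg = SimConfig(seed=17, n_founders=30, missing_rate=0.0,
                        unreduced_gamete_homozygosity_loss=0.0)
        truth = simulate_founders(cfg)
        rng = np.random.default_rng(17)
        ids = truth.ids
        for t in range(10):
            cross(truth, ids[2 * t], ids[2 * t + 1], child_id=f"D{t}", rng=rng)
            cross(truth, ids[2 * t], ids[2 * t + 1],
                  model_a="unreduced_diploid", child_id=f"T{t}", rng=rng)
        coll = render_collection(truth)
        prof = coll.ssr_by_id()
        for t in range(10):
            ma, pa = ids[2 * t], ids[2 * t + 1]
            assert po_compatible(prof[ma], prof[f"D{t}"]).overall == "plausible"
            assert po_compatible(prof[pa], prof[f"D{t}"]).overall == "plausible"
            tri = diploid_complement_in_triploid(
                prof[ma], prof[f"T{t}"], tolerance=0)
            assert tri.overall == "plausible"
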