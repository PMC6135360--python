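"""Ploidy-aware SSR compatibility and exclusion rules for parentage.

Codominant SSR profiles support three gamete models:

* ``haploid`` — an ordinary reduced gamete from a diploid parent (one
  allele per locus); the basis of diploid parent-offspring checks.
* ``unreduced_diploid`` — a first-division-restitution gamete carrying the
  diploid parent's full two-allele complement, the route by which triploid
  offspring arise; parental heterozygosity is largely retained, with
  occasional per-locus homozygosity (crossover loss).
* ``triploid`` — an unreduced gamete from a triploid parent, producing
  tetraploid offspring.

All checks are exclusion-based: a candidate parent is excluded when it
cannot supply the alleles a gamete model requires at some scored locus.
A single reported size is treated as "at least one copy, possibly
homozygous" — ambiguity resolves in favour of consistency under a
distinct status so downstream users can count ambiguous loci.  Loci with
missing data in either profile never contribute (no wildcard matching).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .io import AccessionMeta, SSRProfile

__all__ = [
    "GameteModel",
    "LocusVerdict",
    "ParentageAssessment",
    "CandidateResult",
    "IndeterminateError",
    "PloidyContractError",
    "ExcludedParentError",
    "po_compatible",
    "diploid_complement_in_triploid",
    "infer_missing_parent",
    "triploid_complement_in_tetraploid",
    "full_sib_plausible",
    "timeline_check",
    "repeat_shift_annotations",
]


class GameteModel(str, Enum):
    """Named gamete model with the allele count it transmits per locus."""

    haploid = "haploid"
    unreduced_diploid = "unreduced_diploid"
    triploid = "triploid"

    @property
    def transmitted_alleles(self) -> int:
        return {"haploid": 1, "unreduced_diploid": 2, "triploid": 3}[self.value]


class IndeterminateError(ValueError):
    """No commonly scored locus — compatibility cannot be assessed."""


class PloidyContractError(ValueError):
    """A profile reports more alleles than its ploidy/model permits."""


class ExcludedParentError(ValueError):
    """The supposedly known parent fails its own compatibility check."""


@dataclass
class LocusVerdict:
    """Per-locus outcome of a gamete-model compatibility check.

    ``residual_alleles`` is the canonical multiset owed by the other
    parent; ``residual_options`` enumerates the alternative single-gamete
    contributions compatible with the data (used by the exclusion search).
    """

    locus_id: str
    status: str  # consistent | consistent_homozygous_ambiguous |
    #              tolerated_missing | inconsistent | no_data
    residual_alleles: tuple[int, ...] = ()
    residual_options: tuple[tuple[int, ...], ...] = ()


_OK_STATUSES = ("consistent", "consistent_homozygous_ambiguous")


@dataclass
class ParentageAssessment:
    offspring_id: str
    parent_ids: tuple[str, ...]
    gamete_model: GameteModel
    verdicts: dict[str, LocusVerdict] = field(default_factory=dict)
    n_inconsistent: int = 0
    n_tolerated: int = 0
    overall: str = "plausible"  # plausible | plausible_with_tolerance | excluded
    locus_categories: Counter = field(default_factory=Counter)

    def scored_loci(self) -> list[str]:
        return [l for l, v in self.verdicts.items() if v.status != "no_data"]


def _finalize(assessment: ParentageAssessment, tolerance: int) -> ParentageAssessment:
    if not assessment.scored_loci():
        raise IndeterminateError(
            f"no commonly scored locus between {assessment.parent_ids} and "
            f"{assessment.offspring_id}"
        )
    if assessment.n_inconsistent > 0:
        assessment.overall = "excluded"
    elif assessment.n_tolerated > 0:
        assessment.overall = "plausible_with_tolerance"
    else:
        assessment.overall = "plausible"
    return assessment


def po_compatible(
    parent: SSRProfile, offspring: SSRProfile, tolerance: int = 0
) -> ParentageAssessment:
    """Diploid parent-offspring check under the haploid gamete model.

    A locus is consistent iff the offspring shares at least one allele with
    the parent.  With zero tolerance (default) any inconsistent scored
    locus excludes the parent.  Residuals: the allele(s) the other parent
    must supply; when several assignments are possible all are enumerated.
    """
    for who in (parent, offspring):
        for locus, alleles in who.genotype.items():
            if len(alleles) > 2 and (who.ploidy or 2) == 2:
                raise PloidyContractError(
                    f"{who.accession_id}/{locus}: >2 alleles for a diploid"
                )
    out = ParentageAssessment(
        offspring_id=offspring.accession_id,
        parent_ids=(parent.accession_id,),
        gamete_model=GameteModel.haploid,
    )
    loci = sorted(set(parent.genotype) | set(offspring.genotype))
    for locus in loci:
        pa = set(parent.alleles(locus))
        oa = offspring.alleles(locus)
        if not pa or not oa:
            out.verdicts[locus] = LocusVerdict(locus, "no_data")
            continue
        # single reported size on a diploid: treat as homozygous for the
        # residual (the other parent must then also carry it)
        oa_full = oa if len(oa) >= 2 else (oa[0], oa[0])
        shared = pa & set(oa_full)
        if not shared:
            out.n_inconsistent += 1
            out.verdicts[locus] = LocusVerdict(locus, "inconsistent")
            continue
        options = set()
        for s in shared:
            rest = list(oa_full)
            rest.remove(s)
            options.add(tuple(sorted(rest)))
        options = tuple(sorted(options))
        status = "consistent"
        if len(oa) < 2 or len(pa) < 2:
            status = "consistent_homozygous_ambiguous"
        out.verdicts[locus] = LocusVerdict(
            locus, status,
            residual_alleles=min(options, key=lambda t: (len(t), t)),
            residual_options=options,
        )
    return _finalize(out, tolerance)


def diploid_complement_in_triploid(
    parent: SSRProfile, offspring: SSRProfile, tolerance: int = 1
) -> ParentageAssessment:
    """Is the parent's full diploid complement contained in the triploid?

    Under the unreduced-diploid (first-division-restitution) gamete model
    a triploid offspring carries both alleles of the donating parent at
    every locus.  A heterozygous parent {A,B} is consistent iff both A and
    B appear in the offspring; one absent allele is tolerated while the
    budget (default 1, matching the single-missing-allele precedent)
    lasts.  A single-size parent {A} is consistent when A appears: with
    three distinct offspring alleles the parent's unreported second allele
    may be among them (status ``consistent``); with fewer the state is
    indistinguishable from homozygosity (``consistent_homozygous_ambiguous``).
    """
    for locus, alleles in parent.genotype.items():
        if len(alleles) > 2:
            raise PloidyContractError(
                f"{parent.accession_id}/{locus}: >2 alleles for a diploid parent"
            )
    out = ParentageAssessment(
        offspring_id=offspring.accession_id,
        parent_ids=(parent.accession_id,),
        gamete_model=GameteModel.unreduced_diploid,
    )
    for locus in sorted(set(parent.genotype) | set(offspring.genotype)):
        pa = tuple(sorted(set(parent.alleles(locus))))
        oa = offspring.alleles(locus)
        if not pa or not oa:
            out.verdicts[locus] = LocusVerdict(locus, "no_data")
            continue
        od = tuple(sorted(set(oa)))
        present = [a for a in pa if a in od]
        absent = [a for a in pa if a not in od]
        leftover = tuple(a for a in od if a not in pa)

        if len(pa) == 2:
            if not absent:
                # residual: the haploid gamete of the other parent
                options = (leftover and tuple((x,) for x in leftover)) or \
                    tuple((x,) for x in od)
                out.verdicts[locus] = LocusVerdict(
                    locus, "consistent",
                    residual_alleles=options[0], residual_options=options)
            elif len(absent) == 1:
                if out.n_tolerated < tolerance:
                    out.n_tolerated += 1
                    out.verdicts[locus] = LocusVerdict(locus, "tolerated_missing")
                else:
                    out.n_inconsistent += 1
                    out.verdicts[locus] = LocusVerdict(locus, "inconsistent")
            else:
                out.n_inconsistent += 1
                out.verdicts[locus] = LocusVerdict(locus, "inconsistent")
        else:  # single reported size
            if present:
                if len(od) == 3:
                    # parent's unreported second allele may be either leftover
                    options = tuple((x,) for x in leftover)
                    status = "consistent"
                else:
                    options = tuple((x,) for x in od)
                    status = "consistent_homozygous_ambiguous"
                out.verdicts[locus] = LocusVerdict(
                    locus, status,
                    residual_alleles=options[0] if options else (),
                    residual_options=options)
            else:
                out.n_inconsistent += 1
                out.verdicts[locus] = LocusVerdict(locus, "inconsistent")
    return _finalize(out, tolerance)


@dataclass
class CandidateResult:
    candidate_id: str
    n_fully_consistent_loci: int
    n_scored_loci: int


def infer_missing_parent(
    offspring: SSRProfile,
    known_parent: SSRProfile,
    panel: list[SSRProfile],
    model: GameteModel = GameteModel.haploid,
    tolerance: int = 0,
) -> tuple[list[CandidateResult], bool]:
    """Exclusion search for the unknown second parent.

    The known parent must itself pass the applicable compatibility check
    (haploid for diploid offspring, unreduced-diploid for triploids); the
    residual allele requirements it leaves are then tested against every
    panel member.  A candidate survives iff at every commonly scored locus
    it can supply one of the residual options (homozygous ambiguity
    permitted).  Survivors are ranked by fully consistent locus count
    (descending) then accession id; the second element of the return value
    flags a unique survivor.
    """
    if model is GameteModel.haploid:
        base = po_compatible(known_parent, offspring, tolerance=tolerance)
    elif model is GameteModel.unreduced_diploid:
        base = diploid_complement_in_triploid(
            known_parent, offspring, tolerance=tolerance)
    else:
        raise ValueError("second-parent inference supports haploid and "
                         "unreduced_diploid known-parent models")
    if base.overall == "excluded":
        raise ExcludedParentError(
            f"{known_parent.accession_id} is itself excluded as a parent of "
            f"{offspring.accession_id} "
            f"({base.n_inconsistent} inconsistent loci)"
        )

    requirements: dict[str, tuple[tuple[int, ...], ...]] = {}
    for locus, v in base.verdicts.items():
        if v.status in _OK_STATUSES and v.residual_options:
            requirements[locus] = v.residual_options

    survivors = []
    for cand in panel:
        if cand.accession_id in (offspring.accession_id,
                                 known_parent.accession_id):
            continue
        ok = True
        n_full = 0
        n_scored = 0
        for locus, options in requirements.items():
            ca = set(cand.alleles(locus))
            if not ca:
                continue  # missing data never excludes (nor supports)
            n_scored += 1
            if any(set(opt) <= ca for opt in options):
                n_full += 1
            else:
                ok = False
                break
        if ok and n_scored > 0:
            survivors.append(CandidateResult(
                candidate_id=cand.accession_id,
                n_fully_consistent_loci=n_full,
                n_scored_loci=n_scored,
            ))
    survivors.sort(key=lambda c: (-c.n_fully_consistent_loci, c.candidate_id))
    return survivors, len(survivors) == 1


def triploid_complement_in_tetraploid(
    parent: SSRProfile, offspring: SSRProfile,
    max_inconsistent: int = 0,
) -> ParentageAssessment:
    """Does the tetraploid contain the triploid parent's full complement?

    Per locus the outcome is categorized: ``full_complement`` (all three
    distinct parent alleles present), ``indistinguishable`` (parent shows
    fewer than three distinct sizes, all present — potential homozygosity
    hides the third), ``partial`` (exactly one parent allele absent) or
    ``inconsistent`` (two or more absent).  Category counts are returned;
    by default any inconsistent locus excludes.
    """
    for locus, alleles in parent.genotype.items():
        if len(alleles) > 3:
            raise PloidyContractError(
                f"{parent.accession_id}/{locus}: >3 alleles for a triploid parent"
            )
    out = ParentageAssessment(
        offspring_id=offspring.accession_id,
        parent_ids=(parent.accession_id,),
        gamete_model=GameteModel.triploid,
    )
    for locus in sorted(set(parent.genotype) | set(offspring.genotype)):
        pa = tuple(sorted(set(parent.alleles(locus))))
        oa = set(offspring.alleles(locus))
        if not pa or not oa:
            out.verdicts[locus] = LocusVerdict(locus, "no_data")
            continue
        absent = [a for a in pa if a not in oa]
        leftover = tuple(sorted(a for a in oa if a not in pa))
        if len(absent) == 0:
            if len(pa) == 3:
                cat, status = "full_complement", "consistent"
            else:
                cat, status = "indistinguishable", "consistent_homozygous_ambiguous"
            options = tuple((x,) for x in leftover) or tuple((x,) for x in sorted(oa))
            out.verdicts[locus] = LocusVerdict(
                locus, status, residual_alleles=options[0],
                residual_options=options)
        elif len(absent) == 1:
            cat, status = "partial", "tolerated_missing"
            out.n_tolerated += 1
            out.verdicts[locus] = LocusVerdict(locus, status)
        else:
            cat, status = "inconsistent", "inconsistent"
            out.n_inconsistent += 1
            out.verdicts[locus] = LocusVerdict(locus, status)
        out.locus_categories[cat] += 1
    out = _finalize(out, tolerance=len(out.verdicts))
    if out.n_inconsistent > max_inconsistent:
        out.overall = "excluded"
    return out


def min_required_alleles(
    options_a: tuple[tuple[int, ...], ...],
    options_b: tuple[tuple[int, ...], ...],
) -> int:
    """Fewest distinct alleles one co-parent genotype must carry to cover
    one residual alternative from each offspring; more than two cannot fit
    in a diploid and rules out full siblingship at that locus."""
    return min(
        len(set(oa) | set(ob))
        for oa in (options_a or ((),))
        for ob in (options_b or ((),))
    )


def full_sib_plausible(
    a: SSRProfile,
    b: SSRProfile,
    shared_parent: SSRProfile,
    panel: list[SSRProfile] | None = None,
) -> dict:
    """Could two accessions be full siblings through a shared parent?

    Both must be parent-offspring compatible with the shared parent; the
    residual alleles each owes to the unknown co-parent are then unified
    per locus, and the pair is plausible iff one diploid genotype could
    cover both residuals everywhere (at most two distinct required
    alleles, minimized over alternative assignments).  With a panel, a
    joint exclusion search for the co-parent is run as well.
    """
    ass_a = po_compatible(shared_parent, a)
    ass_b = po_compatible(shared_parent, b)
    for who, ass in ((a, ass_a), (b, ass_b)):
        if ass.overall == "excluded":
            raise ExcludedParentError(
                f"{shared_parent.accession_id} excluded as parent of "
                f"{who.accession_id}"
            )
    verdict = True
    per_locus: dict[str, int] = {}
    for locus in sorted(set(ass_a.verdicts) & set(ass_b.verdicts)):
        va, vb = ass_a.verdicts[locus], ass_b.verdicts[locus]
        if va.status == "no_data" or vb.status == "no_data":
            continue
        best = min_required_alleles(va.residual_options, vb.residual_options)
        per_locus[locus] = best
        if best > 2:
            verdict = False
    result = {"plausible": verdict, "required_alleles_per_locus": per_locus}
    if panel is not None and verdict:
        surv_a, _ = infer_missing_parent(a, shared_parent, panel)
        surv_b, _ = infer_missing_parent(b, shared_parent, panel)
        joint = sorted(
            {c.candidate_id for c in surv_a} & {c.candidate_id for c in surv_b}
        )
        result["joint_candidates"] = joint
        result["unique_joint_candidate"] = len(joint) == 1
    return result


def timeline_check(
    meta_parent: AccessionMeta, meta_offspring: AccessionMeta
) -> str:
    """Provenance-date sanity check: 'conflict' when the parent's earliest
    documented year postdates the offspring's (a flag, never an exclusion —
    'pre' dates are only upper bounds), 'unknown' when either is undated."""
    py, oy = meta_parent.date_of_origin.year, meta_offspring.date_of_origin.year
    if py is None or oy is None:
        return "unknown"
    return "conflict" if py > oy else "ok"


def repeat_shift_annotations(
    parent: SSRProfile, offspring: SSRProfile, shift: int = 2
) -> dict[str, list[tuple[int, int]]]:
    """Annotate near-miss alleles one repeat unit (default 2 bp) apart.

    Purely advisory: a 2 bp shift between a parental and offspring allele
    may be mutation or scoring drift and warns rather than excludes.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for locus in set(parent.genotype) & set(offspring.genotype):
        pairs = [
            (pa, oa)
            for pa in set(parent.alleles(locus))
            for oa in set(offspring.alleles(locus))
            if abs(pa - oa) == shift
        ]
        if pairs:
            out[locus] = sorted(pairs)
    return out
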