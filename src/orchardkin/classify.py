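"""Relationship calls from a similarity matrix: clone/duplicate collapse,
borderline flags, close-relation groups and tier summaries.

Calibrated thresholds on the Jaccard score partition pairs into bands:
scores >= 0.90 generally signify clonality or duplication; [0.88, 0.90)
is a borderline band that warrants manual review; [0.80, 0.90) marks
relationships closer than a standard parent-offspring or full-sibling
(often inbreeding or heteroploid parent-offspring via an unreduced
gamete).  Groups are formalized as single-linkage connected components
over edges at or above the close threshold, which reproduces the way a
shared parent links triploid offspring that do not all exceed the
threshold pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import AccessionMeta, SSRProfile
from .similarity import SimilarityMatrix

__all__ = [
    "Thresholds",
    "RelationshipCall",
    "CloneCollapse",
    "CloseGroup",
    "classify_pairs",
    "collapse_clones",
    "find_close_groups",
    "tier_summaries",
]


@dataclass(frozen=True)
class Thresholds:
    """Similarity bands: clone [clone, 1]; borderline [borderline, clone);
    close relation [close, borderline); standard below close."""

    clone: float = 0.90
    close: float = 0.80
    borderline: float = 0.88

    def __post_init__(self) -> None:
        if not (0 < self.close <= self.borderline <= self.clone <= 1):
            raise ValueError(
                f"need 0 < close <= borderline <= clone <= 1, got {self}"
            )

    def category(self, score: float) -> str:
        if np.isnan(score):
            return "standard"
        if score >= self.clone:
            return "clone_or_duplicate"
        if score >= self.borderline:
            return "borderline_clone"
        if score >= self.close:
            return "close_relation"
        return "standard"


@dataclass
class RelationshipCall:
    pair: tuple[str, str]
    score: float
    category: str
    flags: frozenset[str] = frozenset()


@dataclass
class CloneCollapse:
    """Result of clone/duplicate collapse.

    ``components`` partitions every accession (singletons included);
    ``representatives`` holds one id per component; ``conflicts`` lists
    marker-indistinguishable pairs kept apart because their SSR profiles
    disagree (suspected collecting errors).
    """

    representatives: list[str]
    components: list[list[str]]
    conflicts: list[RelationshipCall] = field(default_factory=list)

    def component_of(self, accession: str) -> list[str]:
        for comp in self.components:
            if accession in comp:
                return comp
        raise KeyError(accession)

    def representative_of(self, accession: str) -> str:
        for rep, comp in zip(self.representatives, self.components):
            if accession in comp:
                return rep
        raise KeyError(accession)


@dataclass
class CloseGroup:
    members: list[str]
    edges: list[tuple[str, str, float]]
    ploidy_profile: dict[str, int]
    group_class: str  # diploid_sibling_group | heteroploid_group | mixed_unknown


def classify_pairs(
    sim: SimilarityMatrix,
    thresholds: Thresholds = Thresholds(),
    include_standard: bool = False,
) -> list[RelationshipCall]:
    """Band every scored pair; by default only pairs at or above the close
    threshold are materialized (set ``include_standard`` for all pairs)."""
    lower = -np.inf if include_standard else thresholds.close
    df = sim.pairs(lower=lower)
    return [
        RelationshipCall(
            pair=(row.acc_i, row.acc_j),
            score=float(row.score),
            category=thresholds.category(row.score),
        )
        for row in df.itertuples()
    ]


def _ssr_locus_differences(a: SSRProfile, b: SSRProfile) -> int:
    """Number of commonly scored loci at which the reported allele
    multisets differ."""
    common = set(a.genotype) & set(b.genotype)
    return sum(1 for loc in common if a.genotype[loc] != b.genotype[loc])


def collapse_clones(
    sim: SimilarityMatrix,
    meta: dict[str, AccessionMeta] | None = None,
    ssr_profiles: dict[str, SSRProfile] | None = None,
    thresholds: Thresholds = Thresholds(),
    keep_list: list[str] | None = None,
    ssr_conflict_loci: int = 2,
) -> CloneCollapse:
    """Single-linkage clone collapse with SSR conflict screening.

    Edges at or above the clone threshold define components; each collapses
    to one representative (the lowest accession id, unless ``keep_list``
    names a member).  A pair indistinguishable by markers but differing at
    >= ``ssr_conflict_loci`` commonly scored SSR loci is a suspected
    collecting error: the edge is removed so both genotypes survive, and
    the pair is recorded as a conflict.
    """
    edges = sim.pairs(lower=thresholds.clone)
    conflicts: list[RelationshipCall] = []
    g = nx.Graph()
    g.add_nodes_from(sim.accession_ids)
    for row in edges.itertuples():
        if ssr_profiles is not None:
            pa, pb = ssr_profiles.get(row.acc_i), ssr_profiles.get(row.acc_j)
            if pa is not None and pb is not None:
                if _ssr_locus_differences(pa, pb) >= ssr_conflict_loci:
                    conflicts.append(RelationshipCall(
                        pair=(row.acc_i, row.acc_j), score=float(row.score),
                        category="clone_or_duplicate",
                        flags=frozenset({"collecting_error_suspect",
                                         "ssr_conflict"}),
                    ))
                    continue
        g.add_edge(row.acc_i, row.acc_j)

    keep = set(keep_list or ())
    components, representatives = [], []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        preferred = sorted(keep & comp)
        representatives.append(preferred[0] if preferred else members[0])
        components.append(members)
    order = np.argsort([c[0] for c in components])
    return CloneCollapse(
        representatives=[representatives[i] for i in order],
        components=[components[i] for i in order],
        conflicts=conflicts,
    )


def find_close_groups(
    sim_reduced: SimilarityMatrix,
    meta: dict[str, AccessionMeta] | None = None,
    thresholds: Thresholds = Thresholds(),
) -> list[CloseGroup]:
    """Single-linkage components over edges in [close, clone) on the
    clone-collapsed matrix, classified by the ploidy of their members."""
    edges = sim_reduced.pairs(lower=thresholds.close, upper=thresholds.clone)
    g = nx.Graph()
    for row in edges.itertuples():
        g.add_edge(row.acc_i, row.acc_j, score=float(row.score))

    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        comp_edges = [
            (a, b, g.edges[a, b]["score"])
            for a, b in g.edges(comp)
            if a in comp and b in comp
        ]
        comp_edges = sorted({(min(a, b), max(a, b), s) for a, b, s in comp_edges})
        ploidies = {}
        for m in members:
            p = meta[m].ploidy if meta is not None and m in meta else None
            ploidies[m] = 0 if p is None else p
        known = [p for p in ploidies.values() if p]
        if known and all(p == 2 for p in known) and len(known) == len(members):
            group_class = "diploid_sibling_group"
        elif any(p >= 3 for p in known):
            group_class = "heteroploid_group"
        else:
            group_class = "mixed_unknown"
        groups.append(CloseGroup(
            members=members, edges=comp_edges, ploidy_profile=ploidies,
            group_class=group_class,
        ))
    groups.sort(key=lambda gr: gr.members[0])
    return groups


def tier_summaries(
    sim: SimilarityMatrix,
    meta: dict[str, AccessionMeta],
    diploid_only: bool = True,
) -> pd.DataFrame:
    """Similarity summaries for documented-relationship tiers.

    Tiers: all pairs; documented sibling pairs (sharing at least one
    documented parent); documented parent-offspring pairs; documented
    full-sibling pairs (both parents documented and identical).  Reports
    n, mean, SD, min, max per tier; empty tiers report n=0.

    The relationship tiers characterize standard haploid-gamete
    transmission, so members with known ploidy >= 3 are excluded from them
    by default (unreduced-gamete offspring score far above these tiers and
    are handled by the close-relation machinery); the population tier
    always covers all pairs.
    """
    ids = [a for a in sim.accession_ids]
    idx = {a: i for i, a in enumerate(ids)}
    S = sim.S.to_numpy()

    def stats(pairs: set[tuple[int, int]]) -> dict:
        vals = np.array([S[i, j] for i, j in pairs], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return {"n": 0, "mean": np.nan, "sd": np.nan,
                    "min": np.nan, "max": np.nan}
        return {"n": int(vals.size), "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "min": float(vals.min()), "max": float(vals.max())}

    name_to_id = {}
    for a in ids:
        if a in meta:
            name_to_id.setdefault(meta[a].cultivar_name or a, a)
        name_to_id.setdefault(a, a)

    def is_diploid(a: str) -> bool:
        p = meta[a].ploidy if a in meta else None
        return p is None or p == 2

    sib_pairs: set[tuple[int, int]] = set()
    fs_pairs: set[tuple[int, int]] = set()
    po_pairs: set[tuple[int, int]] = set()
    with_parents = [a for a in ids if a in meta and meta[a].documented_parents]
    if diploid_only:
        with_parents = [a for a in with_parents if is_diploid(a)]
    for k, a in enumerate(with_parents):
        pa = set(meta[a].documented_parents)
        for p in pa:
            pid = name_to_id.get(p)
            if pid is not None and pid in idx and pid != a:
                po_pairs.add(tuple(sorted((idx[a], idx[pid]))))
        for b in with_parents[k + 1:]:
            pb = set(meta[b].documented_parents)
            if pa & pb:
                sib_pairs.add(tuple(sorted((idx[a], idx[b]))))
            if pa == pb and len(pa) == 2:
                fs_pairs.add(tuple(sorted((idx[a], idx[b]))))

    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    all_pairs = set(zip(iu.tolist(), ju.tolist()))

    rows = [
        {"tier": "population", **stats(all_pairs)},
        {"tier": "documented_siblings", **stats(sib_pairs)},
        {"tier": "documented_parent_offspring", **stats(po_pairs)},
        {"tier": "documented_full_sibs", **stats(fs_pairs)},
    ]
    return pd.DataFrame(rows)
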