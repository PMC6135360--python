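"""Synthetic germplasm collections with planted truth.

Generates collections containing the structures the analysis chain is
built to detect: clonal groups differing only by rare marker-state flips
and missing calls; diploid full-sib / half-sib / parent-offspring
families; triploids formed by a maternal unreduced
(first-division-restitution) gamete carrying the parent's full diploid
complement with occasional per-locus homozygosity; and tetraploids from
triploid gametes.  Underlying genotypes are codominant (biallelic
presence/absence alleles for the dominant markers; multi-allelic integer
sizes for the SSR loci) and are rendered the way the assays report them:
dominant band calls (present iff any presence allele across all copies,
dosage-blind) and distinct SSR allele sizes.

The planted truth (pedigree, gamete models, clone events, ploidy) is
retained so parameter-recovery tests can compare pipeline output with
what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    AccessionMeta,
    MarkerMatrix,
    OriginDate,
    SSRProfile,
    StructureRunSummary,
)

__all__ = [
    "SimConfig",
    "Individual",
    "TruthSet",
    "RenderedCollection",
    "simulate_founders",
    "cross",
    "make_clone",
    "render_collection",
    "simulate_structure_logs",
    "simulate_collection",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic collection.

    Defaults mirror the assay the pipeline targets: 562 dominant markers,
    12 SSR loci on separate chromosomes with up to 8 alleles spaced 2 bp
    apart, presence-allele frequencies spanning (0.05, 0.95), a clone
    flip rate producing the 0.97-1 replicate-similarity band, 1% missing
    calls, and a 5% per-locus homozygosity loss in unreduced gametes.
    """

    seed: int = 0
    n_founders: int = 40
    n_dart_loci: int = 562
    n_ssr_loci: int = 12
    ssr_alleles_per_locus: int = 8
    ssr_base_size: int = 100
    ssr_allele_step: int = 2
    dart_presence_freq: tuple[float, float] = (0.05, 0.95)
    clone_flip_rate: float = 0.005
    missing_rate: float = 0.01
    unreduced_gamete_homozygosity_loss: float = 0.05
    n_redundant_markers: int = 0
    corrupt_parent_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("clone_flip_rate", "missing_rate",
                     "unreduced_gamete_homozygosity_loss",
                     "corrupt_parent_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_dart_loci < 1:
            raise ValueError("n_dart_loci must be >=1")
        lo, hi = self.dart_presence_freq
        if not (0 <= lo <= hi <= 1):
            raise ValueError("dart_presence_freq must be an ordered range in [0,1]")


@dataclass
class Individual:
    """One genotype: per-marker presence-allele copy counts and per-locus
    SSR allele tuples (length = ploidy)."""

    id: str
    ploidy: int
    dart: np.ndarray  # int8 copies of the presence allele, 0..ploidy
    ssr: list[tuple[int, ...]]
    parents: tuple[str, str] | None = None
    gamete_models: tuple[str, str] | None = None
    clone_of: str | None = None
    flip_events: tuple[int, ...] = ()  # marker indices flipped at render


@dataclass
class TruthSet:
    config: SimConfig
    individuals: dict[str, Individual] = field(default_factory=dict)
    dart_freqs: np.ndarray | None = None
    ssr_freqs: list[np.ndarray] = field(default_factory=list)
    ssr_sizes: list[np.ndarray] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return list(self.individuals)

    def clone_components(self) -> list[list[str]]:
        """Connected components of the clone-of relation (size >= 2)."""
        root: dict[str, str] = {}
        for ind in self.individuals.values():
            src = ind.clone_of
            root[ind.id] = root.get(src, src) if src else ind.id
        comps: dict[str, list[str]] = {}
        for k, r in root.items():
            comps.setdefault(r, []).append(k)
        return [sorted(v) for v in comps.values() if len(v) > 1]

    def parent_map(self) -> dict[str, tuple[tuple[str, str], tuple[str, str]]]:
        out = {}
        for ind in self.individuals.values():
            if ind.parents is not None:
                out[ind.id] = (
                    (ind.parents[0], ind.gamete_models[0]),
                    (ind.parents[1], ind.gamete_models[1]),
                )
        return out


@dataclass
class RenderedCollection:
    marker_matrix: MarkerMatrix
    ssr_profiles: list[SSRProfile]
    meta: dict[str, AccessionMeta]
    truth: TruthSet

    def ssr_by_id(self) -> dict[str, SSRProfile]:
        return {p.accession_id: p for p in self.ssr_profiles}


# ---------------------------------------------------------------------------
# founders and transmission


def simulate_founders(
    config: SimConfig,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    id_prefix: str = "F",
) -> TruthSet:
    """Unrelated diploid founders in Hardy-Weinberg proportions.

    Dominant-marker presence-allele frequencies are uniform over the
    configured range; SSR allele frequencies are symmetric-Dirichlet
    (concentration 1) over equally spaced fragment sizes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_founders if n is None else n
    truth = TruthSet(config=config)
    truth.dart_freqs = rng.uniform(*config.dart_presence_freq,
                                   size=config.n_dart_loci)
    for _ in range(config.n_ssr_loci):
        k = config.ssr_alleles_per_locus
        truth.ssr_freqs.append(rng.dirichlet(np.ones(k)))
        start = config.ssr_base_size + rng.integers(0, 40) * config.ssr_allele_step
        truth.ssr_sizes.append(
            start + config.ssr_allele_step * np.arange(k)
        )
    for i in range(n):
        ind = Individual(
            id=f"{id_prefix}{i:04d}",
            ploidy=2,
            dart=rng.binomial(2, truth.dart_freqs).astype(np.int8),
            ssr=[
                tuple(sorted(rng.choice(truth.ssr_sizes[l], size=2, replace=True,
                                        p=truth.ssr_freqs[l]).tolist()))
                for l in range(config.n_ssr_loci)
            ],
        )
        truth.individuals[ind.id] = ind
    return truth


def _gamete(
    parent: Individual, model: str, loss: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Draw one gamete (dart presence-copy vector, per-locus SSR tuple)."""
    if model == "haploid":
        if parent.ploidy != 2:
            raise ValueError(f"haploid gamete needs a diploid parent, "
                             f"{parent.id} is {parent.ploidy}x")
        # pick one of the two homologs per locus
        take_first = rng.integers(0, 2, size=len(parent.ssr)).astype(bool)
        ssr = [(al[0],) if t else (al[1],)
               for al, t in zip(parent.ssr, take_first)]
        dart = rng.hypergeometric(parent.dart, 2 - parent.dart, 1).astype(np.int8)
        return dart, ssr
    if model == "unreduced_diploid":
        if parent.ploidy != 2:
            raise ValueError(f"unreduced diploid gamete needs a diploid "
                             f"parent, {parent.id} is {parent.ploidy}x")
        ssr = []
        dart = parent.dart.copy()
        lose = rng.random(len(parent.ssr))
        keep_first = rng.integers(0, 2, size=len(parent.ssr))
        for l, al in enumerate(parent.ssr):
            if lose[l] < loss:
                kept = al[keep_first[l]]
                ssr.append((kept, kept))
            else:
                ssr.append(tuple(al))
        # crossover-loss on dominant loci: duplicate one homolog
        affected = rng.random(len(dart)) < loss
        het = parent.dart == 1
        dup_presence = rng.integers(0, 2, size=len(dart)).astype(bool)
        dart[affected & het] = np.where(dup_presence[affected & het], 2, 0)
        return dart.astype(np.int8), ssr
    if model == "triploid":
        if parent.ploidy != 3:
            raise ValueError(f"triploid gamete needs a triploid parent, "
                             f"{parent.id} is {parent.ploidy}x")
        return parent.dart.copy(), [tuple(al) for al in parent.ssr]
    raise ValueError(f"unknown gamete model {model!r}")


def cross(
    truth: TruthSet,
    parent_a: str,
    parent_b: str,
    model_a: str = "haploid",
    model_b: str = "haploid",
    child_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> Individual:
    """Cross two individuals under named gamete models; offspring ploidy is
    the sum of the transmitted complements.  Parent A is maternal (the
    unreduced gamete in heteroploid crosses is maternal by default)."""
    rng = rng if rng is not None else np.random.default_rng(truth.config.seed)
    pa, pb = truth.individuals[parent_a], truth.individuals[parent_b]
    loss = truth.config.unreduced_gamete_homozygosity_loss
    da, sa = _gamete(pa, model_a, loss, rng)
    db, sb = _gamete(pb, model_b, loss, rng)
    ploidy = {"haploid": 1, "unreduced_diploid": 2, "triploid": 3}
    child = Individual(
        id=child_id or f"X{len(truth.individuals):04d}",
        ploidy=ploidy[model_a] + ploidy[model_b],
        dart=(da + db).astype(np.int8),
        ssr=[tuple(sorted(x + y)) for x, y in zip(sa, sb)],
        parents=(parent_a, parent_b),
        gamete_models=(model_a, model_b),
    )
    truth.individuals[child.id] = child
    return child


def make_clone(
    truth: TruthSet,
    source: str,
    clone_id: str | None = None,
    rng: np.random.Generator | None = None,
    flip_rate: float | None = None,
) -> Individual:
    """A somatic mutant ('sport') of an existing individual: dominant
    band states flip independently at the clone flip rate at render time,
    SSR profile is unchanged, and the flip events are logged."""
    rng = rng if rng is not None else np.random.default_rng(truth.config.seed)
    eps = truth.config.clone_flip_rate if flip_rate is None else flip_rate
    src = truth.individuals[source]
    flips = tuple(np.flatnonzero(rng.random(len(src.dart)) < eps).tolist())
    clone = Individual(
        id=clone_id or f"{source}.c{len(truth.individuals):04d}",
        ploidy=src.ploidy,
        dart=src.dart.copy(),
        ssr=[tuple(al) for al in src.ssr],
        clone_of=source,
        flip_events=tuple(sorted(set(src.flip_events) ^ set(flips))),
    )
    truth.individuals[clone.id] = clone
    return clone


# ---------------------------------------------------------------------------
# rendering


def render_collection(
    truth: TruthSet,
    rng: np.random.Generator | None = None,
    batches: dict[str, str] | None = None,
) -> RenderedCollection:
    """Render the truth set the way the assays report it.

    Dominant calls: band present iff at least one presence allele across
    all chromosome copies (ploidy-aware), XOR any logged somatic flips;
    missing calls injected at the configured rate.  SSR: distinct allele
    sizes per locus (dosage-blind).  Metadata carries true ploidy, clone
    groups and documented parents, with a configurable fraction of parent
    entries corrupted to exercise mis-documentation handling.
    """
    cfg = truth.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    ids = truth.ids
    n, m = len(ids), cfg.n_dart_loci

    calls = np.zeros((n, m), dtype=float)
    for i, acc in enumerate(ids):
        ind = truth.individuals[acc]
        band = (ind.dart > 0).astype(float)
        if ind.flip_events:
            fl = np.array(ind.flip_events, dtype=int)
            band[fl] = 1.0 - band[fl]
        calls[i] = band
    if cfg.missing_rate > 0:
        calls[rng.random((n, m)) < cfg.missing_rate] = np.nan

    marker_ids = [f"M{j:04d}" for j in range(m)]
    df = pd.DataFrame(calls, index=ids, columns=marker_ids)
    if cfg.n_redundant_markers > 0:
        d = min(cfg.n_redundant_markers, m)
        dup = df.iloc[:, :d].copy()
        dup.columns = [f"R{j:04d}" for j in range(d)]
        df = pd.concat([df, dup], axis=1)
    matrix = MarkerMatrix(df)

    locus_ids = [f"SSR{l:02d}" for l in range(cfg.n_ssr_loci)]
    profiles = [
        SSRProfile(
            accession_id=acc,
            genotype={
                locus_ids[l]: tuple(sorted(set(al)))
                for l, al in enumerate(truth.individuals[acc].ssr)
            },
            ploidy=truth.individuals[acc].ploidy,
        )
        for acc in ids
    ]

    clone_group_of: dict[str, str] = {}
    for comp in truth.clone_components():
        label = f"CG_{comp[0]}"
        for member in comp:
            clone_group_of[member] = label

    meta: dict[str, AccessionMeta] = {}
    for acc in ids:
        ind = truth.individuals[acc]
        parents = ind.parents or ()
        if parents and cfg.corrupt_parent_rate > 0:
            parents = tuple(
                rng.choice([x for x in ids if x not in (acc, p)])
                if rng.random() < cfg.corrupt_parent_rate else p
                for p in parents
            )
        meta[acc] = AccessionMeta(
            accession_id=acc,
            cultivar_name=acc,
            ploidy=ind.ploidy,
            documented_parents=tuple(parents),
            clone_group=clone_group_of.get(acc),
            date_of_origin=OriginDate(),
        )
    return RenderedCollection(
        marker_matrix=matrix, ssr_profiles=profiles, meta=meta, truth=truth
    )


# ---------------------------------------------------------------------------
# clustering-log harness


def simulate_structure_logs(
    true_k: int,
    k_range: tuple[int, int] = (1, 10),
    n_replicates: int = 10,
    slope_before: float = 500.0,
    slope_after: float = 20.0,
    noise_base: float = 5.0,
    noise_growth: float = 15.0,
    lnp_at_k1: float = -50_000.0,
    rng: np.random.Generator | int | None = None,
) -> list[StructureRunSummary]:
    """Piecewise-linear mean ln-probability with a slope break at the true
    cluster number and replicate noise that grows past it — the elbow
    pattern delta-K is designed to locate."""
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else rng)
    k_lo, k_hi = k_range
    if not (k_lo < true_k < k_hi):
        raise ValueError("true_k must be interior to k_range")
    runs = []
    for K in range(k_lo, k_hi + 1):
        mean = lnp_at_k1 + slope_before * (min(K, true_k) - k_lo)
        if K > true_k:
            mean += slope_after * (K - true_k)
        sd = noise_base + noise_growth * max(0, K - true_k)
        for r in range(n_replicates):
            runs.append(StructureRunSummary(
                K=K, replicate=f"rep{r:02d}",
                lnP=float(mean + rng.normal(0.0, sd)),
            ))
    return runs


# ---------------------------------------------------------------------------
# default study design


def simulate_collection(
    config: SimConfig,
    n_clone_groups: int = 4,
    clones_per_group: int = 4,
    n_mothers: int = 3,
    families_per_mother: int = 2,
    sibs_per_family: int = 3,
    n_triploid_offspring: int = 8,
    add_tetraploid: bool = True,
    rng: np.random.Generator | None = None,
) -> RenderedCollection:
    """The default planted study: founders, clonal groups, diploid
    families with both full-sib (within family) and half-sib (same mother,
    different father) structure, one diploid parent with unreduced-gamete
    triploid offspring (each with a distinct second parent), and
    optionally a tetraploid from a triploid gamete."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = simulate_founders(config, rng=rng)
    founders = truth.ids

    for g in range(n_clone_groups):
        src = founders[g % len(founders)]
        for c in range(clones_per_group):
            make_clone(truth, src, clone_id=f"{src}.s{c}", rng=rng)

    fam_parents = founders[n_clone_groups:]
    need = n_mothers * (1 + families_per_mother)
    if len(fam_parents) < need:
        raise ValueError(f"need >= {n_clone_groups + need} founders")
    mothers = fam_parents[:n_mothers]
    fathers = fam_parents[n_mothers:need]
    for mi, mother in enumerate(mothers):
        for f in range(families_per_mother):
            father = fathers[mi * families_per_mother + f]
            for s in range(sibs_per_family):
                cross(truth, mother, father,
                      child_id=f"FS{mi}_{f}_{s}", rng=rng)

    tri_parent = founders[-1]
    second_parents = [founders[i] for i in
                      range(len(founders) - 1 - n_triploid_offspring,
                            len(founders) - 1)]
    triploids = []
    for t, other in enumerate(second_parents):
        child = cross(truth, tri_parent, other,
                      model_a="unreduced_diploid", model_b="haploid",
                      child_id=f"TRI{t}", rng=rng)
        triploids.append(child.id)

    if add_tetraploid and triploids:
        cross(truth, triploids[0], founders[0],
              model_a="triploid", model_b="haploid",
              child_id="TET0", rng=rng)

    return render_collection(truth, rng=rng)
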