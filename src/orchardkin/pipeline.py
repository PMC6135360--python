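"""End-to-end orchestration: screen -> similarity -> clone collapse ->
close groups -> ploidy partition -> SSR parentage verification -> tier
summaries, with table-shaped reports written to an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    CloneCollapse,
    CloseGroup,
    Thresholds,
    collapse_clones,
    find_close_groups,
    tier_summaries,
)
from .io import (
    AccessionMeta,
    MarkerMatrix,
    SSRProfile,
    screen_markers,
)
from .pedigree import (
    GameteModel,
    IndeterminateError,
    diploid_complement_in_triploid,
    infer_missing_parent,
    triploid_complement_in_tetraploid,
)
from .similarity import (
    SimilarityMatrix,
    group_stats,
    pairwise_matrix,
    write_similarity_long,
)

logger = logging.getLogger("orchardkin")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "report_tables"]


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    batches: dict[str, str] | None = None
    redundancy_mode: str = "identical_scores"
    keep_list: list[str] | None = None
    ssr_tolerance: int = 1
    ssr_conflict_loci: int = 2
    seed: int = 0
    out_dir: str | Path | None = None


@dataclass
class PipelineResult:
    screening_report: pd.DataFrame
    similarity: SimilarityMatrix
    collapse: CloneCollapse
    similarity_reduced: SimilarityMatrix
    close_groups: list[CloseGroup]
    clone_stats: pd.DataFrame
    tier_table: pd.DataFrame
    heteroploid_assessments: pd.DataFrame
    exclusion_searches: pd.DataFrame
    manifest: dict


def _clone_stats_table(
    sim: SimilarityMatrix, meta: dict[str, AccessionMeta] | None
) -> pd.DataFrame:
    """Documented-clone-group baseline statistics (cultivar, n_clones,
    max, min within-group, max vs any non-member)."""
    cols = ["cultivar", "n_clones", "max_clone_similarity",
            "min_clone_similarity", "max_non_clone_similarity"]
    if not meta:
        return pd.DataFrame(columns=cols)
    groups = {
        a: m.clone_group for a, m in meta.items()
        if m.clone_group and a in set(sim.accession_ids)
    }
    rows = [
        {
            "cultivar": st.group,
            "n_clones": st.n_members,
            "max_clone_similarity": round(st.max_within, 3),
            "min_clone_similarity": round(st.min_within, 3),
            "max_non_clone_similarity": round(st.max_vs_nonmember, 3),
        }
        for st in group_stats(sim, groups)
        if st.n_members >= 2
    ]
    return pd.DataFrame(rows, columns=cols)


def _verify_heteroploid_groups(
    groups: list[CloseGroup],
    meta: dict[str, AccessionMeta],
    ssr: dict[str, SSRProfile],
    tolerance: int,
) -> pd.DataFrame:
    """Within each heteroploid group, test every lower-ploidy member as the
    unreduced-gamete donor for every higher-ploidy member."""
    rows = []
    for gi, grp in enumerate(groups):
        if grp.group_class != "heteroploid_group":
            continue
        for parent in grp.members:
            for child in grp.members:
                pp = grp.ploidy_profile.get(parent, 0)
                cp = grp.ploidy_profile.get(child, 0)
                if parent == child or not pp or not cp or pp >= cp:
                    continue
                if parent not in ssr or child not in ssr:
                    continue
                try:
                    if pp == 2 and cp == 3:
                        ass = diploid_complement_in_triploid(
                            ssr[parent], ssr[child], tolerance=tolerance)
                    elif pp == 3 and cp == 4:
                        ass = triploid_complement_in_tetraploid(
                            ssr[parent], ssr[child])
                    else:
                        continue
                except IndeterminateError:
                    continue
                counts = ass.locus_categories
                rows.append({
                    "group": gi,
                    "parent": parent,
                    "offspring": child,
                    "gamete_model": ass.gamete_model.value,
                    "overall": ass.overall,
                    "n_inconsistent": ass.n_inconsistent,
                    "n_tolerated": ass.n_tolerated,
                    "n_full_complement": counts.get("full_complement", 0),
                    "n_indistinguishable": counts.get("indistinguishable", 0),
                    "n_partial": counts.get("partial", 0),
                })
    return pd.DataFrame(rows, columns=[
        "group", "parent", "offspring", "gamete_model", "overall",
        "n_inconsistent", "n_tolerated", "n_full_complement",
        "n_indistinguishable", "n_partial",
    ])


def _exclusion_searches(
    groups: list[CloseGroup],
    meta: dict[str, AccessionMeta],
    ssr: dict[str, SSRProfile],
) -> pd.DataFrame:
    """For diploid close groups whose members have exactly one documented
    parent with an SSR profile, run the second-parent exclusion search
    against the full profiled panel."""
    panel = list(ssr.values())
    name_to_id = {}
    for a, m in meta.items():
        name_to_id.setdefault(m.cultivar_name or a, a)
        name_to_id.setdefault(a, a)
    rows = []
    for gi, grp in enumerate(groups):
        if grp.group_class != "diploid_sibling_group":
            continue
        for member in grp.members:
            m = meta.get(member)
            if m is None or len(m.documented_parents) != 1:
                continue
            pid = name_to_id.get(m.documented_parents[0])
            if pid is None or pid not in ssr or member not in ssr:
                continue
            try:
                survivors, unique = infer_missing_parent(
                    ssr[member], ssr[pid], panel, model=GameteModel.haploid)
            except Exception as exc:  # noqa: BLE001
                logger.warning("exclusion search failed for %s: %s", member, exc)
                continue
            rows.append({
                "group": gi,
                "offspring": member,
                "known_parent": pid,
                "n_candidates": len(survivors),
                "unique": unique,
                "top_candidates": ";".join(
                    c.candidate_id for c in survivors[:5]),
            })
    return pd.DataFrame(rows, columns=[
        "group", "offspring", "known_parent", "n_candidates", "unique",
        "top_candidates",
    ])


def run_pipeline(
    matrix: MarkerMatrix,
    meta: dict[str, AccessionMeta] | None = None,
    ssr_profiles: list[SSRProfile] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full analysis chain on in-memory inputs.

    SSR input is optional: without it the parentage-verification stages
    are skipped with a warning and everything through close groups and
    tier summaries still runs.  Output is a pure function of
    (inputs, config).
    """
    cfg = config or PipelineConfig()
    meta = meta or {}
    ssr = {p.accession_id: p for p in (ssr_profiles or [])}

    logger.info("stage screen: %d markers in", matrix.n_markers)
    screened, screen_report = screen_markers(
        matrix, batches=cfg.batches, redundancy_mode=cfg.redundancy_mode,
        keep_list=cfg.keep_list)

    logger.info("stage similarity: %d accessions", screened.n_accessions)
    sim = pairwise_matrix(screened)
    clone_stats = _clone_stats_table(sim, meta)

    logger.info("stage collapse")
    collapse = collapse_clones(
        sim, meta=meta, ssr_profiles=ssr or None,
        thresholds=cfg.thresholds, keep_list=cfg.keep_list,
        ssr_conflict_loci=cfg.ssr_conflict_loci)
    sim_reduced = sim.subset(sorted(collapse.representatives))

    logger.info("stage groups")
    close_groups = find_close_groups(sim_reduced, meta=meta,
                                     thresholds=cfg.thresholds)

    tier_table = tier_summaries(sim_reduced, meta)

    if ssr:
        het = _verify_heteroploid_groups(close_groups, meta, ssr,
                                         cfg.ssr_tolerance)
        excl = _exclusion_searches(close_groups, meta, ssr)
    else:
        logger.warning("no SSR input: parentage verification skipped")
        het = _verify_heteroploid_groups([], {}, {}, 0)
        excl = _exclusion_searches([], {}, {})

    manifest = {
        "orchardkin_version": __version__,
        "thresholds": {"clone": cfg.thresholds.clone,
                       "close": cfg.thresholds.close,
                       "borderline": cfg.thresholds.borderline},
        "redundancy_mode": cfg.redundancy_mode,
        "ssr_tolerance": cfg.ssr_tolerance,
        "ssr_conflict_loci": cfg.ssr_conflict_loci,
        "seed": cfg.seed,
        "n_accessions": screened.n_accessions,
        "n_markers_screened": screened.n_markers,
        "n_clone_components": sum(1 for c in collapse.components if len(c) > 1),
        "n_close_groups": len(close_groups),
    }

    result = PipelineResult(
        screening_report=screen_report,
        similarity=sim,
        collapse=collapse,
        similarity_reduced=sim_reduced,
        close_groups=close_groups,
        clone_stats=clone_stats,
        tier_table=tier_table,
        heteroploid_assessments=het,
        exclusion_searches=excl,
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        report_tables(result, cfg.out_dir)
    return result


def report_tables(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the report bundle: one CSV per table shape (similarity to 3
    decimals), a DOT graph of the close groups, and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    save(result.screening_report, "screening_report.csv")
    save(result.clone_stats, "clone_stats.csv")
    save(result.tier_table, "tier_summaries.csv")
    save(result.heteroploid_assessments, "heteroploid_assessments.csv")
    save(result.exclusion_searches, "exclusion_searches.csv")

    comp_rows = [
        {"representative": rep, "members": ";".join(comp), "n": len(comp)}
        for rep, comp in zip(result.collapse.representatives,
                             result.collapse.components)
        if len(comp) > 1
    ]
    save(pd.DataFrame(comp_rows,
                      columns=["representative", "members", "n"]),
         "clone_components.csv")

    grp_rows = [
        {
            "group": gi,
            "group_class": g.group_class,
            "members": ";".join(g.members),
            "n_members": len(g.members),
            "ploidy_profile": ";".join(
                f"{m}:{p or '?'}" for m, p in g.ploidy_profile.items()),
        }
        for gi, g in enumerate(result.close_groups)
    ]
    save(pd.DataFrame(grp_rows, columns=[
        "group", "group_class", "members", "n_members", "ploidy_profile",
    ]), "close_groups.csv")

    p = out / "similarity_long.csv"
    write_similarity_long(result.similarity, p)
    written.append(p)

    dot_lines = ["graph close_groups {"]
    for g in result.close_groups:
        for a, b, s in g.edges:
            dot_lines.append(f'  "{a}" -- "{b}" [label="{s:.3f}"];')
    dot_lines.append("}")
    p = out / "close_groups.dot"
    p.write_text("\n".join(dot_lines) + "\n")
    written.append(p)

    p = out / "manifest.json"
    p.write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written
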