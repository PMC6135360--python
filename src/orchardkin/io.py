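"""Readers, writers and validators for the tables the pipeline touches.

Four table kinds flow through the analysis:

* binary (dominant) marker matrices — accessions x markers, band
  present/absent with missing calls;
* accession metadata — provenance, ploidy, documented parents, clone groups;
* SSR genotype tables — per accession and locus, 1-4 integer allele sizes
  (codominant, dosage-blind);
* clustering-run summaries — (K, replicate, ln probability of data).

Marker matrices are held as a pandas DataFrame of floats (1.0 band present,
0.0 absent, NaN missing); SSR genotypes as per-locus sorted tuples of allele
sizes.  A single reported size at a locus means "at least one copy, possibly
homozygous" — copy number is never inferred at read time.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntegrityError",
    "ParseError",
    "MarkerMatrix",
    "AccessionMeta",
    "SSRProfile",
    "StructureRunSummary",
    "OriginDate",
    "read_marker_matrix",
    "write_marker_matrix",
    "screen_markers",
    "read_accession_meta",
    "write_accession_meta",
    "read_ssr_table",
    "write_ssr_table",
    "read_structure_runs",
    "write_structure_runs",
    "parse_origin_date",
]


class IntegrityError(ValueError):
    """A structural invariant of an input table is violated."""


class ParseError(ValueError):
    """A cell could not be interpreted under the declared dialect."""


DEFAULT_MISSING_CODES = ("", "NA", "-", "nan", "NaN")


@dataclass
class MarkerMatrix:
    """Accessions x binary markers with missing states.

    ``calls`` is a float DataFrame: 1.0 = band present, 0.0 = absent,
    NaN = missing.  ``batch_of_marker`` optionally labels each marker with
    the assay batch it was scored in (used by :func:`screen_markers`).
    """

    calls: pd.DataFrame
    batch_of_marker: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.calls.index.duplicated().any():
            dup = self.calls.index[self.calls.index.duplicated()][0]
            raise IntegrityError(f"duplicate accession id {dup!r}")
        if self.calls.columns.duplicated().any():
            dup = self.calls.columns[self.calls.columns.duplicated()][0]
            raise IntegrityError(f"duplicate marker id {dup!r}")
        vals = self.calls.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise IntegrityError(
                f"non-binary call {vals[i, j]!r} at accession "
                f"{self.calls.index[i]!r}, marker {self.calls.columns[j]!r}"
            )
        all_missing = np.isnan(vals).all(axis=1)
        if all_missing.any():
            acc = self.calls.index[np.argmax(all_missing)]
            raise IntegrityError(f"accession {acc!r} has no non-missing call")
        if self.batch_of_marker is not None:
            missing = set(self.calls.columns) - set(self.batch_of_marker.index)
            if missing:
                raise IntegrityError(
                    f"markers without batch label: {sorted(missing)[:5]}"
                )

    @property
    def accession_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def subset_accessions(self, ids: list[str]) -> "MarkerMatrix":
        return MarkerMatrix(self.calls.loc[ids], self.batch_of_marker)


@dataclass
class OriginDate:
    """A documented date of origin: a year plus a 'pre' (at-or-before) flag."""

    year: int | None = None
    pre: bool = False
    raw: str = ""


def parse_origin_date(text: str | None) -> OriginDate:
    """Extract the year and 'pre' flag from free-text provenance dates.

    Handles forms like ``1897``, ``pre 1800``, ``pre-1750``, ``c.1820``;
    anything without a 4-digit year parses to an unknown date.
    """
    raw = "" if text is None else str(text).strip()
    if not raw or raw in ("-", "nan"):
        return OriginDate(raw=raw)
    m = re.search(r"(\d{4})", raw)
    if not m:
        return OriginDate(raw=raw)
    pre = bool(re.search(r"\bpre\b|pre-", raw, flags=re.IGNORECASE))
    return OriginDate(year=int(m.group(1)), pre=pre, raw=raw)


@dataclass
class AccessionMeta:
    accession_id: str
    cultivar_name: str = ""
    country: str = ""
    date_of_origin: OriginDate = field(default_factory=OriginDate)
    ploidy: int | None = None  # 2, 3, 4 or None (unknown)
    documented_parents: tuple[str, ...] = ()
    clone_group: str | None = None
    subset_flag: bool = True

    def __post_init__(self) -> None:
        if self.ploidy not in (None, 2, 3, 4):
            raise IntegrityError(
                f"{self.accession_id}: ploidy {self.ploidy!r} not in {{2,3,4,unknown}}"
            )
        if self.accession_id in self.documented_parents:
            raise IntegrityError(f"{self.accession_id}: listed as its own parent")


@dataclass
class SSRProfile:
    """Per-accession SSR genotype: locus -> sorted tuple of allele sizes (bp).

    The tuple is a multiset of *reported* sizes; duplicated entries appear
    only when the source table repeated them explicitly.
    """

    accession_id: str
    genotype: dict[str, tuple[int, ...]] = field(default_factory=dict)
    ploidy: int | None = None
    truncated_loci: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for locus, alleles in self.genotype.items():
            if any(a <= 0 for a in alleles):
                raise IntegrityError(
                    f"{self.accession_id}/{locus}: non-positive allele size"
                )

    def loci(self) -> list[str]:
        return list(self.genotype)

    def alleles(self, locus: str) -> tuple[int, ...]:
        return self.genotype.get(locus, ())


@dataclass(frozen=True)
class StructureRunSummary:
    K: int
    replicate: str
    lnP: float

    def __post_init__(self) -> None:
        if self.K < 1:
            raise IntegrityError(f"K must be >=1, got {self.K}")


# ---------------------------------------------------------------------------
# marker matrices


def read_marker_matrix(
    path,
    sep: str | None = None,
    present: str = "1",
    absent: str = "0",
    missing: tuple[str, ...] = DEFAULT_MISSING_CODES,
    batch_of_marker: dict[str, str] | None = None,
) -> MarkerMatrix:
    """Read a delimited accession x marker table of 0/1/missing calls.

    First row holds marker ids, first column accession ids.  The codes for
    present/absent/missing are configurable; unrecognized tokens raise
    :class:`ParseError` naming the offending cell.
    """
    engine = "python" if sep is None else "c"
    # pandas de-duplicates repeated header names silently; check them raw
    header = pd.read_csv(path, sep=sep, engine=engine, dtype=str,
                         header=None, nrows=1, keep_default_na=False)
    raw_markers = [str(t).strip() for t in header.iloc[0, 1:]]
    if len(set(raw_markers)) != len(raw_markers):
        dup = next(m for m in raw_markers if raw_markers.count(m) > 1)
        raise IntegrityError(f"duplicate marker id {dup!r}")
    df = pd.read_csv(
        path, sep=sep, engine=engine,
        dtype=str, index_col=0, keep_default_na=False,
    )
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()

    mapping = {present: 1.0, absent: 0.0}
    mapping.update({m: np.nan for m in missing})
    out = np.empty(df.shape, dtype=float)
    raw = df.to_numpy(dtype=str)
    for (i, j), tok in np.ndenumerate(raw):
        tok = tok.strip()
        try:
            out[i, j] = mapping[tok]
        except KeyError:
            raise ParseError(
                f"unrecognized call {tok!r} at accession {df.index[i]!r}, "
                f"marker {df.columns[j]!r}"
            ) from None
    calls = pd.DataFrame(out, index=df.index, columns=df.columns)
    batches = None
    if batch_of_marker is not None:
        batches = pd.Series(batch_of_marker, dtype=str)
    return MarkerMatrix(calls, batches)


def write_marker_matrix(
    matrix: MarkerMatrix, path, sep: str = ",", missing_code: str = "NA"
) -> None:
    df = matrix.calls.map(
        lambda v: missing_code if np.isnan(v) else str(int(v))
    )
    df.to_csv(path, sep=sep, index_label="accession")


def screen_markers(
    matrix: MarkerMatrix,
    batches: dict[str, str] | None = None,
    redundancy_mode: str = "identical_scores",
    keep_list: list[str] | None = None,
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Apply the two marker-screening stages and return a screening report.

    Stage 1 (batch intersection): ``batches`` maps each accession to the
    assay batch it was genotyped in; a marker survives only if it *reported*
    — has at least one non-missing call — within every batch.  With no
    batch map (single batch) the stage passes everything through.  Stage 2
    (redundancy): under ``identical_scores``, markers with identical call
    vectors (missing pattern included) are collapsed to the
    lexicographically first id; under ``provided_list`` an explicit
    keep-list is applied instead.

    Surviving call values are never altered, and the operation is idempotent.
    """
    calls = matrix.calls
    report_rows = []

    n_in = calls.shape[1]
    if batches is not None:
        batch_ser = pd.Series({a: batches[a] for a in calls.index})
        observed = calls.notna()
        reported_everywhere = pd.Series(True, index=calls.columns)
        for _, accs in batch_ser.groupby(batch_ser):
            reported_everywhere &= observed.loc[accs.index].any(axis=0)
        calls = calls.loc[:, reported_everywhere]
    report_rows.append(("batch_intersection", n_in, calls.shape[1]))

    n_in = calls.shape[1]
    if redundancy_mode == "provided_list":
        if keep_list is None:
            raise ValueError("provided_list mode requires keep_list")
        keep = [mk for mk in calls.columns if mk in set(keep_list)]
        calls = calls[keep]
    elif redundancy_mode == "identical_scores":
        sig_to_id: dict[bytes, str] = {}
        for mk in sorted(calls.columns):
            sig = calls[mk].to_numpy(dtype=float).tobytes()
            sig_to_id.setdefault(sig, mk)
        survivors = set(sig_to_id.values())
        calls = calls[[mk for mk in calls.columns if mk in survivors]]
    else:
        raise ValueError(f"unknown redundancy_mode {redundancy_mode!r}")
    report_rows.append(("redundancy", n_in, calls.shape[1]))

    if calls.shape[1] == 0:
        raise IntegrityError("no markers survive screening")

    report = pd.DataFrame(report_rows, columns=["stage", "markers_in", "markers_out"])
    marker_batches = (
        matrix.batch_of_marker.loc[calls.columns]
        if matrix.batch_of_marker is not None
        else None
    )
    return MarkerMatrix(calls, marker_batches), report


# ---------------------------------------------------------------------------
# accession metadata


_META_COLUMNS = [
    "accession_id", "cultivar_name", "country", "date_of_origin", "ploidy",
    "parent_1", "parent_2", "clone_group", "subset_flag",
]


def read_accession_meta(path, sep: str = ",") -> dict[str, AccessionMeta]:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = set(_META_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"metadata table lacks columns: {sorted(missing_cols)}")
    out: dict[str, AccessionMeta] = {}
    for _, row in df.iterrows():
        acc = row["accession_id"].strip()
        if acc in out:
            raise IntegrityError(f"duplicate accession id {acc!r} in metadata")
        ploidy_tok = row["ploidy"].strip().rstrip("x")
        ploidy = int(ploidy_tok) if ploidy_tok.isdigit() else None
        parents = tuple(
            p.strip() for p in (row["parent_1"], row["parent_2"]) if p.strip()
        )
        out[acc] = AccessionMeta(
            accession_id=acc,
            cultivar_name=row["cultivar_name"].strip(),
            country=row["country"].strip(),
            date_of_origin=parse_origin_date(row["date_of_origin"]),
            ploidy=ploidy,
            documented_parents=parents,
            clone_group=row["clone_group"].strip() or None,
            subset_flag=row["subset_flag"].strip().lower() not in ("no", "false", "0"),
        )
    return out


def write_accession_meta(meta: dict[str, AccessionMeta], path, sep: str = ",") -> None:
    rows = []
    for m in meta.values():
        parents = list(m.documented_parents) + ["", ""]
        rows.append({
            "accession_id": m.accession_id,
            "cultivar_name": m.cultivar_name,
            "country": m.country,
            "date_of_origin": m.date_of_origin.raw,
            "ploidy": "" if m.ploidy is None else str(m.ploidy),
            "parent_1": parents[0],
            "parent_2": parents[1],
            "clone_group": m.clone_group or "",
            "subset_flag": "yes" if m.subset_flag else "no",
        })
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# SSR tables


def read_ssr_table(
    path,
    sep: str = ",",
    ploidy_of: dict[str, int] | None = None,
) -> list[SSRProfile]:
    """Read a long-form SSR table: accession, locus, up to 4 allele columns.

    Blank allele cells are missing.  When an accession's known ploidy is
    exceeded by the reported allele count the record is truncated to ploidy
    and flagged (never silently dropped).
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ParseError("SSR table needs accession, locus and >=1 allele column")
    acc_col, locus_col = df.columns[0], df.columns[1]
    allele_cols = list(df.columns[2:6])

    genotypes: dict[str, dict[str, tuple[int, ...]]] = {}
    truncated: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        acc = row[acc_col].strip()
        locus = row[locus_col].strip()
        alleles = []
        for c in allele_cols:
            tok = row[c].strip()
            if not tok or tok in DEFAULT_MISSING_CODES:
                continue
            try:
                size = int(float(tok))
            except ValueError:
                raise ParseError(
                    f"bad allele size {tok!r} for {acc!r} at {locus!r}"
                ) from None
            alleles.append(size)
        if not alleles:
            continue
        ploidy = (ploidy_of or {}).get(acc)
        if ploidy is not None and len(alleles) > ploidy:
            warnings.warn(
                f"{acc}/{locus}: {len(alleles)} alleles exceed ploidy {ploidy}; "
                "truncating and flagging",
                stacklevel=2,
            )
            alleles = alleles[:ploidy]
            truncated.setdefault(acc, []).append(locus)
        g = genotypes.setdefault(acc, {})
        if locus in g:
            raise IntegrityError(f"duplicate locus {locus!r} for accession {acc!r}")
        g[locus] = tuple(sorted(alleles))

    return [
        SSRProfile(
            accession_id=acc,
            genotype=g,
            ploidy=(ploidy_of or {}).get(acc),
            truncated_loci=tuple(truncated.get(acc, ())),
        )
        for acc, g in genotypes.items()
    ]


def write_ssr_table(profiles: list[SSRProfile], path, sep: str = ",") -> None:
    rows = []
    for p in profiles:
        for locus in sorted(p.genotype):
            alleles = list(p.genotype[locus])[:4]
            alleles += [""] * (4 - len(alleles))
            rows.append([p.accession_id, locus, *alleles])
    pd.DataFrame(
        rows, columns=["accession_id", "locus", "allele_1", "allele_2",
                       "allele_3", "allele_4"]
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# clustering-run summaries


def read_structure_runs(path, sep: str = ",") -> list[StructureRunSummary]:
    """Read a (K, replicate, lnP) CSV, validated and sorted by K.

    K values with a single replicate are accepted (the ΔK denominator is
    undefined there and flagged downstream); a duplicated (K, replicate)
    pair is an integrity error.
    """
    df = pd.read_csv(path, sep=sep)
    needed = {"K", "replicate", "lnP"}
    if not needed.issubset(df.columns):
        raise ParseError(f"runs table needs columns {sorted(needed)}")
    seen = set()
    runs = []
    for _, row in df.iterrows():
        key = (int(row["K"]), str(row["replicate"]))
        if key in seen:
            raise IntegrityError(f"duplicate (K, replicate) entry {key}")
        seen.add(key)
        runs.append(StructureRunSummary(K=key[0], replicate=key[1],
                                        lnP=float(row["lnP"])))
    runs.sort(key=lambda r: (r.K, r.replicate))
    return runs


def write_structure_runs(runs: list[StructureRunSummary], path, sep: str = ",") -> None:
    pd.DataFrame(
        [(r.K, r.replicate, r.lnP) for r in runs],
        columns=["K", "replicate", "lnP"],
    ).to_csv(path, sep=sep, index=False)
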