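"""Readers, writers and validated containers for the pipeline's file formats.

All tables travel as plain TSV/CSV with ids as opaque, case-sensitive
strings.  Count tables are oriented taxa x samples; the transposed
orientation is only accepted behind an explicit flag, never auto-detected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

SEGMENTS = ("duodenum", "jejunum", "ileum", "caecum")
AGES = (11, 25, 34, 46)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Integer taxon x sample count table.

    Parameters
    ----------
    df : pandas.DataFrame
        Rows are taxa, columns are samples, values non-negative integers.
    allow_empty_samples : bool
        Permit all-zero sample columns (default False).
    """

    df: pd.DataFrame
    allow_empty_samples: bool = False

    def __post_init__(self) -> None:
        _check_unique(list(self.df.index), "taxon")
        _check_unique(list(self.df.columns), "sample")
        values = self.df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise FormatError("counts must be integers")
            self.df = self.df.astype(np.int64)
            values = self.df.to_numpy()
        if values.size and values.min() < 0:
            raise FormatError("counts must be non-negative")
        if not self.allow_empty_samples and values.size:
            empty = self.df.columns[values.sum(axis=0) == 0]
            if len(empty):
                raise FormatError(
                    f"sample(s) with all-zero counts: {', '.join(map(str, empty))}"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def sample_totals(self) -> pd.Series:
        return self.df.sum(axis=0)


@dataclass
class RelAbundanceMatrix:
    """Column-normalized composition: every sample column sums to 1."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(list(self.df.index), "taxon")
        _check_unique(list(self.df.columns), "sample")
        values = self.df.to_numpy(dtype=float)
        if values.size:
            if values.min() < 0:
                raise FormatError("relative abundances must be non-negative")
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.df.columns[~np.isclose(sums, 1.0, atol=1e-9)]
                raise FormatError(
                    f"sample column(s) do not sum to 1: {', '.join(map(str, bad))}"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)


@dataclass
class TaxonomyTable:
    """Seven-rank assignment per taxon; lower ranks may be missing (NaN).

    Invariant: if a rank is missing, every rank below it is missing too
    (no species without a genus).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.df.columns]
        if missing:
            raise FormatError(f"taxonomy missing rank column(s): {', '.join(missing)}")
        _check_unique(list(self.df.index), "taxon")
        self.df = self.df[list(RANKS)]
        present = self.df.notna().to_numpy()
        # once a rank is absent all deeper ranks must be absent
        for row, tid in zip(present, self.df.index):
            seen_gap = False
            for ok in row:
                if seen_gap and ok:
                    raise FormatError(
                        f"taxon {tid!r}: rank assigned below a missing rank"
                    )
                if not ok:
                    seen_gap = True

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.df.index)

    def candidates_for_species_refinement(self) -> list[str]:
        """Taxa with a genus but no species."""
        has_genus = self.df["genus"].notna()
        no_species = self.df["species"].isna()
        return list(self.df.index[has_genus & no_species])


@dataclass
class SampleMetadata:
    """Per-sample design factors: intestine segment, age (days), pen."""

    df: pd.DataFrame
    segments: tuple[str, ...] = SEGMENTS
    ages: tuple[int, ...] = AGES

    def __post_init__(self) -> None:
        for col in ("segment", "age_days", "pen"):
            if col not in self.df.columns:
                raise FormatError(f"metadata missing column {col!r}")
        _check_unique(list(self.df.index), "sample")
        bad_seg = set(self.df["segment"]) - set(self.segments)
        if bad_seg:
            raise FormatError(
                f"unknown segment level(s) {sorted(bad_seg)}; "
                f"allowed: {list(self.segments)}"
            )
        self.df["age_days"] = self.df["age_days"].astype(int)
        bad_age = set(self.df["age_days"]) - set(self.ages)
        if bad_age:
            raise FormatError(
                f"unknown age level(s) {sorted(bad_age)}; allowed: {list(self.ages)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.df.index]
        if missing:
            raise FormatError(f"samples without metadata: {', '.join(missing)}")

    def groups(self, factors: Sequence[str]) -> pd.Series:
        """Group label per sample from one or more factor columns."""
        for f in factors:
            if f not in self.df.columns:
                raise FormatError(f"unknown metadata factor {f!r}")
        if len(factors) == 1:
            return self.df[factors[0]].astype(str)
        return self.df[list(factors)].astype(str).agg("_".join, axis=1)


BLAST_COLUMNS = (
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bitscore",
)


@dataclass
class BlastHitTable:
    """BLAST hits with identity, query coverage and subject species resolved."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("query_id", "subject_id", "subject_species",
                    "percent_identity", "percent_query_coverage", "bitscore"):
            if col not in self.df.columns:
                raise FormatError(f"hit table missing column {col!r}")
        ident = self.df["percent_identity"].to_numpy(dtype=float)
        cov = self.df["percent_query_coverage"].to_numpy(dtype=float)
        if ident.size and (ident.min() < 0 or ident.max() > 100):
            raise FormatError("percent_identity outside [0, 100]")
        if cov.size and (cov.min() < 0 or cov.max() > 100.05):
            raise FormatError("percent_query_coverage outside [0, 100]")

    def __len__(self) -> int:
        return len(self.df)

    def hits_for(self, query_id: str) -> pd.DataFrame:
        return self.df[self.df["query_id"] == query_id]


def species_from_subject_id(subject_id: str) -> str:
    """Resolve species text from a subject id.

    Convention: ``<accession>|<Species_name>`` with underscores for spaces;
    a bare id is returned unchanged.
    """
    if "|" in subject_id:
        return subject_id.rsplit("|", 1)[1].replace("_", " ")
    return subject_id


# ---------------------------------------------------------------------------
# readers


def read_count_table(path: str | Path, transposed: bool = False,
                     allow_empty_samples: bool = False) -> CountMatrix:
    """Read a taxa x samples TSV count table.

    ``transposed=True`` declares the file is samples x taxa; the orientation
    is never guessed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if transposed:
        df = df.T
    try:
        return CountMatrix(df, allow_empty_samples=allow_empty_samples)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    matrix.df.to_csv(path, sep="\t", index_label="taxon_id")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return TaxonomyTable(df)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    taxonomy.df.to_csv(path, sep="\t", index_label="taxon_id")


def read_metadata(path: str | Path, segments: Sequence[str] = SEGMENTS,
                  ages: Sequence[int] = AGES) -> SampleMetadata:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, skipinitialspace=True)
    df.index = df.index.astype(str)
    df["segment"] = df["segment"].astype(str).str.strip()
    return SampleMetadata(df, segments=tuple(segments), ages=tuple(ages))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.df.to_csv(path, index_label="sample_id")


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Sequence lengths keyed by record id (text up to first whitespace)."""
    lengths: dict[str, int] = {}
    current: str | None = None
    n = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if current is not None:
                    lengths[current] = n
                current = line[1:].split()[0]
                if current in lengths:
                    raise FormatError(f"duplicate FASTA id: {current!r}")
                n = 0
            elif line:
                n += len(line)
    if current is not None:
        lengths[current] = n
    return lengths


def read_blast_tabular(path: str | Path, query_lengths: Mapping[str, int],
                       species_map: Mapping[str, str] | None = None
                       ) -> BlastHitTable:
    """Read a 12-column outfmt-6 hit file (optional 13th column = qcovs).

    Coverage comes from the qcovs column when present, else it is computed
    as alignment_length / query_length x 100.  Species text is resolved via
    ``species_map`` or from the subject id.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise FormatError(
                    f"{path}:{lineno}: expected 12 or 13 tab-separated "
                    f"columns, found {len(parts)}"
                )
            try:
                rec = dict(zip(BLAST_COLUMNS, parts))
                rec["percent_identity"] = float(rec["percent_identity"])
                rec["alignment_length"] = int(rec["alignment_length"])
                rec["bitscore"] = float(rec["bitscore"])
                qcovs = float(parts[12]) if len(parts) == 13 else None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from None
            qid = rec["query_id"]
            if qid not in query_lengths:
                raise FormatError(f"{path}:{lineno}: unknown query id {qid!r}")
            if qcovs is None:
                qcovs = 100.0 * rec["alignment_length"] / query_lengths[qid]
            sid = rec["subject_id"]
            if species_map is not None:
                if sid not in species_map:
                    raise FormatError(
                        f"{path}:{lineno}: subject {sid!r} absent from species map"
                    )
                species = species_map[sid]
            else:
                species = species_from_subject_id(sid)
            rows.append(
                (qid, sid, species, rec["percent_identity"], qcovs, rec["bitscore"])
            )
    df = pd.DataFrame(
        rows,
        columns=["query_id", "subject_id", "subject_species",
                 "percent_identity", "percent_query_coverage", "bitscore"],
    )
    return BlastHitTable(df)


def write_blast_tabular(hits: BlastHitTable, path: str | Path,
                        query_lengths: Mapping[str, int]) -> None:
    """Write hits in the 12-column dialect read_blast_tabular accepts."""
    with open(path, "w") as fh:
        for rec in hits.df.itertuples(index=False):
            qlen = query_lengths[rec.query_id]
            alen = int(round(rec.percent_query_coverage / 100.0 * qlen))
            fh.write("\t".join(map(str, (
                rec.query_id, rec.subject_id, rec.percent_identity, alen,
                0, 0, 1, alen, 1, alen, 0.0, rec.bitscore))) + "\n")


# ---------------------------------------------------------------------------
# matrix / network / venn writers


def write_matrix(df: pd.DataFrame, path: str | Path,
                 index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_network(network, path_edges: str | Path,
                  path_nodes: str | Path) -> None:
    """Write a VariableNetwork as an edge list plus node-coordinate table."""
    with open(path_edges, "w") as fh:
        fh.write("source\ttarget\tdissimilarity\n")
        for u, v, d in network.edges:
            fh.write(f"{u}\t{v}\t{d:.6f}\n")
    with open(path_nodes, "w") as fh:
        fh.write("node\ttype\tx\ty\n")
        for node, (kind, x, y) in network.node_table.items():
            fh.write(f"{node}\t{kind}\t{x:.6f}\t{y:.6f}\n")


def write_venn(regions: Mapping[tuple[str, ...], Sequence[str]],
               path: str | Path) -> None:
    """Venn regions as TSV: region (group names joined by '&'), count, taxa."""
    with open(path, "w") as fh:
        fh.write("region\tcount\ttaxa\n")
        for groups in sorted(regions, key=lambda g: (len(g), g)):
            taxa = sorted(regions[groups])
            fh.write(f"{'&'.join(groups)}\t{len(taxa)}\t{','.join(taxa)}\n")


def read_venn(path: str | Path) -> dict[tuple[str, ...], list[str]]:
    out: dict[tuple[str, ...], list[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("region"):
            raise FormatError(f"{path}: not a Venn region table")
        for line in fh:
            region, count, taxa = line.rstrip("\n").split("\t")
            members = taxa.split(",") if taxa else []
            if len(members) != int(count):
                raise FormatError(f"{path}: count mismatch in region {region!r}")
            out[tuple(region.split("&"))] = members
    return out


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
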