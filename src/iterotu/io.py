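"""FASTA input/output, exact deduplication and cluster serialization.

Multiplicities use the USEARCH-style ``;size=K`` header suffix, the de
facto standard for dereplicated amplicon data.  Files ending in ``.gz``
are transparently decompressed/compressed.
"""

from __future__ import annotations

import csv
import gzip
from collections import defaultdict
from pathlib import Path
from typing import Iterable, TextIO

from .align import Cluster
from .records import Dataset, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "deduplicate",
    "write_clusters",
    "read_clusters",
]

CLUSTER_TSV_COLUMNS = [
    "cluster_id",
    "representative_id",
    "member_id",
    "member_multiplicity",
    "similarity_to_representative",
]


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode)  # type: ignore[return-value]
    return open(p, mode)


def _parse_header(header: str) -> tuple[str, int]:
    """Split a FASTA header into (id, multiplicity).

    The id is the first whitespace token; a trailing ``;size=K`` (or an
    interior ``;size=K;``) sets the multiplicity, default 1.
    """
    token = header.split()[0]
    mult = 1
    parts = token.split(";")
    kept = []
    for part in parts:
        if part.startswith("size=") and part[5:].isdigit():
            mult = int(part[5:])
        elif part:
            kept.append(part)
    return ";".join(kept), mult


def read_fasta(path: str | Path) -> Dataset:
    """Read a (optionally gzipped) FASTA file into a :class:`Dataset`.

    Multiplicity is parsed from a ``;size=K`` header suffix when present,
    else 1.  Sequences are uppercased.  Raises ``ValueError`` on
    malformed input (naming the offending line) and on an empty file.
    """
    records: list[SequenceRecord] = []
    cur_id: str | None = None
    cur_mult = 1
    cur_seq: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal cur_id
        if cur_id is None:
            return
        bases = "".join(cur_seq).upper()
        if not bases:
            raise ValueError(
                f"{path}: record {cur_id!r} ending before line {lineno} "
                "has no sequence"
            )
        records.append(SequenceRecord(id=cur_id, bases=bases, multiplicity=cur_mult))
        cur_id = None

    lineno = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                cur_id, cur_mult = _parse_header(line[1:])
                if not cur_id:
                    raise ValueError(f"{path}: empty sequence id at line {lineno}")
                cur_seq = []
            else:
                if cur_id is None:
                    raise ValueError(
                        f"{path}: line {lineno}: sequence data before "
                        "any FASTA header"
                    )
                cur_seq.append(line)
        flush(lineno + 1)
    if not records:
        raise ValueError(f"{path}: no FASTA records found (empty dataset)")
    return Dataset(records=records)


def write_fasta(ds: Dataset | Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA with ``;size=K`` multiplicity suffixes."""
    with _open_text(path, "wt") as fh:
        for rec in ds:
            fh.write(f">{rec.id};size={rec.multiplicity}\n{rec.bases}\n")


def deduplicate(ds: Dataset) -> Dataset:
    """Merge records with identical bases, summing multiplicities.

    The surviving id is the lexicographically smallest among the merged
    ids.  Total raw count is conserved; the operation is idempotent.
    Input order of first occurrence is preserved.
    """
    groups: dict[str, list[SequenceRecord]] = defaultdict(list)
    order: list[str] = []
    for rec in ds:
        if rec.bases not in groups:
            order.append(rec.bases)
        groups[rec.bases].append(rec)
    merged = []
    for bases in order:
        recs = groups[bases]
        merged.append(
            SequenceRecord(
                id=min(r.id for r in recs),
                bases=bases,
                multiplicity=sum(r.multiplicity for r in recs),
            )
        )
    return Dataset(records=merged)


def write_clusters(
    clusters: list[Cluster],
    tsv_path: str | Path,
    representatives_path: str | Path | None = None,
) -> None:
    """Serialize clusters to a TSV (one row per member) plus an optional
    representatives FASTA whose ``;size=`` suffix carries the total
    cluster multiplicity.

    Raises ``ValueError`` if two clusters share a member id.
    """
    seen: set[str] = set()
    for cl in clusters:
        ids = cl.member_ids()
        overlap = seen & ids
        if overlap:
            raise ValueError(f"overlapping cluster membership: {sorted(overlap)[:5]}")
        seen |= ids
    with _open_text(tsv_path, "wt") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLUSTER_TSV_COLUMNS)
        for i, cl in enumerate(clusters):
            for rec, sim in cl.members:
                w.writerow(
                    [f"cluster_{i}", cl.representative.id, rec.id,
                     rec.multiplicity, f"{sim:.6f}"]
                )
    if representatives_path is not None:
        with _open_text(representatives_path, "wt") as fh:
            for cl in clusters:
                fh.write(
                    f">{cl.representative.id};size={cl.total_size}\n"
                    f"{cl.representative.bases}\n"
                )


def read_clusters(tsv_path: str | Path) -> dict[str, dict]:
    """Read a cluster TSV back into a mapping
    ``cluster_id -> {"representative_id": str, "members": [(member_id,
    multiplicity, similarity), ...]}``.

    Sequence bases are not stored in the TSV; pair with the
    representatives FASTA when bases are needed.
    """
    out: dict[str, dict] = {}
    with _open_text(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != CLUSTER_TSV_COLUMNS:
            raise ValueError(
                f"{tsv_path}: unexpected columns {reader.fieldnames!r}"
            )
        for row in reader:
            entry = out.setdefault(
                row["cluster_id"],
                {"representative_id": row["representative_id"], "members": []},
            )
            entry["members"].append(
                (
                    row["member_id"],
                    int(row["member_multiplicity"]),
                    float(row["similarity_to_representative"]),
                )
            )
    return out
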