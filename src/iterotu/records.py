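"""Core record types: deduplicated sequences with multiplicities.

An amplicon data set is represented after exact deduplication: each
:class:`SequenceRecord` is a distinct sequence together with its
*multiplicity*, the number of identical copies observed in the raw reads.
All downstream sampling and clustering operates on these deduplicated
records; multiplicities let cluster sizes be reported on the raw-read
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = ["SequenceRecord", "Dataset"]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True, slots=True)
class SequenceRecord:
    """A deduplicated sequence.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    bases : str
        DNA string over ``{A, C, G, T, N}`` (uppercased on construction
        by the readers; enforced here).
    multiplicity : int
        Number of identical copies of ``bases`` in the raw input
        (``>= 1``).
    """

    id: str
    bases: str
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.multiplicity < 1:
            raise ValueError(
                f"record {self.id!r}: multiplicity must be >= 1, "
                f"got {self.multiplicity}"
            )
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r} "
                "(expected A/C/G/T/N after uppercasing)"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Dataset:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate sequence id {r.id!r}")
            seen.add(r.id)

    @property
    def total_raw(self) -> int:
        """Total raw-read count, i.e. the sum of multiplicities."""
        return sum(r.multiplicity for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    def by_id(self) -> dict[str, SequenceRecord]:
        return {r.id: r for r in self.records}

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord]) -> "Dataset":
        return cls(records=list(records))
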