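"""Dataset bookkeeping helpers for benchmark-style studies.

When a proteome-scale structure set is screened before batch
projection, structures are dropped for two reasons: missing coordinates
(no usable atoms in the model file) and orphans (no family assignment,
so the aligned workflow cannot place them). :func:`filter_report`
tallies those exclusions over a record table and reports what survives.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = ["ProteinRecord", "FilterReport", "filter_report", "length_summary"]


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    has_coordinates: bool = True
    has_family: bool = True
    n_residues: int = 0


@dataclass(frozen=True)
class FilterReport:
    total: int
    missing_coordinates: int
    orphans: int

    @property
    def retained(self) -> int:
        return self.total - self.missing_coordinates - self.orphans


def filter_report(records: Iterable[ProteinRecord]) -> FilterReport:
    """Count exclusions over a screening table.

    A record with no coordinates is excluded first; a coordinate-bearing
    record with no family assignment counts as an orphan. Everything
    else is retained.
    """
    total = missing = orphan = 0
    for rec in records:
        total += 1
        if not rec.has_coordinates:
            missing += 1
        elif not rec.has_family:
            orphan += 1
    return FilterReport(total, missing, orphan)


def length_summary(records: Iterable[ProteinRecord]) -> dict[str, float]:
    """Min/mean/max residue counts of a record set."""
    lengths = [r.n_residues for r in records]
    if not lengths:
        raise ValueError("no records")
    return {
        "min": float(min(lengths)),
        "mean": float(sum(lengths) / len(lengths)),
        "max": float(max(lengths)),
        "n": float(len(lengths)),
    }
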