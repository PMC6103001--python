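"""ID-normalized proteome list comparisons: overlap percentages and Venn
partitions against external resources (pain gene databases, transcriptome
lists, protein-atlas presence lists).

Identifier conversion (e.g. gene symbol -> reviewed mouse UniProt accession)
is consumed as a user-supplied two-column mapping table; some identifiers are
always lost in conversion and are counted rather than silently dropped.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "NamedProteinList",
    "OverlapReport",
    "normalize_ids",
    "percentage_overlap",
    "venn_partition",
    "atlas_subtraction",
    "round_half_up_percent",
]


@dataclass
class NamedProteinList:
    """A named set of protein accessions after ID normalization."""

    name: str
    accessions: frozenset[str]
    source_count: int
    unmapped_count: int = 0
    multi_mapped_count: int = 0
    unmapped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass
class OverlapReport:
    list_a: str
    list_b: str
    n_a: int
    n_b: int
    n_intersection: int
    pct_of_a: float  # NaN when list a is empty
    pct_of_b: float


def read_mapping(path) -> dict[str, set[str]]:
    """Load a two-column TSV (raw identifier -> accession) into a multimap."""
    df = pd.read_csv(path, sep="\t", header=None, names=["raw", "accession"],
                     dtype=str, comment="#")
    mapping: dict[str, set[str]] = {}
    for raw, acc in zip(df["raw"], df["accession"]):
        mapping.setdefault(raw, set()).add(acc)
    return mapping


def normalize_ids(
    raw_ids,
    mapping: dict[str, set[str]] | None = None,
    name: str = "list",
) -> NamedProteinList:
    """Convert raw identifiers to a deduplicated accession set.

    With no mapping the identifiers are taken as accessions already.  A raw
    id mapping to several accessions keeps all of them (union semantics —
    conservative for overlap claims) and is counted as multi-mapped; ids
    absent from the mapping are counted and listed as unmapped.
    """
    raw_list = list(raw_ids)
    if mapping is None:
        return NamedProteinList(
            name=name,
            accessions=frozenset(raw_list),
            source_count=len(raw_list),
        )
    accessions: set[str] = set()
    unmapped: list[str] = []
    multi = 0
    for raw in raw_list:
        targets = mapping.get(raw)
        if not targets:
            unmapped.append(raw)
            continue
        if len(targets) > 1:
            multi += 1
        accessions |= targets
    return NamedProteinList(
        name=name,
        accessions=frozenset(accessions),
        source_count=len(raw_list),
        unmapped_count=len(unmapped),
        multi_mapped_count=multi,
        unmapped=unmapped,
    )


def percentage_overlap(a: NamedProteinList, b: NamedProteinList) -> OverlapReport:
    """Intersection size and both directional percentages (0-100 scale).

    An empty list leaves its directional percentage undefined (NaN).
    """
    inter = len(a.accessions & b.accessions)
    return OverlapReport(
        list_a=a.name,
        list_b=b.name,
        n_a=len(a),
        n_b=len(b),
        n_intersection=inter,
        pct_of_a=100.0 * inter / len(a) if len(a) else math.nan,
        pct_of_b=100.0 * inter / len(b) if len(b) else math.nan,
    )


def round_half_up_percent(pct: float) -> int:
    """Integer percent for report text; 0.5 rounds up (e.g. 31.84 -> 32)."""
    return int(math.floor(pct + 0.5))


def venn_partition(
    lists: list[NamedProteinList],
) -> dict[tuple[str, ...], frozenset[str]]:
    """Exclusive Venn regions for two or three lists.

    Returns every non-empty-key region (2^k - 1 of them) keyed by the sorted
    tuple of member list names, mapping to the accessions found in exactly
    those lists.  Region sizes sum to the size of the union.
    """
    if not 2 <= len(lists) <= 3:
        raise ValueError("venn_partition supports exactly 2 or 3 lists")
    names = [lst.name for lst in lists]
    if len(set(names)) != len(names):
        raise ValueError("list names must be distinct")
    sets = {lst.name: lst.accessions for lst in lists}
    regions: dict[tuple[str, ...], frozenset[str]] = {}
    for k in range(1, len(lists) + 1):
        for inside in itertools.combinations(sorted(names), k):
            members = set.intersection(*(set(sets[n]) for n in inside))
            for outside in set(names) - set(inside):
                members -= sets[outside]
            regions[inside] = frozenset(members)
    return regions


def atlas_subtraction(
    enriched: NamedProteinList, atlas_present: NamedProteinList
) -> NamedProteinList:
    """Enriched proteins absent from an atlas presence list.

    Set difference enriched \\ atlas: the putative candidates whose
    enrichment may extend beyond the profiled species (e.g. mouse PNS
    proteins with no human-atlas match).
    """
    kept = enriched.accessions - atlas_present.accessions
    return NamedProteinList(
        name=f"{enriched.name}_minus_{atlas_present.name}",
        accessions=frozenset(kept),
        source_count=len(enriched),
    )
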