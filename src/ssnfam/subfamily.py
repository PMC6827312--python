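"""Subfamily calling from a chosen SSN partition.

A connected cluster becomes a subfamily when it has at least 20 members and
spans at least two distinct taxonomic classes; the diversity requirement can
be waived per cluster (some robust single-taxon groups, e.g. genus-restricted
ones that segregate early, warrant a manual override). Everything else is
reported as nonclassified rather than force-merged. Subfamilies are numbered
deterministically and can export random representatives for external tree
building.
"""

from __future__ import annotations

import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .network import Partition
from .seqio import RANKS, SequenceRecord

DEFAULT_MIN_SIZE = 20
DEFAULT_DIVERSITY_RANK = "class"
DEFAULT_MIN_DISTINCT = 2
DEFAULT_N_REPRESENTATIVES = 30


class DelineationError(ValueError):
    pass


@dataclass
class Subfamily:
    """A called cluster: numeric label, members, and per-rank taxonomy counts."""

    number: int
    members: frozenset[str]
    taxonomy_summary: dict[str, Counter] = field(default_factory=dict)
    diversity_override: bool = False

    @property
    def size(self) -> int:
        return len(self.members)

    def distinct_at(self, rank: str) -> int:
        """Distinct non-empty lineage values among members at a rank."""
        return len(self.taxonomy_summary.get(rank, Counter()))


@dataclass
class DelineationResult:
    subfamilies: list[Subfamily]
    nonclassified: frozenset[str]
    threshold: float

    @property
    def classified_fraction(self) -> float:
        n_classified = sum(s.size for s in self.subfamilies)
        total = n_classified + len(self.nonclassified)
        return n_classified / total if total else 0.0

    def membership(self) -> dict[str, int]:
        """id -> subfamily number (nonclassified ids are absent)."""
        out: dict[str, int] = {}
        for sf in self.subfamilies:
            for m in sf.members:
                out[m] = sf.number
        return out


def _taxonomy_summary(
    members: Iterable[str], records: Mapping[str, SequenceRecord]
) -> dict[str, Counter]:
    summary: dict[str, Counter] = {rank: Counter() for rank in RANKS}
    for mid in members:
        for rank, value in zip(RANKS, records[mid].taxonomy):
            if value:
                summary[rank][value] += 1
    return {rank: c for rank, c in summary.items() if c}


def delineate(
    partition: Partition,
    records: Sequence[SequenceRecord],
    min_size: int = DEFAULT_MIN_SIZE,
    diversity_rank: str = DEFAULT_DIVERSITY_RANK,
    min_distinct: int = DEFAULT_MIN_DISTINCT,
    overrides: Iterable[int] = (),
) -> DelineationResult:
    """Call subfamilies from an SSN partition.

    A cluster qualifies iff its size is at least ``min_size`` and it spans at
    least ``min_distinct`` distinct non-empty values at ``diversity_rank``
    (or the cluster id is listed in ``overrides``, which waives the diversity
    requirement only, not the size floor). All other members become
    nonclassified.
    """
    if diversity_rank not in RANKS:
        raise DelineationError(f"unknown rank {diversity_rank!r}")
    by_id = {r.id: r for r in records}
    missing = set().union(*partition.clusters.values()) - set(by_id) if partition.clusters else set()
    if missing:
        raise DelineationError(f"partition members without records: {sorted(missing)[:5]}")
    overrides = set(overrides)
    unknown = overrides - set(partition.clusters)
    if unknown:
        raise DelineationError(f"override names nonexistent cluster(s): {sorted(unknown)}")

    called: list[Subfamily] = []
    nonclassified: set[str] = set()
    for cid in sorted(partition.clusters):
        members = partition.clusters[cid]
        summary = _taxonomy_summary(members, by_id)
        distinct = len(summary.get(diversity_rank, ()))
        overridden = cid in overrides
        if len(members) >= min_size and (distinct >= min_distinct or overridden):
            called.append(
                Subfamily(
                    number=0,
                    members=members,
                    taxonomy_summary=summary,
                    diversity_override=overridden and distinct < min_distinct,
                )
            )
        else:
            nonclassified |= members
    return DelineationResult(
        subfamilies=label_subfamilies(called),
        nonclassified=frozenset(nonclassified),
        threshold=partition.threshold,
    )


def label_subfamilies(
    subfamilies: Sequence[Subfamily],
    order: Sequence[frozenset[str]] | None = None,
) -> list[Subfamily]:
    """Assign subfamily numbers 1..S deterministically.

    Default ordering is by descending size with ties broken by the
    lexicographically smallest member id; ``order`` may supply an explicit
    member-set sequence instead. Renumbering is idempotent.
    """
    if order is not None:
        by_members = {sf.members: sf for sf in subfamilies}
        if set(by_members) != set(order):
            raise DelineationError("explicit order must list every subfamily exactly once")
        ranked = [by_members[m] for m in order]
    else:
        ranked = sorted(subfamilies, key=lambda sf: (-sf.size, min(sf.members)))
    for i, sf in enumerate(ranked, start=1):
        sf.number = i
    return ranked


def sample_representatives(
    subfamily: Subfamily,
    n: int = DEFAULT_N_REPRESENTATIVES,
    seed: int = 0,
) -> list[str]:
    """Uniform sample of n member ids without replacement (all if size < n).

    Reproducible under the seed; intended for export as FASTA for external
    phylogenetic analysis.
    """
    if n < 1:
        raise DelineationError("n must be >= 1")
    members = sorted(subfamily.members)
    if len(members) <= n:
        return members
    rng = random.Random(seed)
    return sorted(rng.sample(members, n))


def membership_table(result: DelineationResult) -> pd.DataFrame:
    """Per-sequence assignment table (subfamily 0 = nonclassified)."""
    rows = [
        {"id": rid, "subfamily": num}
        for rid, num in sorted(result.membership().items())
    ]
    rows += [{"id": rid, "subfamily": 0} for rid in sorted(result.nonclassified)]
    return pd.DataFrame(rows, columns=["id", "subfamily"]).sort_values("id", ignore_index=True)


def summary_table(result: DelineationResult, diversity_rank: str = DEFAULT_DIVERSITY_RANK) -> pd.DataFrame:
    rows = [
        {
            "subfamily": sf.number,
            "size": sf.size,
            "distinct_" + diversity_rank: sf.distinct_at(diversity_rank),
            "diversity_override": sf.diversity_override,
        }
        for sf in result.subfamilies
    ]
    return pd.DataFrame(
        rows,
        columns=["subfamily", "size", "distinct_" + diversity_rank, "diversity_override"],
    )
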