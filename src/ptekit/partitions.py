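"""Partitions of a quote set.

A :class:`Partition` maps each item (quote id) to a group label.  It is the
common currency of the toolkit: each sorter's piles form a partition of the
quotes they sorted, and community detection returns partitions of the
co-occurrence network's nodes.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from typing import Hashable

from .errors import ValidationError

__all__ = ["Partition"]


class Partition:
    """An assignment of items to disjoint, covering, non-empty groups.

    Parameters
    ----------
    assignment
        Mapping from item id to group label.  Labels are opaque hashables;
        two partitions are *equivalent* when they induce the same grouping,
        regardless of the labels used.
    """

    __slots__ = ("_assignment",)

    def __init__(self, assignment: Mapping[str, Hashable]):
        self._assignment = dict(assignment)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]]) -> "Partition":
        """Build a partition from an iterable of member groups.

        Groups are labelled by their lexicographically smallest member.
        """
        assignment: dict[str, Hashable] = {}
        for members in groups:
            members = list(members)
            if not members:
                raise ValidationError("empty group in partition")
            label = min(str(m) for m in members)
            for m in members:
                if m in assignment:
                    raise ValidationError(f"item {m!r} appears in two groups")
                assignment[m] = label
        return cls(assignment)

    # -- basic views -------------------------------------------------------

    @property
    def assignment(self) -> dict[str, Hashable]:
        return dict(self._assignment)

    @property
    def items(self) -> frozenset[str]:
        return frozenset(self._assignment)

    @property
    def groups(self) -> dict[Hashable, frozenset[str]]:
        """Group label -> member set."""
        out: dict[Hashable, set[str]] = {}
        for item, label in self._assignment.items():
            out.setdefault(label, set()).add(item)
        return {k: frozenset(v) for k, v in out.items()}

    @property
    def n_groups(self) -> int:
        return len(set(self._assignment.values()))

    def __len__(self) -> int:
        return len(self._assignment)

    def __getitem__(self, item: str) -> Hashable:
        return self._assignment[item]

    def __contains__(self, item: str) -> bool:
        return item in self._assignment

    def __iter__(self):
        return iter(self._assignment)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self._assignment == other._assignment

    def __hash__(self):
        return hash(frozenset(self._assignment.items()))

    def __repr__(self) -> str:
        return f"Partition({self.n_groups} groups, {len(self)} items)"

    # -- semantics ---------------------------------------------------------

    def as_group_sets(self) -> frozenset[frozenset[str]]:
        """The label-free grouping: a set of member sets."""
        return frozenset(self.groups.values())

    def equivalent_to(self, other: "Partition") -> bool:
        """True when both induce the same grouping up to label renaming."""
        return self.as_group_sets() == other.as_group_sets()

    def relabel_canonical(self, prefix: str = "G") -> "Partition":
        """Relabel groups ``G1, G2, ...`` ordered by size (desc) then by
        smallest member id, giving a reproducible labelling for output."""
        ordered = sorted(
            self.groups.values(), key=lambda g: (-len(g), min(str(m) for m in g))
        )
        assignment: dict[str, Hashable] = {}
        for idx, members in enumerate(ordered, start=1):
            for m in members:
                assignment[m] = f"{prefix}{idx}"
        return Partition(assignment)

    def restrict(self, items: Iterable[str]) -> "Partition":
        keep = set(items)
        return Partition({k: v for k, v in self._assignment.items() if k in keep})
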