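"""Comparing partitions, selecting a final grouping, and recording the
panel's manual reassignments.

Two community-detection algorithms can disagree; the toolkit never hides
that.  :func:`select_final` picks the higher-modularity result but always
computes cross-algorithm agreement (adjusted Rand index and normalised
mutual information) so disagreement is visible alongside the chosen
grouping.  During the interpretation session the panel may move quotes
between groups; :func:`reassign` records each move as append-only
provenance, and the algorithmic partition is always recoverable by
replaying (or discarding) the edit log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import comb, log
from pathlib import Path
from typing import IO, Union

import pandas as pd

from .community import MergeHistory, best_partition
from .errors import ValidationError
from .partitions import Partition

__all__ = [
    "ComparisonResult",
    "Edit",
    "FinalGrouping",
    "SelectionResult",
    "adjusted_rand",
    "normalized_mutual_info",
    "contingency_table",
    "compare",
    "select_final",
    "reassign",
]


# ---------------------------------------------------------------------------
# Agreement indices


def _check_same_items(p1: Partition, p2: Partition) -> None:
    if p1.items != p2.items:
        raise ValidationError("partitions are over different item sets")


def contingency_table(p1: Partition, p2: Partition) -> pd.DataFrame:
    """Group-by-group count table; rows are p1's groups, columns p2's."""
    _check_same_items(p1, p2)
    rows = sorted(map(str, p1.groups))
    cols = sorted(map(str, p2.groups))
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for item in p1:
        table.loc[str(p1[item]), str(p2[item])] += 1
    return table


def adjusted_rand(p1: Partition, p2: Partition) -> float:
    """Hubert-Arabie adjusted Rand index, in [-1, 1].

    1 iff the partitions are identical up to labels; expectation 0 for
    independent random partitions with the same group-size profiles.
    """
    table = contingency_table(p1, p2).to_numpy()
    n = int(table.sum())
    index = sum(comb(int(x), 2) for x in table.flat)
    sum_a = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in table.sum(axis=0))
    pairs = comb(n, 2)
    expected = sum_a * sum_b / pairs if pairs else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        # both partitions trivial in the same way (all-singletons or all-one)
        return 1.0 if p1.as_group_sets() == p2.as_group_sets() else 0.0
    return (index - expected) / (max_index - expected)


def normalized_mutual_info(p1: Partition, p2: Partition) -> float:
    """NMI with arithmetic-mean normalisation, in [0, 1]."""
    table = contingency_table(p1, p2).to_numpy()
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    if len(a) == 1 and len(b) == 1:
        return 1.0
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            nij = table[i, j]
            if nij:
                mi += (nij / n) * log(n * nij / (a[i] * b[j]))
    h1 = -sum((x / n) * log(x / n) for x in a if x)
    h2 = -sum((x / n) * log(x / n) for x in b if x)
    denom = (h1 + h2) / 2.0
    if denom == 0.0:
        return 0.0
    return max(0.0, min(1.0, mi / denom))


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement between two partitions of the same quote set."""

    ari: float
    nmi: float
    contingency: pd.DataFrame

    def to_markdown(self) -> str:
        lines = [
            "| index | value |",
            "| --- | --- |",
            f"| adjusted Rand | {self.ari:.4f} |",
            f"| normalised mutual information | {self.nmi:.4f} |",
            "",
            "Contingency (rows: first partition, columns: second):",
            "",
            self.contingency.to_markdown(),
            "",
        ]
        return "\n".join(lines)


def compare(p1: Partition, p2: Partition) -> ComparisonResult:
    """ARI, NMI and the contingency table for two partitions."""
    return ComparisonResult(
        ari=adjusted_rand(p1, p2),
        nmi=normalized_mutual_info(p1, p2),
        contingency=contingency_table(p1, p2),
    )


# ---------------------------------------------------------------------------
# Final grouping with provenance


@dataclass(frozen=True)
class Edit:
    quote_id: str
    from_group: str
    to_group: str
    note: str = ""


@dataclass(frozen=True)
class FinalGrouping:
    """A published grouping: algorithmic base partition plus manual edits.

    ``base`` is the partition an algorithm produced (canonical G1, G2, ...
    labels); ``edits`` is the append-only log of panel reassignments.  The
    current partition is always derived by replaying the edits, so the
    algorithmic original stays recoverable.
    """

    base: Partition
    source: str
    edits: tuple[Edit, ...] = field(default_factory=tuple)

    @property
    def partition(self) -> Partition:
        assignment = self.base.assignment
        for e in self.edits:
            assignment[e.quote_id] = e.to_group
        return Partition(assignment)

    def to_json(self, dest: Union[str, Path, IO[str]]) -> None:
        payload = {
            "source": self.source,
            "base": {k: str(v) for k, v in sorted(self.base.assignment.items())},
            "edits": [
                {
                    "quote_id": e.quote_id,
                    "from_group": e.from_group,
                    "to_group": e.to_group,
                    "note": e.note,
                }
                for e in self.edits
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True) + "\n"
        if hasattr(dest, "write"):
            dest.write(text)  # type: ignore[union-attr]
        else:
            Path(dest).write_text(text, encoding="utf-8")

    @classmethod
    def from_json(cls, source: Union[str, Path, IO[str]]) -> "FinalGrouping":
        if hasattr(source, "read"):
            payload = json.load(source)  # type: ignore[arg-type]
        else:
            payload = json.loads(Path(source).read_text(encoding="utf-8"))
        return cls(
            base=Partition(payload["base"]),
            source=payload["source"],
            edits=tuple(
                Edit(e["quote_id"], e["from_group"], e["to_group"], e.get("note", ""))
                for e in payload["edits"]
            ),
        )


def reassign(
    g: FinalGrouping, quote_id: str, target_group: str, note: str = ""
) -> FinalGrouping:
    """Move a quote to another (possibly new) group, logging the edit.

    Moving a quote to its current group is recorded as a no-op edit so the
    panel's decision is still on the record.
    """
    current = g.partition
    if quote_id not in current:
        raise ValidationError(f"unknown quote id {quote_id!r}")
    edit = Edit(
        quote_id=quote_id,
        from_group=str(current[quote_id]),
        to_group=str(target_group),
        note=note,
    )
    return replace(g, edits=g.edits + (edit,))


# ---------------------------------------------------------------------------
# Reconciling the two algorithms


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of reconciling both algorithms' histories."""

    final: FinalGrouping
    comparison: ComparisonResult
    q_by_algorithm: dict
    best_by_algorithm: dict

    def report_markdown(self) -> str:
        lines = ["# Algorithm reconciliation", ""]
        for name in sorted(self.q_by_algorithm):
            part = self.best_by_algorithm[name]
            lines.append(
                f"- {name}: best Q = {self.q_by_algorithm[name]:.4f}, "
                f"{part.n_groups} groups"
            )
        lines += ["", f"Selected source: **{self.final.source}**", ""]
        lines.append("## Cross-algorithm agreement")
        lines += ["", self.comparison.to_markdown()]
        return "\n".join(lines) + "\n"


def select_final(hA: MergeHistory, hB: MergeHistory) -> SelectionResult:
    """Pick the final grouping from two merge histories.

    The best level of whichever history attains the higher maximal Q wins
    (both algorithms pursue the same objective, so Q is the natural
    arbiter).  If both attain the same Q with the same grouping, the source
    is recorded as "consensus"; an exact Q tie with different groupings
    falls back to alphabetical algorithm order.  The cross-algorithm
    comparison is always part of the result.
    """
    bestA, bestB = best_partition(hA), best_partition(hB)
    if bestA.items != bestB.items:
        raise ValidationError("histories cover different node sets")
    qA, qB = hA.max_q, hB.max_q
    comparison = compare(bestA, bestB)

    if qA == qB and bestA.equivalent_to(bestB):
        chosen, source = bestA, "consensus"
    elif qA > qB or (qA == qB and hA.algorithm <= hB.algorithm):
        chosen, source = bestA, hA.algorithm
    else:
        chosen, source = bestB, hB.algorithm

    final = FinalGrouping(base=chosen.relabel_canonical(), source=source)
    return SelectionResult(
        final=final,
        comparison=comparison,
        q_by_algorithm={hA.algorithm: qA, hB.algorithm: qB},
        best_by_algorithm={hA.algorithm: bestA, hB.algorithm: bestB},
    )
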