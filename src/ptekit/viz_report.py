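"""Network diagram and per-group quote listing.

The diagram follows the conventions the panel sees in a theme-elicitation
session: quotes are shaded circles coloured by group, and edge thickness is
proportional to the number of sorters who co-piled the pair.  The default
six-colour palette is light blue, green, pink, red, yellow, orange, applied
to groups ordered by size (largest first) then label; with more groups than
colours the palette cycles (with a warning).

The group report is the document the panel discusses: one section per
group, verbatim quotes, stable ordering, byte-identical on regeneration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.lines as mlines
import matplotlib.pyplot as plt
import networkx as nx

from .cooccurrence import CooccurrenceNetwork
from .errors import PTEError, ValidationError
from .partitions import Partition
from .partition_tools import FinalGrouping
from .pilesort_data import Quote

__all__ = [
    "DEFAULT_PALETTE",
    "DiagramSpec",
    "layout",
    "render",
    "group_report",
]

DEFAULT_PALETTE = ("lightblue", "green", "pink", "red", "yellow", "orange")

#: display width of a count-1 edge, in points
BASE_EDGE_WIDTH = 0.6
#: edges never drawn wider than this multiple of the base width
MAX_WIDTH_FACTOR = 8


@dataclass(frozen=True)
class DiagramSpec:
    """Layout coordinates plus styling for a network diagram."""

    coordinates: dict
    palette: tuple = DEFAULT_PALETTE
    base_width: float = BASE_EDGE_WIDTH
    layout_seed: int = 0

    def to_jsonable(self) -> dict:
        return {
            "layout_seed": self.layout_seed,
            "base_width": self.base_width,
            "palette": list(self.palette),
            "coordinates": {
                n: [float(x), float(y)]
                for n, (x, y) in sorted(self.coordinates.items())
            },
        }


def layout(net: CooccurrenceNetwork, seed: int = 0) -> DiagramSpec:
    """Force-directed node coordinates, deterministic under ``seed``.

    Spring attraction scales with the co-sort count, so strongly co-sorted
    quotes are drawn close together (equivalently, the inverse-count
    weights act as target edge lengths).
    """
    g = net.similarity_graph()
    if g.number_of_nodes() == 1:
        coords = {n: (0.0, 0.0) for n in g.nodes}
    else:
        pos = nx.spring_layout(g, weight="weight", seed=seed)
        coords = {n: (float(x), float(y)) for n, (x, y) in pos.items()}
    return DiagramSpec(coordinates=coords, layout_seed=seed)


def _group_order(partition: Partition) -> list:
    """Groups ordered by size (desc) then smallest member id — the order in
    which palette colours are assigned."""
    return sorted(
        partition.groups.items(),
        key=lambda kv: (-len(kv[1]), min(str(m) for m in kv[1]), str(kv[0])),
    )


def render(
    net: CooccurrenceNetwork,
    partition: Partition,
    spec: Optional[DiagramSpec] = None,
    out: Union[str, Path] = "network.svg",
) -> Path:
    """Draw the network diagram to ``out`` (SVG or PNG by extension).

    Node fill colour encodes the group; edge width is proportional to the
    co-sort count (capped at 8x the base width for legibility); a legend
    maps colours to group labels.  Inputs are not modified.
    """
    if partition.items != frozenset(net.nodes):
        raise ValidationError("partition must cover exactly the network's nodes")
    if spec is None:
        spec = layout(net)
    missing = set(net.nodes) - set(spec.coordinates)
    if missing:
        raise ValidationError(f"diagram spec lacks coordinates for {sorted(missing)}")

    ordered = _group_order(partition)
    if len(ordered) > len(spec.palette):
        warnings.warn(
            f"{len(ordered)} groups but only {len(spec.palette)} palette colours; "
            "colours will repeat",
            stacklevel=2,
        )
    colour_of_group = {
        label: spec.palette[i % len(spec.palette)]
        for i, (label, _) in enumerate(ordered)
    }

    fig, ax = plt.subplots(figsize=(8, 8))
    ax.set_axis_off()
    pos = spec.coordinates
    for i, j, c in net.edges():
        width = spec.base_width * min(c, MAX_WIDTH_FACTOR)
        (x1, y1), (x2, y2) = pos[i], pos[j]
        ax.plot([x1, x2], [y1, y2], color="0.55", linewidth=width, zorder=1)
    for node in net.nodes:
        x, y = pos[node]
        ax.scatter(
            [x], [y],
            s=220,
            color=colour_of_group[partition[node]],
            edgecolors="0.2",
            zorder=2,
        )
        ax.annotate(node, (x, y), fontsize=6, ha="center", va="center", zorder=3)
    handles = [
        mlines.Line2D(
            [], [], marker="o", linestyle="", markersize=9,
            markerfacecolor=colour_of_group[label], markeredgecolor="0.2",
            label=f"{label} ({len(members)})",
        )
        for label, members in ordered
    ]
    ax.legend(handles=handles, loc="upper right", fontsize=8, frameon=False)

    out = Path(out)
    try:
        fig.savefig(out, bbox_inches="tight")
    except OSError as exc:
        raise PTEError(f"cannot write figure to {out}: {exc}") from exc
    finally:
        plt.close(fig)
    return out


def group_report(
    partition: Partition,
    quotes: Union[Iterable[Quote], Mapping[str, Quote], None],
    out: Union[str, Path, IO[str]],
    grouping: Optional[FinalGrouping] = None,
) -> str:
    """Write the per-group quote listing as markdown; returns the text.

    One section per group (sorted by label), quotes verbatim in quote-id
    order.  Quotes whose text is unavailable appear as id-only entries
    (with a warning).  When a :class:`FinalGrouping` with edits is given,
    the listing reflects post-edit membership and the edit log is appended.
    The document contains no timestamps, so regeneration on the same inputs
    is byte-identical.
    """
    if grouping is not None:
        partition = grouping.partition
    if quotes is None:
        texts: dict[str, Optional[str]] = {}
    elif isinstance(quotes, Mapping):
        texts = {qid: q.text for qid, q in quotes.items()}
    else:
        texts = {q.id: q.text for q in quotes}

    lines = ["# Quote groups", ""]
    meta = f"{partition.n_groups} groups, {len(partition)} quotes"
    if grouping is not None:
        meta += f"; source: {grouping.source}; edits applied: {len(grouping.edits)}"
    lines += [f"_{meta}_", ""]

    n_missing = 0
    for label in sorted(partition.groups, key=str):
        members = sorted(partition.groups[label])
        lines.append(f"## Group {label} ({len(members)} quotes)")
        lines.append("")
        for qid in members:
            text = texts.get(qid)
            if text is None:
                n_missing += 1
                lines.append(f"- **{qid}**")
            else:
                lines.append(f"- **{qid}**: {text}")
        lines.append("")
    if n_missing:
        warnings.warn(
            f"{n_missing} quote(s) listed by id only (no text available)",
            stacklevel=2,
        )

    if grouping is not None and grouping.edits:
        lines.append("## Edit log")
        lines.append("")
        for i, e in enumerate(grouping.edits, start=1):
            note = f" — {e.note}" if e.note else ""
            lines.append(
                f"{i}. {e.quote_id}: {e.from_group} -> {e.to_group}{note}"
            )
        lines.append("")

    text_out = "\n".join(lines)
    if hasattr(out, "write"):
        out.write(text_out)  # type: ignore[union-attr]
    else:
        Path(out).write_text(text_out, encoding="utf-8")  # type: ignore[arg-type]
    return text_out
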