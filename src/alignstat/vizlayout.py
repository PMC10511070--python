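"""Deterministic plot-ready layouts for the figure types.

The tested artifact is the layout (angles, orderings, tables), not
pixels; rendering is a thin matplotlib step on top.  The circular view
assigns one ring per sequence and classifies every column against the
majority consensus as match / mismatch / gap, run-length encoded into
arcs over (360 - reserved_gap) degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .alnstats import consensus
from .clustering import correlation_ordering, leaf_order, nj_tree
from .seqio import Alignment

__all__ = ["Arc", "Track", "CircularLayout", "circular_layout",
           "ordered_heatmap_table", "render_circular"]

MAX_CIRCULAR_SEQUENCES = 300  # beyond this the linear view is advised


@dataclass(frozen=True)
class Arc:
    start_angle: float  # degrees
    end_angle: float
    kind: str  # match_to_consensus | mismatch | gap


@dataclass(frozen=True)
class Track:
    sequence_id: str
    radial_index: int
    arcs: tuple[Arc, ...]


@dataclass
class CircularLayout:
    tracks: list[Track]
    width: int
    reserved_gap: float

    def to_json(self, path) -> None:
        payload = {
            "width": self.width,
            "reserved_gap": self.reserved_gap,
            "tracks": [
                {
                    "sequence_id": t.sequence_id,
                    "radial_index": t.radial_index,
                    "arcs": [
                        [a.start_angle, a.end_angle, a.kind] for a in t.arcs
                    ],
                }
                for t in self.tracks
            ],
        }
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


def _rle(kinds: Sequence[str]) -> list[tuple[int, int, str]]:
    runs = []
    start = 0
    for i in range(1, len(kinds) + 1):
        if i == len(kinds) or kinds[i] != kinds[start]:
            runs.append((start, i - 1, kinds[start]))
            start = i
    return runs


def circular_layout(aln: Alignment, reserved_gap: float = 10.0) -> CircularLayout:
    """Per-sequence arc tracks of consensus-relative runs.

    Each column gets an equal angular slice of (360 - reserved_gap)
    degrees; per sequence the match/mismatch/gap vector against the
    majority consensus is run-length encoded into contiguous arcs.
    """
    if not 0 <= reserved_gap < 360:
        raise ValueError("reserved_gap must be in [0, 360)")
    if aln.n_sequences > MAX_CIRCULAR_SEQUENCES:
        raise ValueError(
            f"{aln.n_sequences} sequences exceed the circular-plot limit of "
            f"{MAX_CIRCULAR_SEQUENCES}; use the linear view"
        )
    cons = consensus(aln, min_freq=0.0).residues
    slice_deg = (360.0 - reserved_gap) / aln.width
    tracks = []
    for idx, rec in enumerate(aln.records):
        kinds = []
        for c, ref in zip(rec.residues, cons):
            if c == "-":
                kinds.append("gap")
            elif c == ref:
                kinds.append("match_to_consensus")
            else:
                kinds.append("mismatch")
        arcs = tuple(
            Arc(start_angle=s * slice_deg, end_angle=(e + 1) * slice_deg,
                kind=k)
            for s, e, k in _rle(kinds)
        )
        tracks.append(Track(sequence_id=rec.id, radial_index=idx, arcs=arcs))
    return CircularLayout(tracks=tracks, width=aln.width,
                          reserved_gap=reserved_gap)


def ordered_heatmap_table(d: DistanceMatrix, order_by: str = "tree",
                          linkage: str = "average"
                          ) -> tuple[pd.DataFrame, list[str]]:
    """Dissimilarity matrix permuted for heatmap display.

    ``tree`` orders rows/columns by the neighbor-joining leaf order;
    ``correlation`` by agglomerative clustering of row correlations.
    The permuted matrix stays symmetric.
    """
    labels = list(d.ids)
    if order_by == "tree":
        order = leaf_order(nj_tree(d)) if len(labels) >= 3 else labels
    elif order_by == "correlation":
        order = correlation_ordering(np.asarray(d.data), labels,
                                     linkage=linkage)
    else:
        raise ValueError(f"unknown order_by {order_by!r}")
    idx = [labels.index(lab) for lab in order]
    m = np.asarray(d.data)[np.ix_(idx, idx)]
    return pd.DataFrame(m, index=order, columns=order), order


_ARC_COLORS = {"match_to_consensus": "#4878b0", "mismatch": "#d65f5f",
               "gap": "#d9d9d9"}


def render_circular(layout: CircularLayout, path) -> None:
    """Thin SVG/PNG rendering of a circular layout (cosmetics only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # deterministic SVG output: stable element ids, no embedded date
    plt.rcParams["svg.hashsalt"] = "alignstat"
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(6, 6))
    for t in layout.tracks:
        for a in t.arcs:
            theta0 = np.deg2rad(a.start_angle)
            span = np.deg2rad(a.end_angle - a.start_angle)
            ax.bar(x=theta0, width=span, height=0.8,
                   bottom=2 + t.radial_index, align="edge",
                   color=_ARC_COLORS[a.kind], linewidth=0)
    ax.set_axis_off()
    fig.savefig(path, metadata={"Date": None}
                if str(path).endswith(".svg") else None)
    plt.close(fig)
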