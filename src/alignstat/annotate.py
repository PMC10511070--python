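"""Join GFF3 gene features to variant positions.

Positions are in reference (ungapped) space since GFF3 describes the
reference sequence, not alignment columns.  When features overlap, the
smallest span wins (most specific, e.g. an exon inside its gene), then
file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .variants import VariantSite

__all__ = ["AnnotatedVariant", "attach_features", "feature_variant_counts",
           "annotated_table"]


@dataclass
class AnnotatedVariant:
    site: VariantSite
    feature_type: str  # exon/intron/CDS/... or "intergenic"
    feature_id: Optional[str]
    cluster_label: Optional[int] = None


def attach_features(sites: list[VariantSite], ft: pd.DataFrame,
                    ref_seqid: str,
                    clusters: Optional[dict] = None) -> list[AnnotatedVariant]:
    """Assign each variant site its most specific overlapping feature.

    ``ft`` is a feature table from :func:`alignstat.seqio.read_gff3`,
    filtered here to ``ref_seqid``.  Sites without a reference position
    are dropped with a warning; strand is carried but ignored for
    containment.  ``clusters`` optionally maps alignment columns to SNP
    cluster labels.
    """
    rows = ft[ft["seqid"] == ref_seqid] if len(ft) else ft
    feats = list(rows.itertuples(index=False))
    out = []
    dropped = 0
    for s in sites:
        if s.ref_pos is None:
            dropped += 1
            continue
        best = None  # (span, file order) minimized
        for order, f in enumerate(feats):
            if f.start <= s.ref_pos <= f.end:
                key = (f.end - f.start, order)
                if best is None or key < best[0]:
                    best = (key, f)
        if best is None:
            ftype, fid = "intergenic", None
        else:
            f = best[1]
            ftype = f.type
            fid = f.attributes.get("ID") or f.attributes.get("Name")
        out.append(
            AnnotatedVariant(
                site=s,
                feature_type=ftype,
                feature_id=fid,
                cluster_label=clusters.get(s.column) if clusters else None,
            )
        )
    if dropped:
        warnings.warn(
            f"{dropped} site(s) without a reference position dropped from "
            "annotation"
        )
    return out


def feature_variant_counts(av: list[AnnotatedVariant]) -> dict[str, int]:
    """Variant counts per feature type; counts partition the input."""
    counts: dict[str, int] = {}
    for a in av:
        counts[a.feature_type] = counts.get(a.feature_type, 0) + 1
    return counts


def annotated_table(av: list[AnnotatedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                column=a.site.column,
                ref_pos=a.site.ref_pos,
                feature_type=a.feature_type,
                feature_id=a.feature_id,
                klass=a.site.klass,
                maf=a.site.maf,
                cluster_label=a.cluster_label,
            )
            for a in av
        ],
        columns=["column", "ref_pos", "feature_type", "feature_id", "klass",
                 "maf", "cluster_label"],
    )
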