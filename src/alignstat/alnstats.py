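"""Alignment-level summary statistics.

Per-sequence statistics (sequence count, length range, GC range), per-column
nucleotide profiles with Shannon entropy, the majority-rule consensus, and
the pairwise dissimilarity matrix that feeds both the heatmap ordering and
the neighbor-joining tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .seqio import AMBIGUOUS_DNA, Alignment, SequenceRecord

__all__ = [
    "AlignmentSummary",
    "ColumnProfile",
    "gc_content",
    "summarize",
    "column_profiles",
    "profiles_table",
    "consensus",
    "pairwise_dissimilarity",
]

BASES = ("A", "C", "G", "T")


def gc_content(record: SequenceRecord) -> float:
    """GC fraction of a DNA sequence.

    Gaps, N and IUPAC ambiguity codes are excluded from both numerator and
    denominator, so the value is identical whether computed on the aligned
    or the ungapped sequence.
    """
    if record.moltype != "dna":
        raise ValueError(f"record {record.id!r}: GC content requires dna moltype")
    s = record.residues
    counts = {b: s.count(b) for b in BASES}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError(
            f"record {record.id!r}: no unambiguous bases, GC undefined"
        )
    return (counts["G"] + counts["C"]) / denom


@dataclass
class AlignmentSummary:
    """Aggregate and per-sequence statistics of a sequence set."""

    n_sequences: int
    min_len: int
    max_len: int
    min_gc: float
    max_gc: float
    per_sequence: pd.DataFrame  # id, ungapped_length, gc, gap_fraction

    def to_tsv(self, path) -> None:
        agg = pd.DataFrame(
            [
                {
                    "Seq. count": self.n_sequences,
                    "Min. Len.": self.min_len,
                    "Max. Len.": self.max_len,
                    "Min. GC. Per.": f"{100 * self.min_gc:.2f}%",
                    "Max. GC. Per.": f"{100 * self.max_gc:.2f}%",
                }
            ]
        )
        agg.to_csv(path, sep="\t", index=False)


def summarize(records: list[SequenceRecord] | Alignment) -> AlignmentSummary:
    """Per-sequence ungapped length / GC / gap fraction with min-max
    aggregates. Accepts an alignment or raw (unaligned) records."""
    if isinstance(records, Alignment):
        records = records.records
    if not records:
        raise ValueError("summarize needs at least one sequence")
    rows = []
    for r in records:
        ungapped = r.ungapped
        rows.append(
            dict(
                id=r.id,
                ungapped_length=len(ungapped),
                gc=gc_content(r),
                gap_fraction=1 - len(ungapped) / len(r.residues),
            )
        )
    df = pd.DataFrame(rows)
    return AlignmentSummary(
        n_sequences=len(df),
        min_len=int(df.ungapped_length.min()),
        max_len=int(df.ungapped_length.max()),
        min_gc=float(df.gc.min()),
        max_gc=float(df.gc.max()),
        per_sequence=df,
    )


@dataclass
class ColumnProfile:
    column: int  # 1-based
    counts: dict[str, int]  # A/C/G/T/N/other/gap
    freqs: dict[str, float]
    gap_fraction: float
    entropy: float  # bits, over called A/C/G/T renormalized
    is_variable: bool


def _profile_column(col: list[str], index: int) -> ColumnProfile:
    n = len(col)
    counts = {b: 0 for b in (*BASES, "N", "other", "gap")}
    for c in col:
        if c in counts and c not in ("other", "gap"):
            counts[c] += 1
        elif c == "-":
            counts["gap"] += 1
        elif c == "N":
            counts["N"] += 1
        else:
            counts["other"] += 1
    freqs = {k: v / n for k, v in counts.items()}
    called = sum(counts[b] for b in BASES)
    if called > 0:
        p = np.array([counts[b] / called for b in BASES])
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
    else:
        entropy = 0.0
    present = sum(1 for b in BASES if counts[b] > 0)
    return ColumnProfile(
        column=index,
        counts=counts,
        freqs=freqs,
        gap_fraction=counts["gap"] / n,
        entropy=entropy,
        is_variable=present >= 2,
    )


def column_profiles(aln: Alignment) -> list[ColumnProfile]:
    """One nucleotide-frequency profile per alignment column.

    Entropy is Shannon entropy in bits over the called A/C/G/T
    frequencies renormalized to exclude gaps and missing residues; gap
    information is carried separately in ``gap_fraction``.
    """
    arr = aln.to_array()
    return [
        _profile_column(list(arr[:, j]), j + 1) for j in range(aln.width)
    ]


def profiles_table(profiles: list[ColumnProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"column": p.column}
        row.update({f"n_{k}": v for k, v in p.counts.items()})
        row.update(
            gap_fraction=p.gap_fraction,
            entropy=p.entropy,
            is_variable=p.is_variable,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def consensus(aln: Alignment, min_freq: float = 0.5,
              id: str = "consensus") -> SequenceRecord:
    """Majority-rule consensus sequence.

    Per column: the most frequent called base, if its frequency among
    non-gap residues reaches ``min_freq``, else 'N'.  A gap is emitted
    only where gaps are a strict majority of the column (and ``min_freq``
    allows).  Ties between bases break alphabetically (A<C<G<T).
    """
    if not 0 <= min_freq <= 1:
        raise ValueError("min_freq must be in [0, 1]")
    arr = aln.to_array()
    n = aln.n_sequences
    out = []
    for j in range(aln.width):
        col = arr[:, j]
        gap_count = int((col == "-").sum())
        if gap_count * 2 > n and gap_count / n >= min_freq:
            out.append("-")
            continue
        non_gap = n - gap_count
        base_counts = [(b, int((col == b).sum())) for b in BASES]
        best_base, best_count = max(base_counts, key=lambda bc: (bc[1],))
        # max() keeps the first of equal counts; BASES is alphabetical.
        if non_gap > 0 and best_count > 0 and best_count / non_gap >= min_freq:
            out.append(best_base)
        else:
            out.append("N")
    return SequenceRecord(id=id, residues="".join(out))


def pairwise_dissimilarity(aln: Alignment,
                           gap_mode: str = "pairwise_delete") -> DistanceMatrix:
    """Pairwise dissimilarity d(i,j) = 1 - matches/compared.

    ``pairwise_delete`` excludes, per pair, columns where either sequence
    is gapped or missing (N/ambiguity); ``gap_as_state`` treats '-' as a
    fifth character state while missing residues stay excluded.  A pair
    with zero comparable columns gets d = 1 with a warning.
    """
    if gap_mode not in ("pairwise_delete", "gap_as_state"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    arr = aln.to_array()
    n = aln.n_sequences
    # integer encoding: A..T -> 0..3, gap -> 4, missing -> 5
    code = np.full(arr.shape, 5, dtype=np.int8)
    for k, b in enumerate(BASES):
        code[arr == b] = k
    code[arr == "-"] = 4
    limit = 4 if gap_mode == "pairwise_delete" else 5
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = (code[i] < limit) & (code[j] < limit)
            compared = int(valid.sum())
            if compared == 0:
                warnings.warn(
                    f"no comparable columns between {aln.ids[i]!r} and "
                    f"{aln.ids[j]!r}; dissimilarity set to 1"
                )
                d[i, j] = d[j, i] = 1.0
                continue
            matches = int((code[i][valid] == code[j][valid]).sum())
            d[i, j] = d[j, i] = 1 - matches / compared
    return DistanceMatrix(d, ids=aln.ids)
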