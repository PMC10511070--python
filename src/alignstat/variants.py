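"""Variant extraction from alignment columns.

Classifies every column (invariant / biallelic SNP / multiallelic SNP /
indel site), filters to clean biallelic sites, encodes a 0/1/NA genotype
matrix (0 = major = "wild" form, 1 = minor = alternative form), maps
alignment columns to ungapped reference coordinates, and reports maximal
gap runs as indel blocks with sharing counts.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .alnstats import BASES, consensus
from .seqio import Alignment

__all__ = [
    "VariantSite",
    "GenotypeMatrix",
    "IndelBlock",
    "classify_column",
    "scan_sites",
    "filter_biallelic",
    "encode_genotypes",
    "map_to_reference",
    "detect_indel_blocks",
    "sites_table",
    "indel_table",
]


@dataclass
class VariantSite:
    """One alignment column's allele tally and classification.

    ``n_missing`` counts '-', N and ambiguity codes together; allele
    counts plus ``n_missing`` always equal the number of sequences.
    ``maf`` is computed over called alleles only.
    """

    column: int  # 1-based alignment column
    ref_pos: Optional[int]  # 1-based ungapped reference position
    alleles: dict[str, int]  # over A/C/G/T, zero counts omitted
    n_missing: int
    n_sequences: int
    klass: str  # invariant | biallelic_snp | multiallelic_snp | indel_site
    major: Optional[str]
    minor: Optional[str]
    maf: float

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_sequences

    @property
    def minor_count(self) -> int:
        return self.alleles.get(self.minor, 0) if self.minor else 0


@dataclass
class GenotypeMatrix:
    """Sites x samples matrix with entries 0 (major), 1 (minor), NaN."""

    sites: list[VariantSite]
    sample_ids: list[str]
    values: np.ndarray  # float, shape (n_sites, n_samples), NaN = missing

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sites), len(self.sample_ids)):
            raise ValueError("genotype matrix dimensions do not match")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[s.column for s in self.sites],
            columns=self.sample_ids,
        )


@dataclass(frozen=True)
class IndelBlock:
    """A maximal run of '-' in one aligned sequence.

    ``n_sharing`` is the number of sequences carrying a block with the
    identical (start_col, end_col) span.
    """

    sample_id: str
    start_col: int  # 1-based inclusive
    end_col: int
    n_sharing: int = 1

    @property
    def length(self) -> int:
        return self.end_col - self.start_col + 1


def classify_column(column_residues: list[str]) -> str:
    """Classify one column of residues.

    Any gap makes the column an indel site (kept disjoint from SNP
    analysis so a VCF REF is always a single base); otherwise the count
    of distinct called A/C/G/T bases decides, with N/ambiguity treated
    as missing.
    """
    if not column_residues:
        raise ValueError("empty column")
    if "-" in column_residues:
        return "indel_site"
    distinct = {c for c in column_residues if c in BASES}
    if len(distinct) <= 1:
        return "invariant"
    if len(distinct) == 2:
        return "biallelic_snp"
    return "multiallelic_snp"


def _map_row(residues: str) -> dict[int, Optional[int]]:
    out: dict[int, Optional[int]] = {}
    pos = 0
    for j, c in enumerate(residues, start=1):
        if c == "-":
            out[j] = None
        else:
            pos += 1
            out[j] = pos
    return out


def map_to_reference(aln: Alignment, ref_id: str) -> dict[int, Optional[int]]:
    """Map alignment columns to 1-based ungapped positions in ``ref_id``.

    Gap columns of the reference map to None; the map is strictly
    increasing over mapped columns.
    """
    return _map_row(aln[ref_id].residues)


def _reference_row(aln: Alignment, ref_id: str) -> str:
    if ref_id == "consensus":
        return consensus(aln, min_freq=0.0).residues
    return aln[ref_id].residues


def scan_sites(aln: Alignment, ref_id: str = "consensus") -> list[VariantSite]:
    """Tally and classify every alignment column as a :class:`VariantSite`.

    ``ref_id`` names the coordinate reference ("wild" form): either an
    aligned sequence or "consensus" for the majority consensus.  The
    major allele is the most frequent called base (ties alphabetical).
    """
    ref_map = _map_row(_reference_row(aln, ref_id))
    arr = aln.to_array()
    n = aln.n_sequences
    sites = []
    for j in range(aln.width):
        col = list(arr[:, j])
        counts = Counter(c for c in col if c in BASES)
        n_missing = n - sum(counts.values())
        klass = classify_column(col)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        major = ranked[0][0] if ranked else None
        minor = ranked[1][0] if len(ranked) > 1 else None
        called = sum(counts.values())
        maf = (ranked[1][1] / called) if len(ranked) > 1 else 0.0
        sites.append(
            VariantSite(
                column=j + 1,
                ref_pos=ref_map[j + 1],
                alleles=dict(counts),
                n_missing=n_missing,
                n_sequences=n,
                klass=klass,
                major=major,
                minor=minor,
                maf=maf,
            )
        )
    return sites


def filter_biallelic(sites: list[VariantSite], max_missing: float = 0.2,
                     min_mac: int = 1) -> list[VariantSite]:
    """Keep clean biallelic SNPs: missing fraction <= ``max_missing`` and
    minor allele count >= ``min_mac``. Order-preserving and idempotent."""
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    if min_mac < 1:
        raise ValueError("min_mac must be >= 1")
    return [
        s
        for s in sites
        if s.klass == "biallelic_snp"
        and s.missing_fraction <= max_missing
        and s.minor_count >= min_mac
    ]


def encode_genotypes(sites: list[VariantSite], aln: Alignment) -> GenotypeMatrix:
    """Encode filtered biallelic sites as a 0/1/NaN genotype matrix.

    0 is the major ("wild") allele, 1 the minor; anything else is NaN.
    Every row of the result carries both alleles — guaranteed by the
    biallelic filter and asserted here.
    """
    if any(s.klass != "biallelic_snp" for s in sites):
        raise ValueError("encode_genotypes requires biallelic sites only")
    arr = aln.to_array()
    values = np.full((len(sites), aln.n_sequences), np.nan)
    for i, s in enumerate(sites):
        col = arr[:, s.column - 1]
        values[i][col == s.major] = 0.0
        values[i][col == s.minor] = 1.0
        assert (values[i] == 0).any() and (values[i] == 1).any()
    return GenotypeMatrix(sites=sites, sample_ids=aln.ids, values=values)


def detect_indel_blocks(aln: Alignment) -> list[IndelBlock]:
    """Maximal '-' runs per sequence, with per-span sharing counts."""
    raw: list[tuple[str, int, int]] = []
    for rec in aln.records:
        start = None
        for j, c in enumerate(rec.residues, start=1):
            if c == "-" and start is None:
                start = j
            elif c != "-" and start is not None:
                raw.append((rec.id, start, j - 1))
                start = None
        if start is not None:
            raw.append((rec.id, start, aln.width))
    span_counts = Counter((s, e) for _, s, e in raw)
    return [
        IndelBlock(sample_id=sid, start_col=s, end_col=e,
                   n_sharing=span_counts[(s, e)])
        for sid, s, e in raw
    ]


def sites_table(sites: list[VariantSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                column=s.column,
                ref_pos=s.ref_pos,
                klass=s.klass,
                major=s.major,
                minor=s.minor,
                maf=s.maf,
                missing_fraction=s.missing_fraction,
            )
            for s in sites
        ],
        columns=["column", "ref_pos", "klass", "major", "minor", "maf",
                 "missing_fraction"],
    )


def indel_table(blocks: list[IndelBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(sample_id=b.sample_id, start_col=b.start_col,
                 end_col=b.end_col, length=b.length, n_sharing=b.n_sharing)
            for b in blocks
        ],
        columns=["sample_id", "start_col", "end_col", "length", "n_sharing"],
    )
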