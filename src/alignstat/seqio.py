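"""Reading and writing of every external format the toolkit touches.

Sequence input is FASTA (aligned or unaligned) or Clustal; annotations come
in as GFF3; results go out as VCFv4.2, 11-column haploid HAPMAP, Newick and
FASTA.  All coordinates are 1-based inclusive, matching GFF3/VCF.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "SequenceRecord",
    "Alignment",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_gff3",
    "write_vcf",
    "read_vcf",
    "write_hapmap",
    "write_newick",
    "read_newick",
    "fetch_popset",
]

# IUPAC nucleotide codes; '-' is the only gap character. '*' and '.' are
# rejected outright rather than coerced.
DNA_CHARS = frozenset("ACGTN-RYSWKMBDHV")
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO-")
AMBIGUOUS_DNA = frozenset("NRYSWKMBDHV")  # treated as missing downstream


@dataclass(frozen=True)
class SequenceRecord:
    """One (possibly gapped) DNA or protein sequence.

    ``id`` is the first whitespace-delimited word of the FASTA header;
    ``description`` the remainder.  Residues are stored uppercase.
    """

    id: str
    residues: str
    description: str = ""
    moltype: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.residues):
            raise ValueError(f"record {self.id!r}: residues contain whitespace")
        object.__setattr__(self, "residues", self.residues.upper())
        alphabet = DNA_CHARS if self.moltype == "dna" else PROTEIN_CHARS
        bad = set(self.residues) - alphabet
        if bad:
            c = sorted(bad)[0]
            raise ValueError(
                f"record {self.id!r}: invalid character {c!r} for moltype "
                f"{self.moltype!r}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """An MSA: >=2 equal-length gapped sequences with unique ids."""

    records: list[SequenceRecord]
    gap_char: str = "-"

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            detail = ", ".join(f"{r.id}={len(r)}" for r in self.records)
            raise ValueError(f"unequal sequence lengths in alignment: {detail}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")

    @property
    def width(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def __getitem__(self, ref_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == ref_id:
                return r
        raise KeyError(f"unknown sequence id {ref_id!r}")

    def column(self, i: int) -> list[str]:
        """Residues of 1-based column ``i``, in record order."""
        return [r.residues[i - 1] for r in self.records]

    def to_array(self) -> np.ndarray:
        """(n_sequences, width) array of single characters."""
        return np.array([list(r.residues) for r in self.records], dtype="U1")


def read_fasta(path: str | Path, moltype: str = "dna") -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    An empty file yields an empty list with a warning; characters outside
    the declared alphabet raise with the record and character named.
    Duplicate ids are an error: downstream matrices are keyed by id.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq),
                description=rec.description[len(rec.id):].strip(),
                moltype=moltype,
            )
        )
    if not records:
        warnings.warn(f"{path}: no FASTA records found")
        return []
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate FASTA ids {dupes}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                line_width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for r in records:
            header = f">{r.id} {r.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(r.residues), line_width):
                fh.write(r.residues[i:i + line_width] + "\n")


def read_alignment(path: str | Path, format: str = "fasta",
                   moltype: str = "dna") -> Alignment:
    """Read an MSA from aligned FASTA or Clustal.

    Clustal interleaved blocks are concatenated per id and conservation
    lines ignored (delegated to Biopython's parser).  Unequal record
    lengths raise an error listing the offending ids and lengths.
    """
    if format == "fasta":
        records = read_fasta(path, moltype=moltype)
    elif format == "clustal":
        msa = AlignIO.read(str(path), "clustal")
        records = [
            SequenceRecord(id=rec.id, residues=str(rec.seq), moltype=moltype)
            for rec in msa
        ]
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    return Alignment(records)


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Parse GFF3 into a feature table.

    Returns a DataFrame with columns seqid, source, type, start, end,
    strand, attributes (a dict parsed from ``key=value;`` pairs).  Lines
    starting with '#' are comments; '.' score/phase are dropped.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            seqid, source, ftype, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates {start!r}/{end!r}"
                ) from None
            if start_i <= 0 or end_i <= 0:
                raise ValueError(f"{path}:{lineno}: coordinates must be positive")
            if start_i > end_i:
                raise ValueError(
                    f"{path}:{lineno}: start {start_i} > end {end_i}"
                )
            attributes = {}
            for pair in attrs.split(";"):
                pair = pair.strip()
                if pair and "=" in pair:
                    k, v = pair.split("=", 1)
                    attributes[k] = v
            rows.append(
                dict(seqid=seqid, source=source, type=ftype, start=start_i,
                     end=end_i, strand=strand, attributes=attributes)
            )
    return pd.DataFrame(
        rows, columns=["seqid", "source", "type", "start", "end", "strand",
                       "attributes"]
    )


def _gt_char(v: float) -> str:
    if np.isnan(v):
        return "."
    return str(int(v))


def write_vcf(sites, genotypes, ref_id: str, path: str | Path,
              ref_length: Optional[int] = None) -> tuple[int, int]:
    """Write biallelic sites as a haploid VCFv4.2 file.

    CHROM is the reference sequence id (the tool works at the gene level,
    not on chromosomes), POS the 1-based ungapped reference coordinate,
    REF the major and ALT the minor allele; GT values are 0, 1 or '.'.
    Sites whose reference position is gapped (``ref_pos is None``) are
    skipped with a warning.  Returns (n_written, n_skipped).
    """
    order = []
    skipped = 0
    for i, s in enumerate(sites):
        if s.ref_pos is None:
            skipped += 1
        else:
            order.append(i)
    if skipped:
        warnings.warn(
            f"{skipped} site(s) without a reference coordinate skipped"
        )
    order.sort(key=lambda i: sites[i].ref_pos)
    length = ref_length
    if length is None:
        length = max((sites[i].ref_pos for i in order), default=1)
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=alignstat\n")
        fh.write(f"##contig=<ID={ref_id},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        for i in order:
            s = sites[i]
            gts = "\t".join(_gt_char(v) for v in genotypes.values[i])
            fh.write(
                f"{ref_id}\t{s.ref_pos}\tcol{s.column}\t{s.major}\t{s.minor}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )
    return len(order), skipped


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Re-read a haploid VCF via pysam into a tidy record table.

    One row per site with chrom, pos, ref, alt and per-sample calls
    (0/1/NaN), used for round-trip verification and interoperability.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        rows = []
        for rec in vf:
            calls = {}
            for s in samples:
                allele = rec.samples[s]["GT"][0]
                calls[s] = np.nan if allele is None else float(allele)
            rows.append(
                dict(chrom=rec.chrom, pos=rec.pos, id=rec.id, ref=rec.ref,
                     alt=rec.alts[0] if rec.alts else None, **calls)
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt", *samples])


_HAPMAP_COLS = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
                "center", "protLSID", "assayLSID", "panelLSID", "QCcode"]


def write_hapmap(sites, genotypes, ref_id: str, path: str | Path) -> tuple[int, int]:
    """Write sites in the 11-column single-letter haploid HAPMAP dialect.

    Calls are the allele letters themselves, missing is "N"; unknown
    metadata columns are "NA".  Skips unmapped sites like :func:`write_vcf`.
    """
    order = []
    skipped = 0
    for i, s in enumerate(sites):
        if s.ref_pos is None:
            skipped += 1
        else:
            order.append(i)
    if skipped:
        warnings.warn(
            f"{skipped} site(s) without a reference coordinate skipped"
        )
    order.sort(key=lambda i: sites[i].ref_pos)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_HAPMAP_COLS + list(genotypes.sample_ids)) + "\n")
        for i in order:
            s = sites[i]
            calls = []
            for v in genotypes.values[i]:
                if np.isnan(v):
                    calls.append("N")
                else:
                    calls.append(s.major if v == 0 else s.minor)
            meta = [f"{ref_id}_{s.ref_pos}", f"{s.major}/{s.minor}", ref_id,
                    str(s.ref_pos), "+", "NA", "NA", "NA", "NA", "NA", "NA"]
            fh.write("\t".join(meta + calls) + "\n")
    return len(order), skipped


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree with branch lengths as Newick; labels with
    metacharacters are quoted by dendropy."""
    with open(path, "w", newline="\n") as fh:
        fh.write(newick_string(tree))


def newick_string(tree: dendropy.Tree) -> str:
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
        real_value_format_specifier=".12g",
    ).strip()
    return s + "\n" if not s.endswith("\n") else s


def read_newick(path: str | Path,
                taxon_namespace: Optional[dendropy.TaxonNamespace] = None
                ) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True,
        taxon_namespace=taxon_namespace,
    )


def fetch_popset(uid: str, email: str = "alignstat@example.org") -> list[SequenceRecord]:
    """Fetch an NCBI PopSet as FASTA via Entrez efetch (network required)."""
    import io

    from Bio import Entrez

    Entrez.email = email
    with Entrez.efetch(db="popset", id=str(uid), rettype="fasta",
                       retmode="text") as handle:
        text = handle.read()
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq),
                                      description=rec.description))
    return records


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
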