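"""Synthetic alignment generator with a machine-readable truth record.

Emulates what the analysis pipeline consumes: an MSA of closely related
gene sequences carrying (i) blocks of biallelic SNPs whose carrier sets
are correlated within a block — the signal the SNP-group clustering is
meant to find, (ii) shared deletions appearing as identical gap runs in
their carriers, and (iii) missing residues ('N') scattered at a fixed
rate.  Every planted event is recorded so parameter-recovery tests can
compare pipeline output to ground truth exactly.

A single NumPy Generator seeded once drives all draws in a fixed order
(ancestral sequence, SNP columns per block, block carrier partitions,
per-SNP partitions and minor alleles, indel carriers, background
substitutions, missing mask), so fixtures are byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .seqio import Alignment, SequenceRecord, write_fasta

__all__ = ["TruthRecord", "simulate_alignment", "write_fixture"]

_BASES = np.array(list("ACGT"))


@dataclass
class TruthRecord:
    """Ground truth of one simulated alignment.

    ``snp_block_labels`` records realized correlated-group membership:
    sites sharing a carrier partition share a group id.  Block partitions
    take ids 1..n_blocks; a SNP that drew an independent partition forms
    its own group (it carries no variation correlated with its block, so
    no clustering method could justifiably return the block id for it).
    """

    planted_snp_columns: list[dict]  # column, major, minor, carriers
    snp_block_labels: dict[int, int]  # column -> correlated-group id
    indel_events: list[dict]  # start_col, length, carriers
    missing_rate: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "planted_snp_columns": self.planted_snp_columns,
            "snp_block_labels": {str(k): v
                                 for k, v in self.snp_block_labels.items()},
            "indel_events": self.indel_events,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


def _draw_partition(rng: np.random.Generator, n: int,
                    forbidden: set[frozenset]) -> np.ndarray:
    """Carrier index set of size < n/2, distinct from ``forbidden`` sets."""
    lo = max(1, n // 4)
    hi = max(lo, (n - 1) // 2)
    for _ in range(1000):
        size = int(rng.integers(lo, hi + 1))
        carriers = np.sort(rng.choice(n, size=size, replace=False))
        if frozenset(carriers.tolist()) not in forbidden:
            return carriers
    raise RuntimeError("could not draw a distinct carrier partition")


def simulate_alignment(
    n_seqs: int = 30,
    width: int = 800,
    n_blocks: int = 2,
    snps_per_block: int = 10,
    block_corr: float = 1.0,
    indel_spec: Optional[Sequence[tuple[int, int, int]]] = None,
    missing_rate: float = 0.0,
    background_sub_rate: float = 0.0,
    seed: int = 1337,
) -> tuple[Alignment, TruthRecord]:
    """Simulate an MSA with planted SNP blocks, shared indels and missing data.

    Parameters
    ----------
    n_seqs, width
        Number of sequences and alignment columns.
    n_blocks, snps_per_block, block_corr
        SNP blocks: each block has one latent carrier partition of the
        samples; each of its SNPs copies that partition with probability
        ``block_corr`` and otherwise gets an independent one.  Carriers
        receive the minor allele (carrier sets are kept below n/2 so the
        ancestral base stays the major allele).
    indel_spec
        Explicit shared deletions as (start_col, length, n_carriers)
        tuples; spans must not overlap each other or planted SNP columns.
    missing_rate
        Per-cell probability of masking a non-gap residue as 'N'.
    background_sub_rate
        Optional per-cell random substitution rate outside planted
        columns and indel spans (off by default: stress tests only).
    seed
        Governs the single random stream for all draws.
    """
    if not 0 <= block_corr <= 1 or not 0 <= missing_rate <= 1:
        raise ValueError("block_corr and missing_rate must be in [0, 1]")
    if n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    indel_spec = list(indel_spec or [])

    forbidden_cols: set[int] = set()
    for start, length, n_car in indel_spec:
        if start < 1 or start + length - 1 > width:
            raise ValueError(f"indel ({start},{length}) outside alignment")
        if not 1 <= n_car <= n_seqs:
            raise ValueError("indel carrier count out of range")
        span = set(range(start, start + length))
        if span & forbidden_cols:
            raise ValueError("overlapping indel spans")
        forbidden_cols |= span

    n_snps = n_blocks * snps_per_block
    if n_snps > width - len(forbidden_cols):
        raise ValueError("alignment too narrow for the planted events")

    # draw 1: ancestral sequence
    ancestral = rng.choice(_BASES, size=width)
    mat = np.tile(ancestral, (n_seqs, 1))

    # draw 2: SNP columns (one draw over free columns, then split by block)
    free = np.array(sorted(set(range(1, width + 1)) - forbidden_cols))
    snp_cols = (np.sort(rng.choice(free, size=n_snps, replace=False))
                if n_snps else np.array([], dtype=int))

    planted: list[dict] = []
    block_labels: dict[int, int] = {}
    sample_ids = [f"s{i+1:03d}" for i in range(n_seqs)]
    used_partitions: set[frozenset] = set()
    # group ids keyed by realized carrier partition; blocks claim 1..n_blocks
    group_of_partition: dict[frozenset, int] = {}
    next_group = n_blocks + 1
    for b in range(n_blocks):
        cols = snp_cols[b * snps_per_block:(b + 1) * snps_per_block]
        # draw 3: the block's latent carrier partition
        block_part = _draw_partition(rng, n_seqs, used_partitions)
        used_partitions.add(frozenset(block_part.tolist()))
        group_of_partition[frozenset(block_part.tolist())] = b + 1
        for col in cols:
            # draws 4/5: per-SNP partition and minor allele
            if rng.random() < block_corr:
                carriers = block_part
            else:
                carriers = _draw_partition(rng, n_seqs, set())
            major = str(ancestral[col - 1])
            minor = str(rng.choice([b_ for b_ in "ACGT" if b_ != major]))
            mat[carriers, col - 1] = minor
            planted.append(
                dict(column=int(col), major=major, minor=minor,
                     carriers=[sample_ids[i] for i in carriers])
            )
            key = frozenset(carriers.tolist())
            if key not in group_of_partition:
                group_of_partition[key] = next_group
                next_group += 1
            block_labels[int(col)] = group_of_partition[key]

    # draw 6: indel carriers
    indel_events = []
    for start, length, n_car in indel_spec:
        carriers = np.sort(rng.choice(n_seqs, size=n_car, replace=False))
        for i in carriers:
            mat[i, start - 1:start - 1 + length] = "-"
        indel_events.append(
            dict(start_col=int(start), length=int(length),
                 carriers=[sample_ids[i] for i in carriers])
        )

    # draw 7: background substitutions (optional stress noise)
    if background_sub_rate > 0:
        touchable = np.ones(width, dtype=bool)
        touchable[[c - 1 for c in forbidden_cols]] = False
        touchable[snp_cols - 1] = False
        hit = (rng.random(mat.shape) < background_sub_rate) & touchable
        hit &= mat != "-"
        for i, j in zip(*np.nonzero(hit)):
            cur = mat[i, j]
            mat[i, j] = rng.choice([b_ for b_ in "ACGT" if b_ != cur])

    # draw 8: missing mask
    if missing_rate > 0:
        mask = (rng.random(mat.shape) < missing_rate) & (mat != "-")
        mat[mask] = "N"

    records = [
        SequenceRecord(id=sid, residues="".join(mat[i]))
        for i, sid in enumerate(sample_ids)
    ]
    truth = TruthRecord(
        planted_snp_columns=planted,
        snp_block_labels=block_labels,
        indel_events=indel_events,
        missing_rate=missing_rate,
        seed=seed,
    )
    return Alignment(records), truth


def write_fixture(outdir: str | Path, **params) -> dict[str, Path]:
    """Write a FASTA fixture, its truth JSON and a toy GFF3 annotation.

    The GFF3 describes a single gene spanning the first sequence's
    ungapped length, split into exon / intron / exon thirds, so the
    annotation-joining stage is exercisable without external files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aln, truth = simulate_alignment(**params)
    fasta = outdir / "fixture.fasta"
    truth_path = outdir / "truth.json"
    gff = outdir / "annotation.gff3"
    write_fasta(aln.records, fasta)
    truth.to_json(truth_path)
    ref = aln.records[0]
    glen = len(ref.ungapped)
    third = max(1, glen // 3)
    with open(gff, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"{ref.id}\tsimgen\tgene\t1\t{glen}\t.\t+\t.\tID=gene1\n")
        fh.write(f"{ref.id}\tsimgen\texon\t1\t{third}\t.\t+\t.\t"
                 "ID=exon1;Parent=gene1\n")
        fh.write(f"{ref.id}\tsimgen\tintron\t{third + 1}\t{2 * third}\t.\t+\t.\t"
                 "ID=intron1;Parent=gene1\n")
        fh.write(f"{ref.id}\tsimgen\texon\t{2 * third + 1}\t{glen}\t.\t+\t.\t"
                 "ID=exon2;Parent=gene1\n")
    return {"fasta": fasta, "truth": truth_path, "gff3": gff}
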