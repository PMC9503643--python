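"""File interchange: FASTA, FASTQ, SAM and the simulator's native TSV formats.

SAM is written against the linearised circular reference: reads that wrap
the origin carry the wrapped tail as a soft clip, and the reader can undo
that (``circular=True``) by re-evaluating end clips as wrap-around, which is
equivalent to re-aligning against a doubled reference.  The native
alignment TSV is the lossless path for circular coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detect import StrandProfiles, TerminiCall
from .simulate import CircularGenome, ReadSet, VirionMolecule, revcomp

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq_pair",
    "write_sam",
    "read_sam_alignments",
    "write_alignment_tsv",
    "read_alignment_tsv",
    "write_manifest_tsv",
    "write_profiles_tsv",
    "write_call_json",
]


def write_fasta(genome: CircularGenome, path, description: str = "") -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.id, description=description)
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path) -> CircularGenome:
    record = next(SeqIO.parse(str(path), "fasta"))
    return CircularGenome(id=record.id, sequence=str(record.seq).upper())


def write_fastq_pair(reads: ReadSet, genome: CircularGenome, prefix) -> tuple[Path, Path]:
    """Paired FASTQ (Phred-33, constant quality 'I' = Q40)."""
    prefix = Path(prefix)
    paths = (prefix.with_suffix(".R1.fastq"), prefix.with_suffix(".R2.fastq"))
    handles = [open(p, "w") for p in paths]
    try:
        for i in range(len(reads)):
            mate = int(reads.mate[i])
            bases = reads.bases_for(i, genome)
            name = f"mol{int(reads.molecule_id[i])}_r{i}"
            handles[mate - 1].write(f"@{name}/{mate}\n{bases}\n+\n{'I' * len(bases)}\n")
    finally:
        for h in handles:
            h.close()
    return paths


def _sam_header(genome: CircularGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": genome.id, "LN": genome.length}],
        }
    )


def write_sam(reads: ReadSet, genome: CircularGenome, path) -> None:
    """Headerful SAM; FLAG carries strand (16) plus pair/mate bits.

    POS is the leftmost aligned base on the linearised reference; the
    portion of an origin-wrapping read that falls past the reference end is
    soft-clipped.
    """
    G = genome.length
    header = _sam_header(genome)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(len(reads)):
            a = pysam.AlignedSegment(header)
            mate = int(reads.mate[i])
            a.query_name = f"mol{int(reads.molecule_id[i])}_r{i}"
            length = int(reads.read_length[i])
            fwd = bool(reads.forward[i])
            five = int(reads.ref_start[i])
            left0 = (five - 1) if fwd else (five - length) % G
            bases = reads.bases_for(i, genome)
            # SAM stores the reference-forward sequence for reverse reads
            a.query_sequence = bases if fwd else revcomp(bases)
            flag = 0x1 | (0x40 if mate == 1 else 0x80)
            if not fwd:
                flag |= 0x10
            else:
                flag |= 0x20  # mate on reverse strand
            a.flag = flag
            a.reference_id = 0
            a.reference_start = left0
            a.mapping_quality = 60
            aligned = min(length, G - left0)
            if aligned < length:  # wraps the origin: clip the tail
                a.cigarstring = f"{aligned}M{length - aligned}S"
            else:
                a.cigarstring = f"{length}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * length)
            out.write(a)


def read_sam_alignments(path, circular: bool = True) -> list[tuple[int, str, int]]:
    """Extract (ref_start, strand, read_length) tuples from a SAM/BAM file.

    ``ref_start`` is the 5' mapped end (1-based).  Only primary mapped
    alignments are used.  With ``circular=True``, soft clips abutting the
    reference ends are treated as origin wrap-around: a trailing clip at the
    reference end extends the read past position G onto position 1, and a
    leading clip at position 1 pulls the 5' end back before the origin.
    Without clip information this recovery is impossible, and reads clipped
    for other reasons are taken at face value.
    """
    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        G = fh.header.to_dict()["SQ"][0]["LN"]
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cig = rec.cigartuples or []
            lead = cig[0][1] if cig and cig[0][0] == 4 else 0
            trail = cig[-1][1] if cig and cig[-1][0] == 4 else 0
            aligned = rec.reference_length or 0
            left1 = rec.reference_start + 1
            right1 = rec.reference_start + aligned
            length = aligned
            if circular:
                if trail and right1 == G:
                    length += trail
                    right1 = trail  # wrapped past the origin
                if lead and left1 == 1:
                    length += lead
                    left1 = G - lead + 1
            if rec.is_reverse:
                out.append((right1, "-", length))
            else:
                out.append((left1, "+", length))
    return out


def write_alignment_tsv(reads: ReadSet, path) -> None:
    """Native alignment table: molecule_id, mate, ref_start, strand, read_length."""
    with open(path, "w") as fh:
        fh.write("molecule_id\tmate\tref_start\tstrand\tread_length\n")
        for i in range(len(reads)):
            fh.write(
                f"{int(reads.molecule_id[i])}\t{int(reads.mate[i])}\t"
                f"{int(reads.ref_start[i])}\t{'+' if reads.forward[i] else '-'}\t"
                f"{int(reads.read_length[i])}\n"
            )


def read_alignment_tsv(path) -> ReadSet:
    df = pd.read_csv(str(path), sep="\t")
    return ReadSet(
        molecule_id=df["molecule_id"].to_numpy(int),
        mate=df["mate"].to_numpy(int),
        ref_start=df["ref_start"].to_numpy(int),
        forward=(df["strand"] == "+").to_numpy(bool),
        read_length=df["read_length"].to_numpy(int),
    )


def write_manifest_tsv(molecules: Iterable[VirionMolecule], strategy: str, path) -> None:
    """Ground-truth molecule manifest."""
    with open(path, "w") as fh:
        fh.write("molecule_id\tstrategy\tstart\tlength\tseries_index\n")
        for m in molecules:
            fh.write(f"{m.molecule_id}\t{strategy}\t{m.start}\t{m.length}\t{m.series_index}\n")


def write_profiles_tsv(profiles: StrandProfiles, path) -> None:
    """bedGraph-style per-strand SPC and coverage (1-based positions).

    Zero rows are omitted for SPC columns but coverage is written densely
    enough to be replottable: one row per position with any signal.
    """
    with open(path, "w") as fh:
        fh.write("position\tspc_fwd\tspc_rev\tcoverage\n")
        keep = (profiles.spc_fwd > 0) | (profiles.spc_rev > 0)
        for i in np.flatnonzero(keep):
            fh.write(
                f"{i + 1}\t{int(profiles.spc_fwd[i])}\t{int(profiles.spc_rev[i])}\t"
                f"{int(profiles.coverage[i])}\n"
            )


def write_call_json(call: TerminiCall, path) -> None:
    with open(path, "w") as fh:
        json.dump(call.as_dict(), fh, indent=2)
        fh.write("\n")
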