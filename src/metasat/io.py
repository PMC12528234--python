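"""Reading and writing of the plain-text formats used across the pipeline.

FASTA/FASTQ parsing goes through Biopython; the writers are thin
serializers so that multi-million-read sets stream quickly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .synthetic import GenomeSequence, ReadSet

PathLike = Union[str, Path]

FASTA_WIDTH = 80

ALIGNMENT_COLUMNS = [
    "read_id",
    "genome_id",
    "contig",
    "start0",
    "strand",
    "aligned_length",
    "mismatches",
    "identity",
]


def read_fasta(path: PathLike, genome_id: Optional[str] = None) -> GenomeSequence:
    """Read a (multi-record) FASTA file as one genome.

    Every record becomes a contig; the genome id defaults to the file stem.
    """
    path = Path(path)
    contigs = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    gid = genome_id if genome_id is not None else path.stem
    return GenomeSequence(id=gid, contigs=contigs, meta={"source": str(path)})


def write_fasta(genome: GenomeSequence, path: PathLike, width: int = FASTA_WIDTH) -> None:
    """Write a genome as FASTA, one record per contig, wrapped at ``width``."""
    with open(path, "w") as fh:
        for cid, seq in genome.contigs:
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: PathLike) -> ReadSet:
    ids: List[str] = []
    seqs: List[str] = []
    quals: List[str] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
        quals.append(
            "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        )
    return ReadSet(ids=ids, seqs=seqs, qualities=quals)


def write_fastq(readset: ReadSet, path: PathLike) -> None:
    quals = readset.qualities
    with open(path, "w") as fh:
        for i, (rid, seq) in enumerate(zip(readset.ids, readset.seqs)):
            q = quals[i] if quals else "I" * len(seq)
            fh.write(f"@{rid}\n{seq}\n+\n{q}\n")


def write_truth_tsv(readset: ReadSet, path: PathLike) -> None:
    """Write the truth table as TSV (read_id, genome_id, contig, start0, strand)."""
    if readset.truth is None:
        raise ValueError("read set carries no truth table")
    with open(path, "w") as fh:
        fh.write("read_id\tgenome_id\tcontig\tstart0\tstrand\n")
        for rid in readset.ids:
            gid, cid, start, strand = readset.truth[rid]
            fh.write(f"{rid}\t{gid}\t{cid}\t{start}\t{strand}\n")


def read_truth_tsv(path: PathLike) -> Dict[str, Tuple[str, str, int, str]]:
    df = pd.read_csv(path, sep="\t")
    return {
        r.read_id: (r.genome_id, r.contig, int(r.start0), r.strand)
        for r in df.itertuples()
    }


def read_bed(path: PathLike) -> Dict[str, List[Tuple[int, int]]]:
    """Read a 3+ column BED file into chrom -> [(start, end), ...] (0-based, half-open)."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            out.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return out


def write_alignments_tsv(alignments, path: PathLike) -> None:
    from .recruitment import ReadAlignment  # local import to avoid cycle

    rows = [
        (
            a.read_id,
            a.genome_id,
            a.contig,
            a.start0,
            a.strand,
            a.aligned_length,
            a.mismatches,
            f"{a.identity:.4f}",
        )
        for a in alignments
    ]
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path: PathLike):
    from .recruitment import ReadAlignment

    df = pd.read_csv(path, sep="\t")
    return [
        ReadAlignment(
            read_id=str(r.read_id),
            genome_id=str(r.genome_id),
            contig=str(r.contig),
            start0=int(r.start0),
            strand=str(r.strand),
            aligned_length=int(r.aligned_length),
            mismatches=int(r.mismatches),
        )
        for r in df.itertuples()
    ]


def write_fit_json(fit, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "genome_id": fit.genome_id,
                "b_max": fit.b_max,
                "tau": fit.tau,
                "rss": fit.rss,
                "n_points": fit.n_points,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_fit_json(path: PathLike):
    from .saturation import SaturationFit

    with open(path) as fh:
        d = json.load(fh)
    return SaturationFit(
        genome_id=d["genome_id"],
        b_max=float(d["b_max"]),
        tau=float(d["tau"]),
        rss=float(d["rss"]),
        n_points=int(d["n_points"]),
    )
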