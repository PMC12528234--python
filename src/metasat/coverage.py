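"""Per-base depth, coverage breadth and seeded alignment subsampling.

Coverage is computed in the excised (masked) coordinate system of the
reference set, so breadth denominators exclude masked bases.  Positions are
0-based and intervals half-open.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from .recruitment import ReadAlignment, ReferenceSet

__all__ = [
    "CoverageProfile",
    "compute_coverage",
    "subsample_alignments",
]


@dataclass
class CoverageProfile:
    """Depth vector and summary statistics for one genome in one metagenome.

    ``breadth`` is the percentage of (post-excision) positions with depth
    >= 1; ``mean_covered_depth`` is ``sum(depth) / count(depth >= 1)`` —
    the "reads/covered position" statistic — and 0 when nothing is covered.
    """

    genome_id: str
    genome_length: int
    depth: np.ndarray
    n_mapped_reads: int
    total_metagenome_reads: int
    breadth: float = field(init=False)
    mean_covered_depth: float = field(init=False)
    pct_reads_mapped: float = field(init=False)

    def __post_init__(self) -> None:
        covered = int(np.count_nonzero(self.depth))
        self.breadth = 100.0 * covered / self.genome_length
        self.mean_covered_depth = (
            float(self.depth.sum()) / covered if covered else 0.0
        )
        self.pct_reads_mapped = (
            100.0 * self.n_mapped_reads / self.total_metagenome_reads
            if self.total_metagenome_reads
            else 0.0
        )

    @property
    def n_covered(self) -> int:
        return int(np.count_nonzero(self.depth))

    @property
    def reads_per_covered_position(self) -> float:
        """Alternative reading: mapped reads per covered position."""
        covered = self.n_covered
        return self.n_mapped_reads / covered if covered else 0.0

    def __str__(self) -> str:
        return (
            f"breadth {self.breadth:.1f}%, "
            f"{self.mean_covered_depth:.1f} reads/covered position"
        )


def _genome_local_layout(refs: ReferenceSet, genome_id: str) -> Dict[str, int]:
    """contig_id -> offset of the contig within the genome (post-excision)."""
    out: Dict[str, int] = {}
    pos = 0
    for g in refs.genomes:
        if g.id != genome_id:
            continue
        for cid, seq in g.contigs:
            out[cid] = pos
            pos += len(seq)
        return out
    raise KeyError(f"genome {genome_id!r} not in reference set")


def compute_coverage(
    alignments: Sequence[ReadAlignment],
    refs: ReferenceSet,
    total_metagenome_reads: int,
) -> Dict[str, CoverageProfile]:
    """Per-base depth and summaries for every genome of the reference set.

    Depth is incremented over ``[start0, start0 + aligned_length)`` for each
    alignment.  Genomes without alignments still get a profile with breadth
    0.  An alignment exceeding its contig bounds raises ``ValueError``
    (it signals coordinate corruption).
    """
    if total_metagenome_reads < len(alignments):
        raise ValueError("total_metagenome_reads smaller than alignment count")
    layouts = {g.id: _genome_local_layout(refs, g.id) for g in refs.genomes}
    contig_len = {
        (g.id, cid): len(seq) for g in refs.genomes for cid, seq in g.contigs
    }
    per_genome: Dict[str, List[ReadAlignment]] = {g.id: [] for g in refs.genomes}
    for a in alignments:
        if a.genome_id not in per_genome:
            raise ValueError(f"alignment to unknown genome {a.genome_id!r}")
        if a.start0 < 0 or a.start0 + a.aligned_length > contig_len[
            (a.genome_id, a.contig)
        ]:
            raise ValueError(
                f"alignment of {a.read_id!r} exceeds bounds of "
                f"{a.genome_id}:{a.contig}"
            )
        per_genome[a.genome_id].append(a)

    profiles: Dict[str, CoverageProfile] = {}
    for g in refs.genomes:
        glen = refs.genome_length(g.id)
        aligns = per_genome[g.id]
        if aligns:
            layout = layouts[g.id]
            starts = np.fromiter(
                (layout[a.contig] + a.start0 for a in aligns),
                dtype=np.int64,
                count=len(aligns),
            )
            lengths = np.fromiter(
                (a.aligned_length for a in aligns), dtype=np.int64, count=len(aligns)
            )
            depth = _depth_from_intervals(starts, lengths, glen)
        else:
            depth = np.zeros(glen, dtype=np.int64)
        profiles[g.id] = CoverageProfile(
            genome_id=g.id,
            genome_length=glen,
            depth=depth,
            n_mapped_reads=len(aligns),
            total_metagenome_reads=total_metagenome_reads,
        )
    return profiles


def _depth_from_intervals(
    starts: np.ndarray, lengths: np.ndarray, genome_length: int
) -> np.ndarray:
    """Dense depth vector from [start, start+length) intervals (diff trick)."""
    diff = np.zeros(genome_length + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + lengths, -1)
    return np.cumsum(diff[:-1])


def _read_id_scores(read_ids: Sequence[str], seed: int) -> np.ndarray:
    """Stable pseudo-random score per read id, keyed on (seed, read_id).

    The scores make subsampling independent of the input order and give
    nested subsets for nested fractions under the same seed.
    """
    key = struct.pack("<q", seed)
    out = np.empty(len(read_ids), dtype=np.uint64)
    for i, rid in enumerate(read_ids):
        h = hashlib.blake2b(rid.encode(), digest_size=8, key=key).digest()
        out[i] = int.from_bytes(h, "little")
    return out


def subsample_alignments(
    alignments: Sequence[ReadAlignment], fraction: float, seed: int
) -> List[ReadAlignment]:
    """Sample exactly ``floor(fraction * N)`` alignments without replacement.

    Sampling is keyed on read ids, so the result is deterministic for a
    fixed seed and independent of the input order.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    n = int(np.floor(fraction * len(alignments) + 1e-9))
    if n == 0:
        return []
    scores = _read_id_scores([a.read_id for a in alignments], seed)
    order = np.lexsort(
        (np.array([a.read_id for a in alignments]), scores)
    )
    return [alignments[i] for i in order[:n]]
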