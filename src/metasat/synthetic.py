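"""Synthetic genomes, conspecific/related variants, communities and reads.

This module generates the inputs every downstream stage consumes: random
genomes with tunable G+C, derived strains that share a core genome but
differ in accessory regions (optionally with extra-conserved islands, as
found between related species), and uniform-length single-end reads with
i.i.d. substitution errors drawn from a community of genomes at fixed
relative abundances.

All randomness flows through :func:`numpy.random.default_rng` seeded from
explicit integer seeds, so identical seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from ._seq import decode, decode_batch, encode

__all__ = [
    "GenomeSequence",
    "CommunitySpec",
    "ReadSet",
    "generate_genome",
    "derive_relative",
    "simulate_reads",
]

_CHUNK = 1 << 17  # reads simulated per block; fixed so output is deterministic

#: annotation role names used by :func:`derive_relative`
ROLE_CORE = "core"
ROLE_ACCESSORY = "accessory"
ROLE_CONSERVED = "conserved"


@dataclass
class GenomeSequence:
    """A named nucleotide sequence, possibly split into several contigs.

    Parameters
    ----------
    id:
        Unique genome identifier.
    contigs:
        Ordered list of ``(contig_id, sequence)`` pairs; sequences are
        uppercase strings over ``{A, C, G, T}`` when produced by the
        simulator (imported genomes may contain ambiguity codes).
    annotations:
        Optional list of ``(contig_id, start, end, role)`` role intervals
        (0-based, half-open).
    meta:
        Free-form provenance metadata.
    """

    id: str
    contigs: List[Tuple[str, str]]
    annotations: List[Tuple[str, int, int, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    @property
    def contig_ids(self) -> List[str]:
        return [cid for cid, _ in self.contigs]

    def contig_seq(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def concatenated(self) -> str:
        return "".join(seq for _, seq in self.contigs)

    def intervals(self, role: str) -> List[Tuple[str, int, int]]:
        """All annotation intervals carrying the given role tag."""
        return [(c, s, e) for c, s, e, r in self.annotations if r == role]

    def validate(self) -> None:
        """Check the type invariants; raises ``ValueError`` on violation."""
        if self.total_length <= 0:
            raise ValueError(f"genome {self.id!r} has zero length")
        lengths = {cid: len(seq) for cid, seq in self.contigs}
        if len(lengths) != len(self.contigs):
            raise ValueError(f"genome {self.id!r} has duplicate contig ids")
        for _, seq in self.contigs:
            if (encode(seq) > 3).any():
                raise ValueError(
                    f"genome {self.id!r} contains non-ACGT characters"
                )
        by_role: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
        for cid, s, e, role in self.annotations:
            if cid not in lengths:
                raise ValueError(f"annotation on unknown contig {cid!r}")
            if not (0 <= s < e <= lengths[cid]):
                raise ValueError(
                    f"annotation interval ({s}, {e}) outside contig {cid!r}"
                )
            by_role.setdefault((cid, role), []).append((s, e))
        for (cid, role), ivs in by_role.items():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping {role!r} intervals on contig {cid!r}"
                    )


@dataclass
class CommunitySpec:
    """A community of genomes with relative abundances and a read model."""

    members: List[Tuple[GenomeSequence, float]]
    read_length: int
    substitution_error_rate: float
    seed: int

    def validate(self) -> None:
        if not self.members:
            raise ValueError("community has no members")
        total = sum(a for _, a in self.members)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")
        if any(a < 0 for _, a in self.members):
            raise ValueError("negative relative abundance")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1)")


@dataclass
class ReadSet:
    """A set of (optionally truth-tracked) reads."""

    ids: List[str]
    seqs: List[str]
    qualities: Optional[List[str]] = None
    #: read_id -> (genome_id, contig_id, 0-based forward start, strand)
    truth: Optional[Dict[str, Tuple[str, str, int, str]]] = None

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def reads(self) -> Iterator[Tuple[str, str, Optional[str]]]:
        quals = self.qualities or [None] * len(self.ids)
        return zip(self.ids, self.seqs, quals)


def _split_lengths(length: int, n_contigs: int) -> List[int]:
    base, rem = divmod(length, n_contigs)
    return [base + (1 if i < rem else 0) for i in range(n_contigs)]


def _gc_probabilities(gc_fraction: float) -> np.ndarray:
    # base order A, C, G, T
    return np.array(
        [
            (1.0 - gc_fraction) / 2.0,
            gc_fraction / 2.0,
            gc_fraction / 2.0,
            (1.0 - gc_fraction) / 2.0,
        ]
    )


def generate_genome(
    length: int,
    gc_fraction: float,
    n_contigs: int = 1,
    seed: int = 0,
    id: Optional[str] = None,
) -> GenomeSequence:
    """Generate a random genome of i.i.d. bases with the given G+C fraction.

    Bases are drawn with ``P(G) = P(C) = gc_fraction / 2`` and
    ``P(A) = P(T) = (1 - gc_fraction) / 2``.  Contig lengths are as equal
    as integer division allows (earlier contigs get the remainder).
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    if n_contigs < 1 or length < n_contigs:
        raise ValueError("need length >= n_contigs >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=_gc_probabilities(gc_fraction))
    codes = codes.astype(np.uint8)
    gid = id if id is not None else f"g{seed}"
    contigs = []
    pos = 0
    for i, clen in enumerate(_split_lengths(length, n_contigs)):
        contigs.append((f"{gid}_c{i + 1}", decode(codes[pos : pos + clen])))
        pos += clen
    return GenomeSequence(
        id=gid,
        contigs=contigs,
        meta={
            "origin": "generate_genome",
            "length": length,
            "gc_fraction": gc_fraction,
            "seed": seed,
        },
    )


def _concat_to_contig_intervals(
    genome: GenomeSequence, start: int, end: int, role: str
) -> List[Tuple[str, int, int, str]]:
    """Project an interval on the concatenated genome onto per-contig coords."""
    out = []
    offset = 0
    for cid, seq in genome.contigs:
        clen = len(seq)
        s = max(start, offset)
        e = min(end, offset + clen)
        if s < e:
            out.append((cid, s - offset, e - offset, role))
        offset += clen
    return out


def derive_relative(
    parent: GenomeSequence,
    substitution_rate: float,
    accessory_swap_fraction: float,
    seed: int = 0,
    id: Optional[str] = None,
    conserved_fraction: float = 0.0,
    conserved_rate: float = 0.0,
    n_conserved_islands: int = 0,
) -> GenomeSequence:
    """Derive a strain/relative of ``parent`` with a shared core genome.

    Each core position is substituted independently at ``substitution_rate``
    (uniform choice among the three alternative bases), giving an expected
    core identity of ``100 * (1 - substitution_rate)`` percent.  A contiguous
    block of ``accessory_swap_fraction`` of the genome at the 3' end is
    replaced by freshly generated sequence of equal length (same empirical
    G+C as the parent), so the pair shares a core but differs in accessory
    content.

    To emulate more distant relatives that retain conserved islands, set
    ``conserved_fraction`` > 0: ``n_conserved_islands`` evenly spaced
    islands totalling that fraction of the genome are substituted at the
    (lower) ``conserved_rate`` instead, and tagged ``"conserved"`` in the
    annotations.  The output genome carries ``"core"`` and ``"accessory"``
    annotations in its own coordinates.
    """
    if not 0.0 <= substitution_rate < 1.0:
        raise ValueError("substitution_rate must be in [0, 1)")
    if not 0.0 <= accessory_swap_fraction < 1.0:
        raise ValueError("accessory_swap_fraction must be in [0, 1)")
    if not 0.0 <= conserved_rate < 1.0:
        raise ValueError("conserved_rate must be in [0, 1)")
    if conserved_fraction and n_conserved_islands < 1:
        raise ValueError("conserved_fraction > 0 needs n_conserved_islands >= 1")

    rng = np.random.default_rng(seed)
    codes = encode(parent.concatenated()).copy()
    if (codes > 3).any():
        raise ValueError("parent genome contains non-ACGT characters")
    total = codes.size
    acc_len = int(round(total * accessory_swap_fraction))
    core_len = total - acc_len

    # per-position substitution rates over the core
    rates = np.full(core_len, substitution_rate)
    islands: List[Tuple[int, int]] = []
    if conserved_fraction > 0 and core_len > 0:
        island_len = int(core_len * min(conserved_fraction / (1 - accessory_swap_fraction), 1.0)) // n_conserved_islands
        spacing = core_len // n_conserved_islands
        island_len = min(island_len, spacing)
        for i in range(n_conserved_islands):
            s = i * spacing
            e = min(s + island_len, core_len)
            if s < e:
                rates[s:e] = conserved_rate
                islands.append((s, e))

    u = rng.random(core_len)
    mask = u < rates
    n_sub = int(mask.sum())
    if n_sub:
        shift = rng.integers(1, 4, size=n_sub).astype(np.uint8)
        codes[:core_len][mask] = (codes[:core_len][mask] + shift) % 4
    if acc_len:
        gc = float(np.isin(codes, (1, 2)).mean())
        codes[core_len:] = rng.choice(
            4, size=acc_len, p=_gc_probabilities(gc)
        ).astype(np.uint8)

    gid = id if id is not None else f"{parent.id}-rel{seed}"
    contigs = []
    offset = 0
    out = GenomeSequence(id=gid, contigs=[], meta={
        "origin": "derive_relative",
        "parent": parent.id,
        "substitution_rate": substitution_rate,
        "accessory_swap_fraction": accessory_swap_fraction,
        "seed": seed,
    })
    for i, (cid, seq) in enumerate(parent.contigs):
        clen = len(seq)
        new_cid = f"{gid}_c{i + 1}"
        contigs.append((new_cid, decode(codes[offset : offset + clen])))
        offset += clen
    out.contigs = contigs
    ann: List[Tuple[str, int, int, str]] = []
    if core_len:
        ann += _concat_to_contig_intervals(out, 0, core_len, ROLE_CORE)
    if acc_len:
        ann += _concat_to_contig_intervals(out, core_len, total, ROLE_ACCESSORY)
    for s, e in islands:
        ann += _concat_to_contig_intervals(out, s, e, ROLE_CONSERVED)
    out.annotations = ann
    return out


def simulate_reads(
    community: CommunitySpec, n_reads: int, track_truth: bool = True
) -> ReadSet:
    """Simulate uniform single-end reads from a community of genomes.

    Each read picks a member genome with probability equal to its relative
    abundance, a uniform start such that the read fits within a single
    contig, a uniform strand, and then i.i.d. substitution errors at the
    community's ``substitution_error_rate``.  Reads never span contig
    junctions.  Deterministic for a fixed ``community.seed``.
    """
    community.validate()
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    L = community.read_length
    rng = np.random.default_rng(community.seed)
    qual = "I" * L
    ids = [f"r{i}" for i in range(n_reads)]
    seqs: List[Optional[str]] = [None] * n_reads
    truth: Optional[Dict[str, Tuple[str, str, int, str]]] = (
        {} if track_truth else None
    )
    if n_reads == 0:
        return ReadSet(ids=ids, seqs=[], qualities=[], truth=truth)

    abund = np.array([a for _, a in community.members], dtype=float)
    member_idx = rng.choice(len(abund), size=n_reads, p=abund / abund.sum())
    err = community.substitution_error_rate
    arange_l = np.arange(L)

    for mi, (genome, _a) in enumerate(community.members):
        ridx = np.flatnonzero(member_idx == mi)
        if ridx.size == 0:
            continue
        contig_codes = [encode(seq) for _, seq in genome.contigs]
        contig_names = [cid for cid, _ in genome.contigs]
        n_starts = np.array([c.size - L + 1 for c in contig_codes])
        n_starts = np.where(n_starts > 0, n_starts, 0)
        if n_starts.sum() == 0:
            raise ValueError(
                f"read_length {L} longer than every contig of {genome.id!r}"
            )
        cum = np.cumsum(n_starts)
        for lo in range(0, ridx.size, _CHUNK):
            sub = ridx[lo : lo + _CHUNK]
            u = rng.integers(0, cum[-1], size=sub.size)
            ci = np.searchsorted(cum, u, side="right")
            prev = np.where(ci > 0, cum[np.maximum(ci - 1, 0)], 0)
            start = (u - prev).astype(np.int64)
            strand = rng.integers(0, 2, size=sub.size)
            block = np.empty((sub.size, L), dtype=np.uint8)
            for c in np.unique(ci):
                sel = ci == c
                block[sel] = contig_codes[c][start[sel][:, None] + arange_l]
            neg = strand == 1
            if neg.any():
                block[neg] = 3 - block[neg][:, ::-1]
            if err > 0:
                emask = rng.random((sub.size, L), dtype=np.float32) < err
                n_err = int(emask.sum())
                if n_err:
                    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                    block[emask] = (block[emask] + shift) % 4
            decoded = decode_batch(block)
            for j, g in enumerate(sub):
                seqs[g] = decoded[j]
            if truth is not None:
                for j, g in enumerate(sub):
                    truth[ids[g]] = (
                        genome.id,
                        contig_names[ci[j]],
                        int(start[j]),
                        "-" if strand[j] else "+",
                    )
    return ReadSet(ids=ids, seqs=seqs, qualities=[qual] * n_reads, truth=truth)
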