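"""Competitive full-length read recruitment against a masked reference set.

The reference set concatenates one or more genomes after excising masked
intervals (e.g. ribosomal operons) and indexes exact k-mer seed words.
Each read is placed full-length and ungapped at its best-identity locus on
either strand; the placement is kept only when the percent identity reaches
the recruitment threshold (default 95%, the species demarcation level).
Each read is assigned to at most one genome (competitive best-hit mapping)
with a deterministic tie-break.

External SAM alignments can be imported through :func:`import_sam`, where
identity is computed from the edit-distance (NM) tag over the query length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from ._seq import KmerLookup, MAX_K, encode, encode_batch, matrix_kmers, rolling_kmers
from .synthetic import GenomeSequence, ReadSet

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_K",
    "DEFAULT_MIN_IDENTITY",
    "ReadAlignment",
    "ReferenceSet",
    "build_reference_set",
    "recruit_reads",
    "import_sam",
    "export_sam",
]

DEFAULT_K = 31
DEFAULT_MIN_IDENTITY = 95.0

_READ_CHUNK = 1 << 17
_VERIFY_CHUNK = 1 << 16

# masks: {genome_id: [(contig_id, start, end), ...]}
MaskMap = Mapping[str, Sequence[Tuple[str, int, int]]]


@dataclass(slots=True)
class ReadAlignment:
    """One full-length placement of a read on one reference genome.

    ``start0`` is the 0-based position on the forward strand of the contig
    in post-excision coordinates; ``identity`` is
    ``100 * (aligned_length - mismatches) / aligned_length``.
    """

    read_id: str
    genome_id: str
    contig: str
    start0: int
    strand: str
    aligned_length: int
    mismatches: int

    @property
    def identity(self) -> float:
        return 100.0 * (self.aligned_length - self.mismatches) / self.aligned_length


def _merge_intervals(ivs: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class ReferenceSet:
    """Concatenated, mask-excised and k-mer indexed reference genomes.

    Attributes
    ----------
    genomes:
        Post-excision :class:`GenomeSequence` objects, input order.
    offsets:
        ``genome_id -> (global_start, length)`` in the concatenation.
    excised:
        ``genome_id -> [(contig_id, start, end), ...]`` excised intervals
        in *original* coordinates, so original positions are recoverable.
    k:
        Seed word length of the recruiter index.
    """

    def __init__(
        self,
        genomes: Sequence[GenomeSequence],
        masks: Optional[MaskMap] = None,
        k: int = DEFAULT_K,
    ):
        if not 1 <= k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
        ids = [g.id for g in genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids in reference set")
        if not genomes:
            raise ValueError("reference set needs at least one genome")
        self.k = k
        masks = masks or {}

        self.genomes: List[GenomeSequence] = []
        self.excised: Dict[str, List[Tuple[str, int, int]]] = {}
        for g in genomes:
            gmask = masks.get(g.id, ())
            by_contig: Dict[str, List[Tuple[int, int]]] = {}
            for cid, s, e in gmask:
                by_contig.setdefault(cid, []).append((s, e))
            new_contigs: List[Tuple[str, str]] = []
            removed: List[Tuple[str, int, int]] = []
            for cid, seq in g.contigs:
                ivs = _merge_intervals(by_contig.pop(cid, []))
                for s, e in ivs:
                    if not (0 <= s < e <= len(seq)):
                        raise ValueError(
                            f"mask ({s}, {e}) outside contig {cid!r} of {g.id!r}"
                        )
                    removed.append((cid, s, e))
                if ivs:
                    kept = []
                    pos = 0
                    for s, e in ivs:
                        kept.append(seq[pos:s])
                        pos = e
                    kept.append(seq[pos:])
                    seq = "".join(kept)
                new_contigs.append((cid, seq))
            if by_contig:
                raise ValueError(
                    f"mask on unknown contig(s) {sorted(by_contig)} of {g.id!r}"
                )
            self.genomes.append(
                GenomeSequence(id=g.id, contigs=new_contigs, meta=dict(g.meta))
            )
            self.excised[g.id] = removed

        # layout arrays over the concatenation
        contig_seqs: List[np.ndarray] = []
        c_start: List[int] = []
        c_len: List[int] = []
        c_genome: List[int] = []
        c_name: List[str] = []
        c_local: List[int] = []  # offset of contig within its genome
        self.offsets: Dict[str, Tuple[int, int]] = {}
        pos = 0
        for gi, g in enumerate(self.genomes):
            gstart = pos
            local = 0
            for cid, seq in g.contigs:
                contig_seqs.append(encode(seq))
                c_start.append(pos)
                c_len.append(len(seq))
                c_genome.append(gi)
                c_name.append(cid)
                c_local.append(local)
                pos += len(seq)
                local += len(seq)
            self.offsets[g.id] = (gstart, pos - gstart)
        self._seq = (
            np.concatenate(contig_seqs) if contig_seqs else np.empty(0, np.uint8)
        )
        self._c_start = np.array(c_start, dtype=np.int64)
        self._c_end = self._c_start + np.array(c_len, dtype=np.int64)
        self._c_genome = np.array(c_genome, dtype=np.int64)
        self._c_name = c_name
        self._c_local = np.array(c_local, dtype=np.int64)
        self.total_length = int(self._seq.size)

        nonempty = [l for l in c_len if l > 0]
        if not nonempty or min(nonempty) < k:
            raise ValueError(f"k={k} larger than the shortest contig")

        # lexicographic genome rank for deterministic tie-breaking
        order = sorted(range(len(self.genomes)), key=lambda i: self.genomes[i].id)
        self._lex_rank = np.empty(len(self.genomes), dtype=np.int64)
        for rank, gi in enumerate(order):
            self._lex_rank[gi] = rank

        hashes, valid = rolling_kmers(self._seq, k)
        # windows must not cross contig boundaries
        for s, e in zip(self._c_start, self._c_end):
            lo = max(int(e) - k + 1, int(s))
            valid[lo : int(e)] = False
        starts = np.flatnonzero(valid)
        kh = hashes[starts]
        srt = np.argsort(kh, kind="stable")
        self._kmers = kh[srt]
        self._kpos = starts[srt]
        self._lookup = KmerLookup(self._kmers, self._kpos, k)

    # -- lookups ---------------------------------------------------------
    @property
    def genome_ids(self) -> List[str]:
        return [g.id for g in self.genomes]

    def genome_length(self, genome_id: str) -> int:
        return self.offsets[genome_id][1]

    def contig_index_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self._c_start, gpos, side="right") - 1

    def global_to_local(self, gpos: int) -> Tuple[str, str, int]:
        """Map a global concatenation position to (genome_id, contig_id, offset)."""
        ci = int(self.contig_index_of(np.array([gpos]))[0])
        return (
            self.genomes[self._c_genome[ci]].id,
            self._c_name[ci],
            int(gpos - self._c_start[ci]),
        )

    def to_original_coord(self, genome_id: str, contig_id: str, pos: int) -> int:
        """Recover the pre-excision coordinate of a post-excision position."""
        orig = pos
        for cid, s, e in sorted(self.excised[genome_id], key=lambda t: t[1]):
            if cid == contig_id and orig >= s:
                orig += e - s
        return orig

    def genome_local_position(self, genome_id: str, contig_id: str, pos: int) -> int:
        """Position within the genome's own (post-excision) coordinate system."""
        gstart, _ = self.offsets[genome_id]
        for ci in range(len(self._c_name)):
            if (
                self._c_name[ci] == contig_id
                and self.genomes[self._c_genome[ci]].id == genome_id
            ):
                return int(self._c_local[ci] + pos)
        raise KeyError(f"contig {contig_id!r} not in genome {genome_id!r}")


def build_reference_set(
    genomes: Sequence[GenomeSequence],
    masks: Optional[MaskMap] = None,
    k: int = DEFAULT_K,
) -> ReferenceSet:
    """Excise masked intervals, concatenate genomes and build the seed index."""
    return ReferenceSet(genomes, masks=masks, k=k)


def _seed_offsets(read_len: int, k: int, stride: int) -> List[int]:
    offs = list(range(0, read_len - k + 1, stride))
    if offs[-1] != read_len - k:
        offs.append(read_len - k)
    return offs


def recruit_reads(
    reads: ReadSet,
    refs: ReferenceSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    seed_stride: Optional[int] = None,
) -> List[ReadAlignment]:
    """Competitively assign each read full-length to at most one genome.

    Candidate loci are found by exact k-mer seeding on both strands (seed
    words sampled every ``seed_stride`` positions, default ``refs.k``, plus
    the final offset), then scored by full-length ungapped mismatch count.
    The best placement is kept iff its identity is at least
    ``min_identity``; ties break deterministically by highest identity,
    then lexicographic genome id, then smallest genome coordinate, then
    '+' strand.  Reads with no qualifying placement are unassigned; reads
    shorter than ``refs.k`` are unassigned with a logged warning.
    """
    k = refs.k
    stride = seed_stride if seed_stride is not None else k
    if stride < 1:
        raise ValueError("seed_stride must be >= 1")

    by_len: Dict[int, List[int]] = {}
    for i, s in enumerate(reads.seqs):
        by_len.setdefault(len(s), []).append(i)

    results: List[Tuple[int, ReadAlignment]] = []
    n_short = 0
    for L, indices in sorted(by_len.items()):
        if L < k:
            n_short += len(indices)
            continue
        offsets = _seed_offsets(L, k, stride)
        arange_l = np.arange(L)
        max_mm = int(np.floor(L * (100.0 - min_identity) / 100.0 + 1e-9))
        idx_arr = np.array(indices, dtype=np.int64)
        for lo in range(0, idx_arr.size, _READ_CHUNK):
            chunk = idx_arr[lo : lo + _READ_CHUNK]
            n = chunk.size
            codes = encode_batch([reads.seqs[gi] for gi in chunk], L)
            rc = (3 - codes)[:, ::-1]
            # rc of non-ACGT (255) wraps; remask so it can never match a ref code
            rc = np.where(codes[:, ::-1] > 3, 255, rc).astype(np.uint8)

            off_arr = np.array(offsets, dtype=np.int64)
            n_off = off_arr.size
            cand_parts = []  # (row, start, strand)
            for strand, mat in ((0, codes), (1, rc)):
                hashes = matrix_kmers(mat, k, offsets)
                flat_idx, pos = refs._lookup.lookup(hashes.ravel())
                if flat_idx.size == 0:
                    continue
                rows = flat_idx // n_off
                starts = pos - off_arr[flat_idx % n_off]
                ci = refs.contig_index_of(pos)
                ok = (starts >= refs._c_start[ci]) & (
                    starts + L <= refs._c_end[ci]
                )
                if ok.any():
                    cand_parts.append(
                        (rows[ok], starts[ok], np.full(int(ok.sum()), strand))
                    )
            if not cand_parts:
                continue
            rows = np.concatenate([p[0] for p in cand_parts])
            starts = np.concatenate([p[1] for p in cand_parts])
            strands = np.concatenate([p[2] for p in cand_parts])
            key = (rows * refs.total_length + starts) * 2 + strands
            _, uniq_idx = np.unique(key, return_index=True)
            rows, starts, strands = rows[uniq_idx], starts[uniq_idx], strands[uniq_idx]

            mm = np.empty(rows.size, dtype=np.int64)
            for mat, s_val in ((codes, 0), (rc, 1)):
                s_idx = np.flatnonzero(strands == s_val)
                for vlo in range(0, s_idx.size, _VERIFY_CHUNK):
                    sel = s_idx[vlo : vlo + _VERIFY_CHUNK]
                    ref_rows = refs._seq[starts[sel][:, None] + arange_l]
                    mm[sel] = (ref_rows != mat[rows[sel]]).sum(axis=1)
            keep = mm <= max_mm
            if not keep.any():
                continue
            rows, starts, strands, mm = rows[keep], starts[keep], strands[keep], mm[keep]

            ci = refs.contig_index_of(starts)
            grank = refs._lex_rank[refs._c_genome[ci]]
            glocal = starts - refs._c_start[ci] + refs._c_local[ci]
            order = np.lexsort((strands, glocal, grank, mm, rows))
            rows_o = rows[order]
            _, first = np.unique(rows_o, return_index=True)
            best = order[first]
            ci_b = ci[best]
            ridx_list = chunk[rows[best]].tolist()
            start_list = (starts[best] - refs._c_start[ci_b]).tolist()
            mm_list = mm[best].tolist()
            strand_list = strands[best].tolist()
            contig_list = [refs._c_name[c] for c in ci_b.tolist()]
            gid_list = [
                refs.genomes[g].id for g in refs._c_genome[ci_b].tolist()
            ]
            results.extend(
                (
                    ridx,
                    ReadAlignment(
                        read_id=reads.ids[ridx],
                        genome_id=gid,
                        contig=cname,
                        start0=st,
                        strand="-" if sv else "+",
                        aligned_length=L,
                        mismatches=mmv,
                    ),
                )
                for ridx, gid, cname, st, sv, mmv in zip(
                    ridx_list, gid_list, contig_list, start_list,
                    strand_list, mm_list,
                )
            )
    if n_short:
        logger.warning("%d reads shorter than k=%d left unassigned", n_short, k)
    results.sort(key=lambda t: t[0])
    return [a for _, a in results]


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------

def _sam_reference_names(refs: ReferenceSet) -> List[Tuple[str, str, str, int]]:
    """(sam_name, genome_id, contig_id, length) per contig."""
    out = []
    for g in refs.genomes:
        for cid, seq in g.contigs:
            out.append((f"{g.id}:{cid}", g.id, cid, len(seq)))
    return out


def _resolve_reference_name(
    name: str, refs: ReferenceSet
) -> Tuple[str, str]:
    """Resolve a SAM sequence name to (genome_id, contig_id)."""
    if ":" in name:
        gid, cid = name.split(":", 1)
        for g in refs.genomes:
            if g.id == gid and cid in g.contig_ids:
                return gid, cid
    matches = [
        (g.id, cid) for g in refs.genomes for cid in g.contig_ids if cid == name
    ]
    if len(matches) == 1:
        return matches[0]
    raise ValueError(f"cannot resolve SAM reference name {name!r}")


def export_sam(
    alignments: Iterable[ReadAlignment],
    refs: ReferenceSet,
    path: Union[str, Path],
    reads: Optional[ReadSet] = None,
) -> None:
    """Write recruiter output as a minimal SAM file with NM tags."""
    names = _sam_reference_names(refs)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": ln} for n, _, _, ln in names],
    }
    tid = {(g, c): i for i, (_, g, c, _) in enumerate(names)}
    seq_of = (
        {rid: s for rid, s in zip(reads.ids, reads.seqs)} if reads is not None else {}
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_id = tid[(a.genome_id, a.contig)]
            seg.reference_start = a.start0
            seg.mapping_quality = 255
            seg.cigarstring = f"{a.aligned_length}M"
            seq = seq_of.get(a.read_id)
            if seq is not None:
                if a.strand == "-":
                    from ._seq import revcomp_str

                    seq = revcomp_str(seq)
                seg.query_sequence = seq
            seg.set_tag("NM", a.mismatches)
            out.write(seg)


def import_sam(
    sam: Union[str, Path],
    refs: ReferenceSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    require_full_length: bool = True,
) -> List[ReadAlignment]:
    """Import external SAM alignments subject to the recruitment criteria.

    Unmapped, secondary and supplementary records are skipped.  Identity is
    ``100 * (L - NM) / L`` over the query length ``L``; records without an
    NM tag are skipped (with a logged count).  When ``require_full_length``
    is set, records with any soft or hard clipping are dropped.
    """
    out: List[ReadAlignment] = []
    n_missing_nm = 0
    with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            gid, cid = _resolve_reference_name(rec.reference_name, refs)
            if not rec.has_tag("NM"):
                n_missing_nm += 1
                continue
            L = rec.infer_read_length() or (
                len(rec.query_sequence) if rec.query_sequence else 0
            )
            if L == 0:
                n_missing_nm += 1
                continue
            if require_full_length and any(
                op in (4, 5) for op, _ in (rec.cigartuples or [])
            ):
                continue
            nm = int(rec.get_tag("NM"))
            identity = 100.0 * (L - nm) / L
            if identity < min_identity:
                continue
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    genome_id=gid,
                    contig=cid,
                    start0=int(rec.reference_start),
                    strand="-" if rec.is_reverse else "+",
                    aligned_length=int(L),
                    mismatches=nm,
                )
            )
    if n_missing_nm:
        logger.warning("skipped %d SAM records without usable NM/length", n_missing_nm)
    return out
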