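"""Overall genome-related indices for species delimitation.

Implements fragment-based whole-genome average nucleotide identity (gANI)
with alignment fractions, the 95% species-demarcation classifier,
marker-gene identity typing at 97%, genome summary statistics, and the
intra-/inter-species gANI-AF scatter records.

The gANI convention: the query is cut into consecutive non-overlapping
fragments (default 1020 bp, terminal short fragment discarded); each
fragment is aligned to its best locus in the reference (exact k-mer seeded,
ungapped scoring with a banded gapped fallback); fragments qualify when
their identity is >= 70% over >= 70% of their length.  gANI is the
length-weighted mean identity of qualifying fragments over both directions;
the alignment fraction (AF) of each direction is the fraction of the
fragmented genome covered by qualifying alignments, and ``af_avg`` is the
arithmetic mean of the two directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import Align

from ._seq import decode, encode, rolling_kmers
from .synthetic import GenomeSequence

__all__ = [
    "GenomeStats",
    "AniResult",
    "ScatterRecord",
    "UnclassifiablePairError",
    "genome_stats",
    "compute_gani",
    "classify_pair",
    "marker_identity",
    "scatter_table",
]

DEFAULT_FRAGMENT_LENGTH = 1020
DEFAULT_MIN_FRAGMENT_IDENTITY = 70.0
DEFAULT_MIN_FRAGMENT_COVERAGE = 70.0
DEFAULT_ANI_SEED_K = 13
_BAND = 48

SAME_SPECIES = "same-species"
DIFFERENT_SPECIES = "different-species"
INTRA = "intra-species"
INTER = "inter-species"
CROSS_BRANCH = "cross-branch"


class UnclassifiablePairError(ValueError):
    """Raised when a pair has no qualifying aligned fragments."""


@dataclass(frozen=True)
class GenomeStats:
    """Summary statistics of one genome assembly.

    ``gc_mol_percent`` is ``100 * (G+C) / (A+C+G+T)`` with ambiguity codes
    excluded from numerator and denominator; ``total_length`` counts all
    characters.
    """

    genome_id: str
    total_length: int
    n_contigs: int
    gc_mol_percent: float


@dataclass(frozen=True)
class AniResult:
    """gANI and alignment fractions for an ordered genome pair.

    ``gani`` is ``None`` (undefined) when no fragment qualifies in either
    direction; ``af_avg`` is order-symmetric by construction.
    """

    query_id: str
    ref_id: str
    gani: Optional[float]
    af_query: float
    af_ref: float
    af_avg: float
    n_fragments: int
    n_aligned: int


@dataclass(frozen=True)
class ScatterRecord:
    """One gANI-AF point labelled for the intra-/inter-species scatter."""

    pair: Tuple[str, str]
    gani: Optional[float]
    af_avg: float
    label: str
    branch: str


def genome_stats(
    genome: Union[GenomeSequence, str, Path], genome_id: Optional[str] = None
) -> GenomeStats:
    """Exact length, contig count and G+C mol% of a genome or FASTA file."""
    if not isinstance(genome, GenomeSequence):
        from .io import read_fasta

        genome = read_fasta(genome, genome_id=genome_id)
    if not genome.contigs:
        raise ValueError("genome has no contigs")
    counts = {b: 0 for b in "ACGT"}
    total = 0
    for _, seq in genome.contigs:
        seq = seq.upper()
        total += len(seq)
        for b in "ACGT":
            counts[b] += seq.count(b)
    unambiguous = sum(counts.values())
    if unambiguous == 0:
        raise ValueError(f"genome {genome.id!r} has no unambiguous nucleotides")
    gc = 100.0 * (counts["G"] + counts["C"]) / unambiguous
    return GenomeStats(
        genome_id=genome.id,
        total_length=total,
        n_contigs=len(genome.contigs),
        gc_mol_percent=gc,
    )


# ---------------------------------------------------------------------------
# gANI
# ---------------------------------------------------------------------------

def _gapped_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


class _RefIndex:
    """Sorted k-mer index over the forward strand of one genome."""

    def __init__(self, genome: GenomeSequence, k: int):
        self.k = k
        seqs = [encode(seq) for _, seq in genome.contigs]
        self.seq = np.concatenate(seqs) if seqs else np.empty(0, np.uint8)
        bounds = np.cumsum([0] + [s.size for s in seqs])
        self.c_start = bounds[:-1]
        self.c_end = bounds[1:]
        hashes, valid = rolling_kmers(self.seq, k)
        for s, e in zip(self.c_start, self.c_end):
            lo = max(int(e) - k + 1, int(s))
            valid[lo : int(e)] = False
        starts = np.flatnonzero(valid)
        kh = hashes[starts]
        order = np.argsort(kh, kind="stable")
        self.kmers = kh[order]
        self.kpos = starts[order]

    def contig_bounds_at(self, pos: int) -> Tuple[int, int]:
        ci = int(np.searchsorted(self.c_start, pos, side="right")) - 1
        ci = max(ci, 0)
        return int(self.c_start[ci]), int(self.c_end[ci])


def _fragment_matrix(
    genome: GenomeSequence, fragment_length: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fragment the genome into consecutive non-overlapping windows.

    Returns ``(matrix, starts, concat)``: the (n_fragments, fragment_length)
    code matrix, each fragment's start in the concatenated genome, and the
    concatenated code vector itself.  Terminal remainders per contig are
    dropped; fragments never span contigs.
    """
    frags = []
    starts = []
    concat = []
    offset = 0
    for _, seq in genome.contigs:
        codes = encode(seq)
        concat.append(codes)
        nf = codes.size // fragment_length
        if nf:
            frags.append(
                codes[: nf * fragment_length].reshape(nf, fragment_length)
            )
            starts.append(offset + np.arange(nf) * fragment_length)
        offset += codes.size
    cat = np.concatenate(concat) if concat else np.empty(0, np.uint8)
    if not frags:
        return np.empty((0, fragment_length), dtype=np.uint8), np.empty(
            0, np.int64
        ), cat
    return np.concatenate(frags, axis=0), np.concatenate(starts), cat


def _best_diagonals(
    frag_starts: np.ndarray,
    concat: np.ndarray,
    fragment_length: int,
    index: _RefIndex,
    k: int,
) -> List[List[Tuple[int, int]]]:
    """Per fragment and strand, the top-voted candidate start diagonals.

    Returns, for each fragment, a list of (strand, ref_start) candidates
    (strand 0: fragment forward, 1: fragment reverse-complemented).
    Fragment k-mers are slices of one genome-wide rolling hash pass, which
    keeps seeding cheap even for every offset.
    """
    nf = frag_starts.size
    fl = fragment_length
    total = concat.size
    offsets = np.arange(fl - k + 1)
    results: List[List[Tuple[int, int]]] = [[] for _ in range(nf)]
    fwd_h, fwd_valid = rolling_kmers(concat, k)
    rc_concat = np.where(concat[::-1] > 3, np.uint8(255), (3 - concat)[::-1])
    rc_h, rc_valid = rolling_kmers(rc_concat.astype(np.uint8), k)
    for strand in (0, 1):
        if strand == 0:
            rows_idx = frag_starts[:, None] + offsets[None, :]
            hashes = fwd_h[rows_idx]
            hvalid = fwd_valid[rows_idx]
        else:
            rc_start = total - frag_starts - fl
            rows_idx = rc_start[:, None] + offsets[None, :]
            hashes = rc_h[rows_idx]
            hvalid = rc_valid[rows_idx]
        flat_h = hashes.ravel()
        flat_ok = hvalid.ravel()
        left = np.searchsorted(index.kmers, flat_h, side="left")
        right = np.searchsorted(index.kmers, flat_h, side="right")
        left = np.where(flat_ok, left, 0)
        right = np.where(flat_ok, right, 0)
        cnt = right - left
        nz = np.flatnonzero(cnt)
        if nz.size == 0:
            continue
        reps = cnt[nz]
        flat = np.repeat(nz, reps)
        base = np.repeat(left[nz], reps)
        csum = np.concatenate(([0], np.cumsum(reps)[:-1]))
        within = np.arange(int(reps.sum())) - np.repeat(csum, reps)
        pos = index.kpos[base + within]
        frag_idx = flat // len(offsets)
        off = np.array(offsets)[flat % len(offsets)]
        diag = pos - off
        order = np.lexsort((diag, frag_idx))
        fi_s, dg_s = frag_idx[order], diag[order]
        starts = np.flatnonzero(
            np.concatenate(([True], fi_s[1:] != fi_s[:-1]))
        )
        bounds = np.concatenate((starts, [fi_s.size]))
        for bi in range(starts.size):
            lo, hi = bounds[bi], bounds[bi + 1]
            d = dg_s[lo:hi]
            uniq, counts = np.unique(d, return_counts=True)
            # windowed vote: sum counts of diagonals within the band
            if uniq.size > 1:
                win = np.array(
                    [
                        counts[(uniq >= u - _BAND) & (uniq <= u + _BAND)].sum()
                        for u in uniq
                    ]
                )
            else:
                win = counts
            bi_best = int(np.argmax(win))
            added = [int(uniq[bi_best])]
            results[int(fi_s[lo])].append(
                (strand, added[0], int(win[bi_best]))
            )
            # secondary strong diagonals (indel-shifted halves of a fragment)
            for oi in np.argsort(counts)[::-1][:3]:
                diag = int(uniq[oi])
                if counts[oi] < _MIN_GAPPED_VOTES:
                    break
                if any(abs(diag - d0) <= 2 for d0 in added):
                    continue
                added.append(diag)
                results[int(fi_s[lo])].append((strand, diag, int(counts[oi])))
    return results


#: minimum seed votes before the gapped fallback is attempted
_MIN_GAPPED_VOTES = 4


def _ungapped_identity(
    frag: np.ndarray,
    index: _RefIndex,
    start: int,
    min_identity: float,
    min_coverage: float,
) -> Optional[Tuple[float, int]]:
    """Qualifying (identity %, aligned length) on the candidate diagonal."""
    fl = frag.size
    cstart, cend = index.contig_bounds_at(min(max(start, 0), index.seq.size - 1))
    ov_s = max(start, cstart)
    ov_e = min(start + fl, cend)
    ov = ov_e - ov_s
    if ov <= 0:
        return None
    ref_seg = index.seq[ov_s:ov_e]
    q_seg = frag[ov_s - start : ov_s - start + ov]
    mm = int(np.count_nonzero(ref_seg != q_seg))
    identity = 100.0 * (ov - mm) / ov
    coverage = 100.0 * ov / fl
    if identity >= min_identity and coverage >= min_coverage:
        return identity, ov
    return None


def _gapped_identity(
    frag: np.ndarray,
    index: _RefIndex,
    start: int,
    aligner: Align.PairwiseAligner,
    min_identity: float,
    min_coverage: float,
) -> Optional[Tuple[float, int]]:
    """Qualifying (identity %, aligned length) from a windowed local alignment."""
    fl = frag.size
    cstart, cend = index.contig_bounds_at(min(max(start, 0), index.seq.size - 1))
    w_s = max(start - _BAND, cstart)
    w_e = min(start + fl + _BAND, cend)
    if w_e - w_s < 1:
        return None
    ref_str = decode(np.minimum(index.seq[w_s:w_e], 3))
    q_str = decode(np.minimum(frag, 3))
    try:
        aln = aligner.align(ref_str, q_str)[0]
    except (IndexError, ValueError):
        return None
    counts = aln.counts()
    columns = aln.length
    if columns == 0:
        return None
    identity = 100.0 * counts.identities / columns
    q_aligned = int(aln.aligned[1][-1][1] - aln.aligned[1][0][0]) if len(
        aln.aligned[1]
    ) else 0
    coverage = 100.0 * q_aligned / fl
    if identity >= min_identity and coverage >= min_coverage:
        return identity, q_aligned
    return None


def _direction(
    query: GenomeSequence,
    index: _RefIndex,
    fragment_length: int,
    min_identity: float,
    min_coverage: float,
    k: int,
) -> Tuple[float, int, int, int]:
    """One direction of the gANI computation.

    Returns (sum of identity*aligned_length, sum of aligned lengths,
    n_fragments, n_qualifying).
    """
    frag_mat, frag_starts, concat = _fragment_matrix(query, fragment_length)
    nf = frag_mat.shape[0]
    if nf == 0:
        return 0.0, 0, 0, 0
    aligner = _gapped_aligner()
    candidates = _best_diagonals(frag_starts, concat, fragment_length, index, k)
    frag_rc_mat = (3 - frag_mat)[:, ::-1]
    sum_id_len = 0.0
    sum_len = 0
    n_qual = 0
    for fi in range(nf):
        best: Optional[Tuple[float, int]] = None
        cands = sorted(candidates[fi], key=lambda t: -t[2])
        for strand, start, _votes in cands:
            frag = frag_mat[fi] if strand == 0 else frag_rc_mat[fi]
            res = _ungapped_identity(frag, index, start, min_identity, min_coverage)
            if res is not None and (best is None or res[0] > best[0]):
                best = res
        strong = [c for c in cands if c[2] >= _MIN_GAPPED_VOTES]
        if best is None or len(strong) >= 2:
            # gapped fallback: no qualifying diagonal, or several strong
            # diagonals (the signature of an indel inside the fragment)
            for strand, start, votes in strong[:3]:
                frag = frag_mat[fi] if strand == 0 else frag_rc_mat[fi]
                res = _gapped_identity(
                    frag, index, start, aligner, min_identity, min_coverage
                )
                if res is not None and (best is None or res[0] > best[0]):
                    best = res
        if best is not None:
            sum_id_len += best[0] * best[1]
            sum_len += best[1]
            n_qual += 1
    return sum_id_len, sum_len, nf, n_qual


def compute_gani(
    query: GenomeSequence,
    reference: GenomeSequence,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    min_fragment_identity: float = DEFAULT_MIN_FRAGMENT_IDENTITY,
    min_fragment_coverage: float = DEFAULT_MIN_FRAGMENT_COVERAGE,
    k: int = DEFAULT_ANI_SEED_K,
) -> AniResult:
    """Fragment-based gANI with alignment fractions for a genome pair.

    Both directions are computed; gANI is the length-weighted mean identity
    of qualifying fragments pooled over the two directions, and each
    direction's AF is the qualifying aligned length divided by that
    genome's fragmented length.  ``af_avg`` is the mean of the two AFs.
    """
    if query.total_length == 0 or reference.total_length == 0:
        raise ValueError("both genomes must be non-empty")
    if fragment_length < k:
        raise ValueError("fragment_length must be >= seed word length k")
    idx_ref = _RefIndex(reference, k)
    idx_query = _RefIndex(query, k)
    s1, l1, nf1, nq1 = _direction(
        query, idx_ref, fragment_length, min_fragment_identity,
        min_fragment_coverage, k,
    )
    s2, l2, nf2, nq2 = _direction(
        reference, idx_query, fragment_length, min_fragment_identity,
        min_fragment_coverage, k,
    )
    if nf1 == 0 and nf2 == 0:
        raise ValueError("genomes shorter than one fragment; nothing to compare")
    n_aligned = nq1 + nq2
    gani = (s1 + s2) / (l1 + l2) if (l1 + l2) else None
    af_query = 100.0 * l1 / (nf1 * fragment_length) if nf1 else 0.0
    af_ref = 100.0 * l2 / (nf2 * fragment_length) if nf2 else 0.0
    return AniResult(
        query_id=query.id,
        ref_id=reference.id,
        gani=gani,
        af_query=af_query,
        af_ref=af_ref,
        af_avg=(af_query + af_ref) / 2.0,
        n_fragments=nf1 + nf2,
        n_aligned=n_aligned,
    )


def classify_pair(ani: AniResult, threshold: float = 95.0) -> str:
    """Species demarcation: same-species iff gANI >= threshold (inclusive)."""
    if ani.gani is None:
        raise UnclassifiablePairError(
            f"pair ({ani.query_id}, {ani.ref_id}) has no aligned fragments"
        )
    return SAME_SPECIES if ani.gani >= threshold else DIFFERENT_SPECIES


def marker_identity(
    seq_a: str,
    seq_b: str,
    threshold: float = 97.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Tuple[float, bool]:
    """Marker-gene identity typing via global alignment.

    Returns ``(identity, assigned)`` where identity is
    ``100 * matches / alignment columns`` of an optimal global alignment
    (default scores: match 1, mismatch -1, gap -2) and ``assigned`` is True
    iff identity reaches the threshold (species assignment).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    counts = aln.counts()
    identity = 100.0 * counts.identities / aln.length
    return identity, identity >= threshold


def scatter_table(
    ani_results: Sequence[AniResult],
    species_labels: Mapping[str, str],
    branch_labels: Mapping[str, str],
) -> List[ScatterRecord]:
    """Label gANI/AF pairs as intra-/inter-species with branch assignment.

    Every genome must appear in ``species_labels``, and every species in
    ``branch_labels``.  Pairs whose species fall on different branches are
    tagged ``cross-branch``.
    """
    out: List[ScatterRecord] = []
    for ani in ani_results:
        for gid in (ani.query_id, ani.ref_id):
            if gid not in species_labels:
                raise ValueError(f"genome {gid!r} has no species label")
        sp_q = species_labels[ani.query_id]
        sp_r = species_labels[ani.ref_id]
        label = INTRA if sp_q == sp_r else INTER
        br_q = branch_labels[sp_q]
        br_r = branch_labels[sp_r]
        branch = br_q if br_q == br_r else CROSS_BRANCH
        out.append(
            ScatterRecord(
                pair=(ani.query_id, ani.ref_id),
                gani=ani.gani,
                af_avg=ani.af_avg,
                label=label,
                branch=branch,
            )
        )
    return out


def write_scatter_tsv(records: Sequence[ScatterRecord], path) -> None:
    """Write scatter records as TSV, ready for gANI-vs-AF plotting."""
    with open(path, "w") as fh:
        fh.write("query\tref\tgani\taf_avg\tlabel\tbranch\n")
        for r in records:
            gani = "NA" if r.gani is None else f"{r.gani:.4f}"
            fh.write(
                f"{r.pair[0]}\t{r.pair[1]}\t{gani}\t{r.af_avg:.4f}\t"
                f"{r.label}\t{r.branch}\n"
            )
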