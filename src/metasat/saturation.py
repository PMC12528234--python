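"""Coverage-breadth saturation curves and the core-genome calibration fit.

Stepwise read subsampling yields (mapped-read-count, breadth) points per
genome; each series is fitted with the saturating exponential

    B(n) = b_max * (1 - exp(-n / tau))

which is the uniform-coverage breadth expectation reparameterized: ``b_max``
is the asymptotic breadth ceiling (the recruitable/core fraction of the
genome, in percent) and ``tau`` the read count scale.  Among several
conspecific reference genomes, the fit with the smallest asymptote reflects
the core genome and is used as the calibration curve for detection.
"""

from __future__ import annotations

import hashlib
import struct
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .coverage import CoverageProfile, _depth_from_intervals, _read_id_scores
from .recruitment import ReadAlignment, ReferenceSet

__all__ = [
    "DEFAULT_FRACTIONS",
    "SaturationPoint",
    "SaturationFit",
    "is_calibration_sample",
    "build_saturation_points",
    "fit_saturation",
    "select_core_fit",
    "predict_breadth",
]

#: default stepwise subsampling fractions (logged in run headers)
DEFAULT_FRACTIONS = (0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)
DEFAULT_REPLICATES = 3

#: calibration filter thresholds (strict inequalities)
CALIBRATION_MIN_DEPTH = 100.0
CALIBRATION_MIN_BREADTH = 70.0


@dataclass(frozen=True)
class SaturationPoint:
    """Breadth/depth recorded at one subsampled mapped-read count."""

    n_reads: int
    breadth: float
    mean_covered_depth: float


@dataclass(frozen=True)
class SaturationFit:
    """Fitted asymptotic breadth curve for one genome."""

    genome_id: str
    b_max: float
    tau: float
    rss: float
    n_points: int


def is_calibration_sample(profile: CoverageProfile) -> bool:
    """True iff the mapping qualifies as a calibration data set.

    Requires coverage depth strictly above 100-fold and breadth strictly
    above 70%.
    """
    return (
        profile.mean_covered_depth > CALIBRATION_MIN_DEPTH
        and profile.breadth > CALIBRATION_MIN_BREADTH
    )


def _replicate_seed(seed: int, replicate: int) -> int:
    h = hashlib.blake2b(
        struct.pack("<qq", seed, replicate), digest_size=8
    ).digest()
    return int.from_bytes(h, "little") & 0x7FFFFFFFFFFFFFFF


def build_saturation_points(
    alignments: Sequence[ReadAlignment],
    refs: ReferenceSet,
    genome_id: str,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    total_metagenome_reads: Optional[int] = None,
) -> List[SaturationPoint]:
    """Stepwise-reduce mapped reads and record breadth/depth per step.

    For each fraction, ``replicates`` seeded subsamples are drawn (keyed on
    read ids, matching :func:`metasat.coverage.subsample_alignments` with
    the per-replicate derived seed) and breadth and depth are averaged
    across replicates.  Returns one point per fraction with
    ``n_reads = floor(fraction * N)`` where ``N`` is the number of
    alignments on ``genome_id``.
    """
    if not alignments:
        raise ValueError("no alignments given")
    fr = list(fractions)
    if not fr:
        raise ValueError("no fractions given")
    if any(not 0.0 < f <= 1.0 for f in fr):
        raise ValueError("fractions must lie in (0, 1]")
    if fr != sorted(fr):
        raise ValueError("fractions must be sorted ascending")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    sub = [a for a in alignments if a.genome_id == genome_id]
    if not sub:
        raise ValueError(f"no alignments on genome {genome_id!r}")
    glen = refs.genome_length(genome_id)
    from .coverage import _genome_local_layout

    layout = _genome_local_layout(refs, genome_id)
    starts = np.fromiter(
        (layout[a.contig] + a.start0 for a in sub), dtype=np.int64, count=len(sub)
    )
    lengths = np.fromiter(
        (a.aligned_length for a in sub), dtype=np.int64, count=len(sub)
    )
    ids = [a.read_id for a in sub]
    N = len(sub)

    breadth_acc = np.zeros(len(fr))
    depth_acc = np.zeros(len(fr))
    for rep in range(replicates):
        scores = _read_id_scores(ids, _replicate_seed(seed, rep))
        order = np.lexsort((np.array(ids), scores))
        for fi, f in enumerate(fr):
            n = int(np.floor(f * N + 1e-9))
            take = order[:n]
            if n == 0:
                continue
            depth = _depth_from_intervals(starts[take], lengths[take], glen)
            covered = int(np.count_nonzero(depth))
            breadth_acc[fi] += 100.0 * covered / glen
            depth_acc[fi] += float(depth.sum()) / covered if covered else 0.0
    return [
        SaturationPoint(
            n_reads=int(np.floor(f * N + 1e-9)),
            breadth=breadth_acc[fi] / replicates,
            mean_covered_depth=depth_acc[fi] / replicates,
        )
        for fi, f in enumerate(fr)
    ]


def _model(n: np.ndarray, b_max: float, tau: float) -> np.ndarray:
    return b_max * (1.0 - np.exp(-n / tau))


def fit_saturation(
    points: Sequence[SaturationPoint], genome_id: str
) -> SaturationFit:
    """Unweighted least-squares fit of ``B(n) = b_max(1 - exp(-n/tau))``.

    Initialization: ``b_max`` at the maximum observed breadth, ``tau`` at
    the read count where breadth first reaches half of it.  Requires at
    least 3 points with at least 2 distinct read counts and non-degenerate
    breadth values.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 saturation points")
    n = np.array([p.n_reads for p in points], dtype=float)
    b = np.array([p.breadth for p in points], dtype=float)
    if len(np.unique(n)) < 2:
        raise ValueError("need at least 2 distinct read counts")
    bmax0 = float(b.max())
    if bmax0 <= 0:
        raise ValueError("all breadth values are zero; nothing to fit")
    half = np.flatnonzero(b >= bmax0 / 2)
    tau0 = float(max(n[half[0]], 1.0)) if half.size else float(max(n.max(), 1.0))
    popt, _ = curve_fit(
        _model,
        n,
        b,
        p0=(bmax0, tau0),
        bounds=((1e-9, 1e-9), (110.0, np.inf)),
        maxfev=500 * len(points),
        xtol=1e-10,
        ftol=1e-12,
    )
    resid = b - _model(n, *popt)
    return SaturationFit(
        genome_id=genome_id,
        b_max=float(popt[0]),
        tau=float(popt[1]),
        rss=float(np.sum(resid**2)),
        n_points=len(points),
    )


def select_core_fit(fits: Sequence[SaturationFit]) -> SaturationFit:
    """The fit with the smallest asymptote (core-genome ceiling).

    Ties break by lexicographic genome id.
    """
    if not fits:
        raise ValueError("no fits given")
    return min(fits, key=lambda f: (f.b_max, f.genome_id))


def predict_breadth(fit: SaturationFit, n_reads: int) -> float:
    """Calibrated coverage breadth expected at ``n_reads`` mapped reads."""
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    return float(fit.b_max * (1.0 - np.exp(-n_reads / fit.tau)))
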