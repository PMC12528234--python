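"""Shared fixtures.

The heavy session fixtures build the calibration world once: a 1.7M-read
calibration metagenome mapped separately onto five conspecific strains
(>98% identity, accessory swaps 0.12-0.28); the smallest-asymptote fit is
the core calibration curve used by the detection tests.
"""

from __future__ import annotations


import pytest

import metasat as m

CAL_SWAPS = (0.12, 0.16, 0.20, 0.24, 0.28)
CAL_GENOME_SIZE = 2_400_000
CAL_READS = 1_700_000
READ_LEN = 150
ERR = 0.002


@pytest.fixture(scope="session")
def calibration_world():
    """Five-strain calibration: profiles, saturation fits and the core fit."""
    ancestor = m.generate_genome(CAL_GENOME_SIZE, 0.40, 1, seed=201, id="calW")
    strains = [
        m.derive_relative(ancestor, 0.005, sw, seed=210 + i, id=f"calS{i + 1}")
        for i, sw in enumerate(CAL_SWAPS)
    ]
    spec = m.CommunitySpec(
        members=[(ancestor, 1.0)],
        read_length=READ_LEN,
        substitution_error_rate=ERR,
        seed=202,
    )
    reads = m.simulate_reads(spec, CAL_READS, track_truth=False)
    fits = []
    summaries = []
    for strain in strains:
        refs = m.build_reference_set([strain])
        alignments = m.recruit_reads(reads, refs)
        profile = m.compute_coverage(alignments, refs, len(reads))[strain.id]
        points = m.build_saturation_points(
            alignments, refs, strain.id, replicates=2, seed=5
        )
        fits.append(m.fit_saturation(points, strain.id))
        summaries.append(
            {
                "genome_id": strain.id,
                "breadth": profile.breadth,
                "mean_covered_depth": profile.mean_covered_depth,
                "n_mapped": profile.n_mapped_reads,
                "is_calibration": m.is_calibration_sample(profile),
                "points": points,
            }
        )
    core = m.select_core_fit(fits)
    return {
        "swaps": CAL_SWAPS,
        "fits": fits,
        "core_fit": core,
        "summaries": summaries,
    }


@pytest.fixture(scope="session")
def detection_world():
    """Reference genome, indexed reference set, and community members."""
    ref = m.generate_genome(CAL_GENOME_SIZE, 0.42, 1, seed=100, id="refA")
    background = m.generate_genome(CAL_GENOME_SIZE, 0.45, 1, seed=101, id="bg")
    target = m.derive_relative(ref, 0.0075, 0.05, seed=102, id="target")
    relative85 = m.derive_relative(
        ref, 0.155, 0.0, seed=103, id="rel85",
        conserved_fraction=0.03, conserved_rate=0.005, n_conserved_islands=30,
    )
    refs = m.build_reference_set([ref])
    return {
        "ref": ref,
        "background": background,
        "target": target,
        "relative85": relative85,
        "refs": refs,
    }


@pytest.fixture(scope="session")
def small_genome():
    return m.generate_genome(10_000, 0.45, 1, seed=11, id="gsmall")
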