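"""Shared fixtures: the default synthetic study, mapped/normalized coverage
and the called sRNA set are built once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

from srna_seeker import coverage as cov
from srna_seeker import discovery, synthdata
from srna_seeker.core import CoverageTrack, DetectionParams

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study():
    return synthdata.synthetic_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def mapped_study(study):
    """Mapping summaries, raw and normalized tracks for all 18 samples."""
    index = cov.GenomeIndex(study.genome)
    raw, norm, summaries, factors = {}, {}, {}, {}
    for sid, reads in study.reads_by_sample.items():
        mapped, summary = cov.map_reads_iterative(reads, index)
        tracks = cov.compute_coverage(mapped, study.genome, sample_id=sid)
        normalized, factor = cov.normalize_to_total(
            tracks, study.annotation, study.normalization_target
        )
        raw[sid], norm[sid] = tracks, normalized
        summaries[sid], factors[sid] = summary, factor
    return {"raw": raw, "norm": norm, "summaries": summaries, "factors": factors}


@pytest.fixture(scope="session")
def called_srnas(study, mapped_study):
    return discovery.call_srnas(
        mapped_study["norm"], study.annotation, study.genome, DetectionParams()
    )


@pytest.fixture()
def flat_track():
    """120 nt track, depth 60 over positions 41..100, zero elsewhere."""
    d = np.zeros(120)
    d[40:100] = 60.0
    return CoverageTrack("chr", d, sample_id="s1", normalized=True)
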