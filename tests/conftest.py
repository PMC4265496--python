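"""Shared fixtures: synthetic datasets under the two study conditions
(neutral and sequence-driven occupancy) and the standard analysis
products derived from them, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import hmrnuc as h
from hmrnuc.synthetic_data import paperlike_dataset, sequence_driven_dataset


def analyze(ds):
    """End-to-end products: called HMRs, occupancy track, boundary
    anchors, metaprofile, and a trained INOS model with its score track."""
    hmrs, fit = h.call_hmrs(ds.methylomes["a"], seed=1)
    kept, filter_report = h.filter_fragments(ds.fragments["a"])
    counts = h.midpoint_counts(kept, chrom_length=len(ds.genome))
    track = h.normalize_track(h.smooth_track(counts, 20.0, chrom=ds.genome.chrom))
    anchors = h.anchors_from_hmrs(hmrs)
    profile = h.metaprofile(track, anchors)
    inos = h.train_on_track(ds.genome, track, sample_n=8000, lam=5e-4, seed=1)
    inos_scores = h.score_inos(ds.genome, inos)
    return {
        "dataset": ds,
        "hmrs": hmrs,
        "fit": fit,
        "filter_report": filter_report,
        "track": track,
        "anchors": anchors,
        "profile": profile,
        "inos_model": inos,
        "inos_scores": inos_scores,
    }


@pytest.fixture(scope="session")
def dataset():
    """Default study conditions: homogeneous phased boundary arrays."""
    return paperlike_dataset(seed=1)


@pytest.fixture(scope="session")
def analysis(dataset):
    return analyze(dataset)


@pytest.fixture(scope="session")
def seq_dataset():
    """Sequence-driven occupancy conditions (GC- and motif-coupled)."""
    return sequence_driven_dataset(seed=1)


@pytest.fixture(scope="session")
def seq_analysis(seq_dataset):
    return analyze(seq_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    genome, truth = h.simulate_genome(
        length=120_000, cgi_spec={"count": 3, "length": 800}, seed=7
    )
    return genome, truth
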