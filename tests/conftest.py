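"""Shared fixtures: synthetic recordings and a small extracted cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pcgkit import (
    SynthConfig,
    extract_table,
    generate_dataset,
    generate_recording,
    preprocess,
)


@pytest.fixture(scope="session")
def clean_synth():
    """One clean normal recording at 60 bpm with ground truth."""
    return generate_recording(SynthConfig(seed=0, duration=10.0, heart_rate_mean=60.0))


@pytest.fixture(scope="session")
def clean_rec(clean_synth):
    return preprocess(clean_synth.recording)


@pytest.fixture(scope="session")
def murmur_synth():
    """One clean abnormal (systolic murmur) recording with ground truth."""
    return generate_recording(
        SynthConfig(seed=0, duration=10.0, heart_rate_mean=60.0, murmur="systolic")
    )


@pytest.fixture(scope="session")
def cohort():
    """Small balanced cohort with features extracted on truth segmentations.

    Returns (feature_table, references_frame).
    """
    ds = generate_dataset(20, 20, 0.2, seed=11)
    recs = [preprocess(r.recording) for r in ds]
    segs = [r.truth_segmentation for r in ds]
    table = extract_table(recs, segs)
    refs = pd.DataFrame(
        {
            "diagnosis": [r.diagnosis_label for r in ds],
            "quality": [r.quality_label for r in ds],
        },
        index=pd.Index(table.record_ids, name="record_id"),
    )
    return table, refs


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
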