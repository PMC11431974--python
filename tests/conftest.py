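import warnings

import numpy as np
import pytest

import pwavekit as pk


@pytest.fixture(scope="session")
def clean_recording():
    """A short noise-free 12-lead recording with its ground truth."""
    spec = pk.default_spec(duration_s=12.0, seed=1)
    return pk.generate_recording(spec)


@pytest.fixture(scope="session")
def clean_delineation(clean_recording):
    rec, truth = clean_recording
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ann, beats = pk.delineate_recording(rec)
    return ann, beats, truth


def fiducial_errors(detected: pk.AnnotationSet, truth: pk.GroundTruth,
                    kind: str) -> np.ndarray:
    """Signed sample errors for one fiducial kind, matched on
    (lead, beat) keys present in both sets."""
    tk = truth.annotations.by_key()
    errs = []
    for (lead, beat, k), s in detected.by_key().items():
        if k == kind and (lead, beat, kind) in tk:
            errs.append(s - tk[(lead, beat, kind)])
    return np.asarray(errs, dtype=float)
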