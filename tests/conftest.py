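import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ifnsig import (
    PipelineConfig,
    RawCountMatrix,
    SampleAnnotation,
    default_config,
)


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return default_config()


def build_matrix(counts: dict[str, dict[str, int]], classes: dict[str, str],
                 batch_of: dict[str, str] | None = None) -> RawCountMatrix:
    """Hand-built matrix from {sample: {gene: count}} plus gene -> class."""
    genes = list(classes)
    frame = pd.DataFrame(
        {s: [counts[s][g] for g in genes] for s in counts},
        index=pd.Index(genes, name="gene"),
        dtype=np.int64,
    )
    info = pd.DataFrame(
        {"code_class": [classes[g] for g in genes], "accession": ""},
        index=frame.index,
    )
    return RawCountMatrix(frame, info, dict(batch_of or {}))


@pytest.fixture
def toy_three_sample():
    """Three samples in one batch: positive-control geomeans 100/200/400 and
    housekeeping counts chosen so hk geomeans are equal after step 1."""
    classes = {f"POS_{c}": "positive_control" for c in "ABCDEF"}
    classes.update({"NRDC": "housekeeping", "OTUD5": "housekeeping", "TUBB": "housekeeping"})
    classes.update({"G1": "endogenous", "G2": "endogenous"})
    counts = {}
    for sample, pos, hk in (("s1", 100, 150), ("s2", 200, 300), ("s3", 400, 600)):
        col = {f"POS_{c}": pos for c in "ABCDEF"}
        col.update({"NRDC": hk, "OTUD5": hk, "TUBB": hk})
        col.update({"G1": 10 * pos, "G2": 50})
        counts[sample] = col
    return build_matrix(counts, classes, {s: "B1" for s in counts})


def make_annotation(sample_id, subject="S1", date="2023-01-04", group="patient",
                    batch="B1", stimulation="none", **kw) -> SampleAnnotation:
    return SampleAnnotation(
        sample_id=sample_id, subject_id=subject, date=dt.date.fromisoformat(date),
        group=group, batch=batch, stimulation=stimulation, **kw,
    )
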