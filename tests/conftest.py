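import numpy as np
import pytest

from csvh import classifier, synthetic
from csvh.classifier import CSVHConfig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blob_dataset():
    """Default two-blob scene with planted far outliers and overlap points."""
    return synthetic.make_blobs_with_outliers(seed=0)


@pytest.fixture(scope="session")
def blob_model(blob_dataset):
    """Model fitted at the within-class kernel scale (resolves outlier structure)."""
    ds = blob_dataset
    return classifier.fit(ds.patient_X, ds.health_X, CSVHConfig(width=1.0))


@pytest.fixture(scope="session")
def clean_blob_dataset():
    """Well-separated blobs without planted anomalies."""
    return synthetic.make_blobs_with_outliers(outlier_frac=0.0, overlap_frac=0.0, seed=0)
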