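import numpy as np
import pytest

from mammocalc.classify import two_stage_classify
from mammocalc.dtcwt_core import default_filter_bank
from mammocalc.features import extract_features
from mammocalc.image_io import normalize_gray
from mammocalc.synthetic import generate_dataset


@pytest.fixture(scope="session")
def bank():
    return default_filter_bank()


@pytest.fixture(scope="session")
def default_dataset():
    """The default 50-ROI synthetic study (25 normal / 25 abnormal, seed 0)."""
    return generate_dataset(seed=0)


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """Feature matrix and labels of the default study (computed once)."""
    X = np.array([extract_features(normalize_gray(r.image)).values
                  for r in default_dataset])
    labels = np.array([r.label for r in default_dataset], dtype=object)
    return X, labels


@pytest.fixture(scope="session")
def default_cv_reports(default_features):
    """Two-stage LOOCV reports on the default study (computed once)."""
    X, labels = default_features
    return two_stage_classify(X, labels)
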