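"""Shared fixtures: synthetic datasets, feature tables, and CV reports.

The heavier artifacts (feature tables and cross-validation reports of the
canned fixtures) are session-scoped so the ensemble, synthetic-data and
acceptance tests share one computation.
"""

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from plantloc.descriptors import extract_table
from plantloc.evaluate import cross_validate
from plantloc.synthdata import make_fixture


def random_sequences(n, rng, min_len=15, max_len=500):
    from plantloc.seqio import AA_ALPHABET

    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(list(AA_ALPHABET), size=length)))
    return out


@pytest.fixture(scope="session")
def tiny_data():
    dataset, scores = make_fixture("tiny")
    features = extract_table(dataset, scores)
    return dataset, scores, features


@pytest.fixture(scope="session")
def strong_data():
    dataset, scores = make_fixture("strong")
    features = extract_table(dataset, scores)
    return dataset, scores, features


@pytest.fixture(scope="session")
def strong_cv(strong_data):
    dataset, _, features = strong_data
    y = [r.labels for r in dataset]
    return cross_validate(features, y, folds=10, seed=1)


@pytest.fixture(scope="session")
def null_cv():
    dataset, scores = make_fixture("null")
    features = extract_table(dataset, scores)
    y = [r.labels for r in dataset]
    return cross_validate(features, y, folds=10, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
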