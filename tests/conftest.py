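"""Shared fixtures: rendered-cell feature tables and a trained classifier.

The expensive artifacts (labeled synthetic cells, the fitted random forest)
are built once per session and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import nucleoscreen as ns
from nucleoscreen.plate_io import make_training_features


@pytest.fixture(scope="session")
def clean_optics() -> ns.OpticsConfig:
    """Default rendering optics without vignetting (post-correction regime)."""
    return ns.OpticsConfig(vignette=False)


@pytest.fixture(scope="session")
def labeled_features(clean_optics) -> pd.DataFrame:
    """Feature table for 1000 rendered cells with ground-truth class labels."""
    return make_training_features(clean_optics, n_cells=1000, seed=3)


@pytest.fixture(scope="session")
def feature_split(labeled_features):
    """Deterministic 80/20 train/test split of the labeled cells."""
    rng = np.random.default_rng(1)
    idx = rng.permutation(len(labeled_features))
    cut = int(0.8 * len(labeled_features))
    train = labeled_features.iloc[idx[:cut]].reset_index(drop=True)
    test = labeled_features.iloc[idx[cut:]].reset_index(drop=True)
    return train, test


@pytest.fixture(scope="session")
def trained_model(feature_split) -> ns.ClassifierModel:
    train, _ = feature_split
    return ns.train_classifier(train, train["true_class"], seed=1)


def match_labels(truth: np.ndarray, predicted: np.ndarray, iou_min: float = 0.5):
    """Greedy IoU matching between two label grids; returns (tp, fp, fn)."""
    matched_t, matched_p = set(), set()
    for t in range(1, int(truth.max()) + 1):
        tmask = truth == t
        for p in np.unique(predicted[tmask]):
            if p == 0 or p in matched_p:
                continue
            pmask = predicted == p
            iou = np.logical_and(tmask, pmask).sum() / np.logical_or(tmask, pmask).sum()
            if iou >= iou_min:
                matched_t.add(t)
                matched_p.add(int(p))
                break
    tp = len(matched_p)
    return tp, int(predicted.max()) - tp, int(truth.max()) - len(matched_t)
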