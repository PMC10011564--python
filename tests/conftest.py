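import numpy as np
import pytest

import darcsign as ds
from darcsign import classifier as clf
from darcsign.types import ArmMap, ChromosomeArms, CopySegment

MB = 1_000_000


@pytest.fixture(scope="session")
def toy_arm_map() -> ArmMap:
    """Two small chromosomes with arms meeting at the centromere."""
    return ArmMap(
        chromosomes={
            "1": ChromosomeArms(length=100 * MB, centromere=40 * MB,
                                p=(1, 40 * MB), q=(40 * MB + 1, 100 * MB)),
            "2": ChromosomeArms(length=60 * MB, centromere=25 * MB,
                                p=(1, 25 * MB), q=(25 * MB + 1, 60 * MB)),
        }
    )


def make_segment(chrom="1", start=1, end=MB, total=2, major=1, minor=1) -> CopySegment:
    return CopySegment(chrom=chrom, start=start, end=end,
                       total_cn=total, major_cn=major, minor_cn=minor)


@pytest.fixture(scope="session")
def trained_cohort():
    """A 40-per-class simulated cohort with the three binary models trained.

    Shared by the parameter-recovery and attribution tests; training uses
    the desk-scale profile (coarse grid, capped rounds).
    """
    cohort = ds.simulate_cohort(40, seed=7)
    X, labels = cohort.feature_matrix()
    models = {}
    evaluations = {}
    for target in ("BRCA2d", "CDK12d", "MMRd"):
        y = clf.binarize_labels(labels.values, target)
        config = clf.TrainConfig.test_profile(seed=7)
        train_idx, test_idx = clf.stratified_split(y, config.test_fraction, seed=7)
        model = clf.grid_search_train(X.iloc[train_idx], y[train_idx], target, config)
        p = clf.predict_proba(model, X)
        model.threshold = clf.derive_threshold(y[train_idx], p[train_idx])
        models[target] = model
        evaluations[target] = clf.evaluate(y[test_idx], p[test_idx])
    return {"cohort": cohort, "X": X, "labels": labels,
            "models": models, "evaluations": evaluations}
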