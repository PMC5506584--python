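import numpy as np
import pytest

import restcombine as rc


SMALL_GRIDS = rc.SelectionGrids(
    percents=(10, 30, 50),
    c_grid=(0.25, 1.0, 4.0),
    gamma_grid=(2 ** -4, 2 ** -2, 1.0),
    inner_k=5,
    seed=0,
)


@pytest.fixture(scope="session")
def small_grids():
    """Reduced search grids keeping nested-CV tests fast."""
    return SMALL_GRIDS


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny deterministic null cohort shared by read-only tests."""
    spec = rc.CohortSpec(n_per_group=4, grid_shape=(8, 8, 8), n_rois=8,
                         n_timepoints=120, seed=11)
    return rc.generate_cohort(spec), spec


@pytest.fixture(scope="session")
def cleaned_subject(small_cohort):
    subjects, _ = small_cohort
    return rc.preprocess_subject(subjects[0])


def make_feature_sets(X_by_type, y):
    """Wrap raw per-type matrices into FeatureSet objects for the CV driver."""
    n = len(y)
    out = []
    for i in range(n):
        feats = {
            ft: rc.FeatureVector(
                feature_type=ft,
                names=tuple(f"f{j}" for j in range(X.shape[1])),
                values=X[i],
            )
            for ft, X in X_by_type.items()
        }
        out.append(rc.FeatureSet(subject_id=f"s{i:03d}", label=int(y[i]),
                                 features=feats))
    return out


@pytest.fixture(scope="session")
def balanced_labels_40():
    return np.array([-1] * 20 + [1] * 20)
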