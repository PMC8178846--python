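import numpy as np
import pandas as pd
import pytest

from dormsig.data_model import CohortSurvival, ExpressionMatrix, GeneSignature


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, two groups of a single model."""
    values = pd.DataFrame(
        [[5.0, 5.5, 7.0, 7.2], [8.0, 8.1, 8.0, 7.9], [3.0, 2.8, 3.1, 3.3]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    ann = pd.DataFrame(
        {
            "model_id": ["m1"] * 4,
            "group": ["RL", "RL", "PT", "PT"],
            "cohort_id": [""] * 4,
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return ExpressionMatrix(values, ann)


@pytest.fixture
def cohort_matrix() -> ExpressionMatrix:
    """2 genes x 3 samples in one cohort, hand-set values for score oracles."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [6.0, 4.0, 2.0]],
        index=["G1", "G2"],
        columns=["p1", "p2", "p3"],
    )
    ann = pd.DataFrame(
        {
            "model_id": [""] * 3,
            "group": [""] * 3,
            "cohort_id": ["c1"] * 3,
        },
        index=pd.Index(["p1", "p2", "p3"], name="sample_id"),
    )
    return ExpressionMatrix(values, ann)


@pytest.fixture
def toy_cohort() -> CohortSurvival:
    return CohortSurvival(
        patient_ids=np.array([f"p{i}" for i in range(6)], dtype=object),
        time_months=np.array([5.0, 8.0, 12.0, 20.0, 33.0, 40.0]),
        event=np.array([1, 1, 0, 1, 1, 1]),
        endpoint="RFS",
        cohort_id="toy",
    )


@pytest.fixture
def sig_pm() -> GeneSignature:
    return GeneSignature([("G1", 1.0), ("G2", -1.0)], name="pm")


def make_cohort(time, event, cohort_id="c", endpoint="RFS") -> CohortSurvival:
    time = np.asarray(time, dtype=float)
    return CohortSurvival(
        patient_ids=np.array(
            [f"{cohort_id}_p{i}" for i in range(len(time))], dtype=object
        ),
        time_months=time,
        event=np.asarray(event, dtype=int),
        endpoint=endpoint,
        cohort_id=cohort_id,
    )
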