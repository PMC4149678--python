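import pandas as pd
import pytest

from refnorm.core_data import IntensityMatrix, SampleRecord


@pytest.fixture
def small_matrix() -> IntensityMatrix:
    """3 samples x 2 metabolites, fully observed."""
    return IntensityMatrix(
        pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
            index=["s1", "s2", "s3"],
            columns=["m1", "m2"],
        )
    )


def make_records(spec: list[tuple]) -> list[SampleRecord]:
    """Build records from (sample_id, batch, run_order, role[, entry]) tuples."""
    out = []
    for row in spec:
        sid, batch, order, role = row[:4]
        entry = row[4] if len(row) > 4 else ""
        out.append(
            SampleRecord(
                sample_id=sid,
                batch_id=batch,
                run_order=order,
                role=role,
                entry=entry,
                dry_weight_mg=3.0,
                is_intensity=1000.0,
            )
        )
    return out


@pytest.fixture
def one_batch_records() -> list[SampleRecord]:
    """One batch, runs 1..6, reference injections at orders 3 and 6."""
    return make_records(
        [
            ("t1", "B1", 1, "test"),
            ("t2", "B1", 2, "test"),
            ("r1", "B1", 3, "reference"),
            ("t3", "B1", 4, "test"),
            ("t4", "B1", 5, "test"),
            ("r2", "B1", 6, "reference"),
        ]
    )
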