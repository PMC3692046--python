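import numpy as np
import pytest

from tmakit import io, synthetic


@pytest.fixture
def tiny_grid_csv(tmp_path):
    """3 samples x (2 replicate columns of MarkerA + batch + covariate)."""
    p = tmp_path / "grid.csv"
    p.write_text(
        "id,MarkerA,MarkerA,*Batch,*covAge\n"
        "P1,2.0,4.0,B1,61\n"
        "P2,NA,3.0,B1,58\n"
        "P3,1.5,NaN,B2,70\n"
    )
    return p


@pytest.fixture
def default_cohort():
    return synthetic.generate_cohort(synthetic.default_spec(seed=11))


def make_table(values, batch=None, columns=None, score_kind=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return io.MarkerTable(
        sample_ids=[f"S{i}" for i in range(n)],
        columns=columns or [f"g{j}" for j in range(m)],
        values=values,
        replicate_map={},
        batch=None if batch is None else np.asarray(batch, dtype=object),
        score_kind=score_kind or {},
    )
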