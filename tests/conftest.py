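import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from icamp.datatypes import ExpressionStudy

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


def make_study(values, study_id="s1", n_cancer=None):
    """Build an ExpressionStudy from a genes x samples array.

    The first half of the columns (or ``n_cancer``) are cancer samples.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if n_cancer is None:
        n_cancer = n_samples // 2
    samples = [f"c{i}" for i in range(n_cancer)] + [
        f"n{i}" for i in range(n_samples - n_cancer)
    ]
    class_of = {s: ("cancer" if s.startswith("c") else "normal") for s in samples}
    df = pd.DataFrame(
        values,
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"),
        columns=samples,
    )
    return ExpressionStudy(study_id=study_id, values=df, class_of=class_of)


@pytest.fixture
def toy_study():
    """5 genes, 3 cancer vs 3 normal, fixed values."""
    rng = np.random.default_rng(42)
    base = rng.normal(7, 1, size=(5, 6))
    base[0, :3] += 3.0   # strongly up
    base[1, :3] -= 3.0   # strongly down
    return make_study(base)
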