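import numpy as np
import pandas as pd
import pytest

from mvharmonize import PanelData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(n=60, p=4, M=3, I=2, seed=0, batch_shift=None, batch_scale=None):
    """Small synthetic panel: covariate effects + optional batch effects.

    ``batch_shift``/``batch_scale`` are per-batch scalars applied to every
    slice of that batch's residuals.
    """
    rng = np.random.default_rng(seed)
    age = rng.normal(50, 10, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    base = n // I
    sizes = [base] * I
    sizes[-1] += n - base * I
    batch = np.concatenate([np.full(s, f"b{i}") for i, s in enumerate(sizes)])
    values = (
        rng.standard_normal((n, p, M))
        + 0.05 * age[:, None, None]
        + 0.5 * sex[:, None, None]
    )
    if batch_shift is not None:
        for i, lab in enumerate(sorted(set(batch))):
            values[batch == lab] += batch_shift[i]
    if batch_scale is not None:
        mean = values.mean(axis=0)
        for i, lab in enumerate(sorted(set(batch))):
            m = batch == lab
            values[m] = mean + (values[m] - mean) * batch_scale[i]
    return PanelData(
        values=values,
        batch=batch,
        covariates=pd.DataFrame({"age": age, "sex": sex}),
        feature_ids=[f"roi{v:02d}" for v in range(p)],
        metric_ids=[f"met{m}" for m in range(M)],
    )


@pytest.fixture
def small_panel():
    return make_panel()
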