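import numpy as np
import pytest
from hypothesis import settings
from threadpoolctl import threadpool_limits

# single-threaded BLAS: batched-matmul reduction order, and therefore
# early-stopping epoch selection, stays bit-reproducible across machines
_limiter = threadpool_limits(limits=1)

from wardwatch.cohort import prepare_cohort
from wardwatch.synthetic import default_config, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort2000():
    """One full-size study cohort shared across tests (seed fixed)."""
    config = default_config(n_stays=2000, seed=11)
    stays = generate_cohort(config)
    kept, labels, audit = prepare_cohort(stays)
    return {"config": config, "stays": stays, "kept": kept,
            "labels": np.array(labels), "audit": audit}


def make_tensor(X, M=None, static=(0.0, 1.0), label=0, channels=None,
                numeric=None, stay_id="s0", normalized=True):
    """Hand-rolled StayTensor for unit tests."""
    from wardwatch.preprocess import StayTensor, compute_delta

    X = np.asarray(X, dtype=float)
    M = (~np.isnan(X)).astype(float) if M is None else np.asarray(M, dtype=float)
    X = np.where(M == 1, np.nan_to_num(X), np.nan)
    T, D = X.shape
    channels = channels or [f"ch{i}" for i in range(D)]
    numeric = np.ones(D, dtype=bool) if numeric is None else np.asarray(numeric)
    return StayTensor(stay_id=stay_id, X=X, M=M, Delta=compute_delta(M),
                      static=np.asarray(static, dtype=float), label=label,
                      channels=channels, numeric=numeric,
                      day_times=np.arange(T, dtype=float),
                      normalized=normalized)
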