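import numpy as np
import pytest

import trialbf as tb


@pytest.fixture(scope="session")
def sleepiness_summary() -> tb.StudySummary:
    """Summary statistics of the duty-hour sleepiness reanalysis: two medical
    training programs compared on a 9-point sleepiness scale, where the
    experimental (flexible) program must not be worse by more than 1 point."""
    return tb.StudySummary(
        n_x=193, n_y=205, mean_x=4.7, mean_y=4.8,
        ci_margin=0.19, ci_level=0.95, mode="means_ci",
    )


def make_summary(t: float, m: int, sd_pooled: float = 1.0) -> tb.StudySummary:
    """Equal-group summary with unit SDs whose two-sample t equals ``t``."""
    se = sd_pooled * np.sqrt(2.0 / m)
    return tb.StudySummary(
        n_x=m, n_y=m, mean_x=0.0, mean_y=t * se,
        sd_x=sd_pooled, sd_y=sd_pooled,
    )


def exact_moments(n: int, mean: float, sd: float, rng) -> np.ndarray:
    """A vector with exactly the requested sample mean and (n-1) SD."""
    base = rng.normal(size=n)
    base -= base.mean()
    base /= base.std(ddof=1)
    return mean + sd * base
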