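import numpy as np
import pytest

from sexalloc import DispersalParams, ReproductionParams, ResourceBudget

# the fully printed reference parameter set used throughout the illustrations
BASE = dict(R=5000.0, r_f=10.0, r_m=1.0, w=1.0, h=1000.0)


@pytest.fixture
def base_budget() -> ResourceBudget:
    return ResourceBudget(BASE["R"], BASE["r_f"], BASE["r_m"])


@pytest.fixture
def base_disp() -> DispersalParams:
    return DispersalParams(h=BASE["h"], w=BASE["w"])


def random_paramsets(n: int, seed: int, with_alpha: bool = True):
    """Random valid (params, disp) pairs; h*r_f/R > 1 so the structural bound
    F <= h never truncates the allocation interval."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        R = rng.uniform(200, 20000)
        r_m = rng.uniform(0.5, 5)
        r_f = r_m * rng.uniform(2, 50)
        w = rng.uniform(0.05, 1.0)
        h = rng.uniform(1.2 * R / r_f, 20 * R / r_f)
        if h <= 3:
            continue
        budget = ResourceBudget(R, r_f, r_m)
        disp = DispersalParams(h=h, w=w)
        if with_alpha:
            alpha = rng.uniform(0.05, 0.95)
            out.append((budget.with_allocation(alpha), disp))
        else:
            out.append((budget, disp))
    return out
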