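import numpy as np
import pytest

from hypermet import AcquisitionScheme, ConversionSet, Pool
from hypermet.synthetic_data import Scenario


@pytest.fixture
def two_product_scenario() -> Scenario:
    """A well-conditioned substrate + two-product scenario for fitting tests."""
    return Scenario(
        substrate=Pool("sub", T1=50.0, role="substrate", s0=1.0,
                       chemical_shift=170.0, linewidth_hz=2.0),
        products=(
            Pool("prod_a", T1=30.0, chemical_shift=160.0, linewidth_hz=2.0),
            Pool("prod_b", T1=15.0, chemical_shift=180.0, linewidth_hz=2.0),
        ),
        conversions=ConversionSet({"prod_a": 3.0e-3, "prod_b": 1.5e-3}),
        scheme=AcquisitionScheme(flip_angle=5.0, repetition_time=3.0,
                                 n_acquisitions=60, transfer_time=25.0),
        seed=7,
    )


def random_scenario(rng: np.random.Generator, n_products: int = 1,
                    flip_angle: float = 5.0) -> Scenario:
    """Random but identifiable scenario; rates and T1s in realistic ranges."""
    names = [f"p{i}" for i in range(n_products)]
    products = tuple(
        Pool(n, T1=float(rng.uniform(8.0, 60.0)), chemical_shift=150.0 + 10 * i,
             linewidth_hz=2.0)
        for i, n in enumerate(names)
    )
    rates = {n: float(rng.uniform(5e-4, 5e-3)) for n in names}
    return Scenario(
        substrate=Pool("sub", T1=float(rng.uniform(20.0, 80.0)), role="substrate",
                       s0=1.0, chemical_shift=170.0, linewidth_hz=2.0),
        products=products,
        conversions=ConversionSet(rates),
        scheme=AcquisitionScheme(flip_angle=flip_angle, repetition_time=3.0,
                                 n_acquisitions=60),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
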