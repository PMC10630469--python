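"""Shared fixtures: small seeded catalogs, window schemes and runs.

Everything is generated programmatically; nothing is read from disk
except what a test itself writes into tmp_path.
"""

import numpy as np
import pytest

from diawin.features import MS1Feature
from diawin.simulate import SimDesign, make_catalog, simulate_dia_run
from diawin.windows import WindowParams, design_windows


def synthetic_features(seed: int, n: int = 1000) -> list[MS1Feature]:
    """Non-uniform m/z layout over the 300–1000 Th acquisition range,
    echoing the class-clustered density of a plasma extract."""
    rng = np.random.default_rng(seed)
    parts = [
        rng.normal(880, 35, int(n * 0.30)),
        rng.normal(780, 30, int(n * 0.25)),
        rng.normal(730, 35, int(n * 0.15)),
        rng.normal(510, 25, int(n * 0.12)),
        rng.normal(600, 35, n - int(n * 0.30) - int(n * 0.25) - int(n * 0.15) - int(n * 0.12)),
    ]
    mz = np.clip(np.concatenate(parts), 300.0, 1000.0)
    return [MS1Feature(mz=float(m), rt_apex=5.0, area=1.0, height=1.0) for m in mz]


@pytest.fixture(scope="session")
def plasma_features() -> list[MS1Feature]:
    return synthetic_features(seed=1)


@pytest.fixture(scope="session")
def window_scheme(plasma_features):
    """The study configuration: 20 windows, widths 10–100 Th, range
    300–1000 Th, 0.5 Th edge extension, density radius 2.5 Th."""
    return design_windows(plasma_features, WindowParams())


@pytest.fixture(scope="session")
def small_catalog():
    """50 species compressed into a short elution window; keeps run
    rendering fast while preserving realistic co-elution."""
    return make_catalog(50, seed=21, rt_range=(0.5, 3.5))


@pytest.fixture(scope="session")
def small_dia_run(small_catalog, window_scheme):
    design = SimDesign(
        catalog=small_catalog, windows=window_scheme,
        noise_cv=0.0, seed=21, rt_range=(0.3, 3.8),
    )
    return simulate_dia_run(design, sample_id="clean_run")
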