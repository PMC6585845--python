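import numpy as np
import pytest

import paveshape as ps


def circle_outline(n: int = 256, r: float = 1.0) -> ps.Outline:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return ps.Outline(np.column_stack([r * np.cos(th), r * np.sin(th)]))


def ellipse_outline(a: float, b: float, n: int = 256) -> ps.Outline:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return ps.Outline(np.column_stack([a * np.cos(th), b * np.sin(th)]))


@pytest.fixture
def unit_square() -> ps.Outline:
    return ps.Outline([[0, 0], [1, 0], [1, 1], [0, 1]])


@pytest.fixture
def rect_2x1() -> ps.Outline:
    return ps.Outline([[0, 0], [2, 0], [2, 1], [0, 1]])


@pytest.fixture
def plus_sign() -> ps.Outline:
    """Five unit squares in a plus; area 5, hull octagon of area 7."""
    return ps.Outline(
        [(1, 0), (2, 0), (2, 1), (3, 1), (3, 2), (2, 2), (2, 3), (1, 3), (1, 2), (0, 2), (0, 1), (1, 1)]
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced clade-structured dataset shared across statistics tests."""
    clades = [
        ps.CladeSpec(name="fern", n_species=8, solidity_mean=0.68, solidity_kappa=80.0,
                     ar_mean=0.60, ar_kappa=60.0, leaf_coupled=True),
        ps.CladeSpec(name="monocot", n_species=8, solidity_mean=0.88, solidity_kappa=120.0,
                     ar_mean=0.35, ar_kappa=40.0, leaf_coupled=True),
        ps.CladeSpec(name="eudicot", n_species=8, solidity_mean=0.78, solidity_kappa=80.0,
                     ar_mean=0.65, ar_kappa=60.0, leaf_coupled=False),
    ]
    return ps.make_dataset(clades, cells_per_side=10, seed=42)


@pytest.fixture(scope="session")
def small_metrics(small_dataset):
    return ps.measure_cells(small_dataset.cells)


@pytest.fixture(scope="session")
def small_summaries(small_dataset, small_metrics):
    from paveshape import stats

    return stats.summarize_species(small_metrics, small_dataset.leaves, small_dataset.meta)


@pytest.fixture(scope="session")
def factorial_grid():
    """400 lobed cells with aspect ratio and lobe amplitude varied on an
    independent 20 x 20 grid (area held near-constant), measured."""
    import pandas as pd

    rng = np.random.default_rng(0)
    rows = []
    for ar in np.linspace(0.3, 0.9, 20):
        for amp in np.linspace(0.0, 0.35, 20):
            o = ps.make_lobed_cell(
                ps.LobedCellParams(a=30 / np.sqrt(ar), b=30 * np.sqrt(ar), k=7, amp=float(amp),
                                   phase=float(rng.uniform(0, 2 * np.pi)),
                                   seed=int(rng.integers(2**31))))
            m = ps.measure(o)
            rows.append({"aspect_ratio": m.aspect_ratio, "area_um2": m.area,
                         "circularity": m.circularity, "solidity": m.solidity,
                         "ar_level": ar, "amp_level": amp})
    return pd.DataFrame(rows)
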