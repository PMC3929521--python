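import numpy as np
import pytest

from doepk import FactorDefinition, datasets


@pytest.fixture(scope="session")
def ccd_table():
    """Bundled 13-run face-centred CCD with measured responses."""
    return datasets.load_ccd_design()


@pytest.fixture(scope="session")
def ccd_design(ccd_table):
    """Design-only columns of the bundled CCD."""
    return ccd_table[["exp_no", "run_order", "A", "B", "point_type"]]


@pytest.fixture(scope="session")
def ccd_factors():
    return datasets.load_ccd_factors()


@pytest.fixture(scope="session")
def two_unit_factors():
    """Two generic factors on symmetric unit ranges."""
    return [
        FactorDefinition("factor one", "A", -1.0, 0.0, 1.0),
        FactorDefinition("factor two", "B", -1.0, 0.0, 1.0),
    ]


def normal_equations_fit(X, y):
    """Independent OLS oracle: solve X'X b = X'y directly."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def quadratic_design_matrix_2f(a, b):
    """Hand-built model matrix [1, a, b, ab, a^2, b^2] for the oracle."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return np.column_stack([np.ones_like(a), a, b, a * b, a**2, b**2])
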