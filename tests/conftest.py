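import numpy as np
import pytest

from cardioniche.profiles import StateProfileMatrix, profiles_from_anndata
from cardioniche.synthetic import SyntheticConfig, generate_reference, generate_sections


@pytest.fixture(scope="session")
def noise_free_config():
    return SyntheticConfig(seed=11, count_noise="none")


@pytest.fixture(scope="session")
def noise_free_reference(noise_free_config):
    adata, truth = generate_reference(noise_free_config)
    return adata, truth


@pytest.fixture(scope="session")
def noise_free_profiles(noise_free_reference):
    adata, _ = noise_free_reference
    return profiles_from_anndata(adata)


@pytest.fixture(scope="session")
def noise_free_sections(noise_free_config):
    return generate_sections(noise_free_config)


@pytest.fixture
def toy_profiles():
    """Hand-built 3-gene x 3-state profile matrix for formula-level checks."""
    import pandas as pd

    genes = pd.Index(["g1", "g2", "g3"], name="gene")
    states = ["A", "B", "C"]
    mean_expr = pd.DataFrame(
        [[1.0, 2.0, 3.0], [0.0, 0.0, 4.0], [5.0, 5.0, 5.0]], index=genes, columns=states
    )
    frac_expr = pd.DataFrame(
        [[0.25, 0.8, 1.0], [0.0, 0.05, 0.9], [1.0, 1.0, 1.0]],
        index=genes,
        columns=states,
    )
    return StateProfileMatrix(
        mean_expr=mean_expr,
        mean_linear=mean_expr.copy(),
        frac_expr=frac_expr,
        n_cells=__import__("pandas").Series({s: 10 for s in states}),
    )


def brute_force_pearson(a, b):
    """Textbook Pearson formula, written independently of the implementation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    num = (a * b).sum() - n * a.mean() * b.mean()
    den_a = np.sqrt((a**2).sum() - n * a.mean() ** 2)
    den_b = np.sqrt((b**2).sum() - n * b.mean() ** 2)
    if den_a == 0 or den_b == 0:
        return np.nan
    return num / (den_a * den_b)
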