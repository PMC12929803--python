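import numpy as np
import pandas as pd
import pytest

from coelunet import FractionScheme, ProfileMatrix, SimConfig, simulate_complexome


@pytest.fixture(scope="session")
def scheme() -> FractionScheme:
    return FractionScheme()


@pytest.fixture(scope="session")
def short_scheme() -> FractionScheme:
    return FractionScheme(n_fractions=20, start_s=0.0, width_s=19.0)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_proteins=60,
        n_complexes=8,
        differential_complexes={"C001": 2.0, "C002": 2.0},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config, scheme):
    return simulate_complexome(small_config, scheme)


def build_matrix(
    traces: dict[str, dict[tuple[str, str], list[float]]],
    scheme: FractionScheme,
) -> ProfileMatrix:
    """Assemble a ProfileMatrix from {protein: {(condition, replicate): trace}}."""
    blocks = {}
    samples: list[tuple[str, str]] = []
    for prot, per_sample in traces.items():
        for sample in per_sample:
            if sample not in samples:
                samples.append(sample)
    proteins = list(traces)
    for cond, rep in samples:
        for f in range(1, scheme.n_fractions + 1):
            blocks[(cond, rep, f)] = [
                traces[p].get((cond, rep), [np.nan] * scheme.n_fractions)[f - 1]
                for p in proteins
            ]
    cols = pd.MultiIndex.from_tuples(blocks, names=["condition", "replicate", "fraction"])
    data = pd.DataFrame(
        np.column_stack([blocks[c] for c in cols]), index=proteins, columns=cols
    )
    return ProfileMatrix(data, scheme)


def gaussian_trace(scheme: FractionScheme, apex: float, sigma: float = 2.0, height: float = 1e6):
    f = np.arange(1, scheme.n_fractions + 1, dtype=float)
    return height * np.exp(-0.5 * ((f - apex) / sigma) ** 2)
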