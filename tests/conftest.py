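import numpy as np
import pandas as pd
import pytest

from cochlear_aging import (
    BoltzmannParams,
    CircuitParams,
    ExpressionMatrix,
    StudyDesign,
    TwoSineProtocol,
    gen_expression_study,
    gen_voltage_clamp_recording,
)


@pytest.fixture(scope="session")
def circuit():
    return CircuitParams(rs=10.0, rm=500.0, clin=7.0)


@pytest.fixture(scope="session")
def boltzmann():
    return BoltzmannParams(qmax=800.0, alpha=33.0, vpk=-70.0)


@pytest.fixture(scope="session")
def protocol():
    return TwoSineProtocol()


@pytest.fixture(scope="session")
def short_protocol():
    """Fewer DC levels for faster simulator tests."""
    return TwoSineProtocol(dc_levels=(-120.0, -90.0, -70.0, -50.0, -20.0, 20.0))


@pytest.fixture(scope="session")
def noisefree_recording(circuit, boltzmann, protocol):
    return gen_voltage_clamp_recording(circuit, boltzmann, protocol, 0.0, seed=1)


@pytest.fixture(scope="session")
def small_study():
    return gen_expression_study(StudyDesign(n_genes=500, seed=42))


def toy_matrix(data: dict, kind: str = "rpkm", lengths=None) -> ExpressionMatrix:
    """Build a small ExpressionMatrix from {sample_name: {gene: value}}."""
    df = pd.DataFrame(data, dtype=float)
    df.index.name = "gene_symbol"
    gl = None
    if lengths is not None:
        gl = pd.Series(lengths, name="length_bp", dtype=float)
    return ExpressionMatrix(values=df, kind=kind, gene_lengths=gl)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
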