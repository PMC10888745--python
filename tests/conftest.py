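import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sigconn.io import CONTROL, TREATED, ExpressionMatrix, SignatureLibrary

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_expression(
    values: np.ndarray,
    genes: list[str] | None = None,
    n_ctrl: int = 3,
    cell_line: str = "A549",
) -> ExpressionMatrix:
    """Wrap a raw array (genes x samples) in a validated ExpressionMatrix;
    the first ``n_ctrl`` columns are controls, the rest treated."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i:03d}" for i in range(1, n_genes + 1)]
    cols = [f"s{i}" for i in range(1, n_samples + 1)]
    groups = {c: (CONTROL if i < n_ctrl else TREATED) for i, c in enumerate(cols)}
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=cols)
    return ExpressionMatrix(frame, groups, cell_line=cell_line)


def make_library(
    amplitudes: dict[str, np.ndarray],
    genes: list[str],
    cell_line: str = "A549",
    dose: str = "10 uM",
    time: str = "6 h",
) -> SignatureLibrary:
    """Build a library from a signature_id -> amplitude-vector map; each
    signature's perturbagen id is its own signature id."""
    frame = pd.DataFrame(amplitudes, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(
        {
            "perturbagen_id": list(amplitudes),
            "cell_line": cell_line,
            "dose": dose,
            "time": time,
        },
        index=pd.Index(list(amplitudes), name="signature_id"),
    )
    return SignatureLibrary(frame, meta)


@pytest.fixture
def five_gene_ref() -> SignatureLibrary:
    """Reference with signed ranks {A:+5, B:-4, C:+3, D:-2, E:+1}."""
    amps = np.array([5.0, -4.0, 3.0, -2.0, 1.0])
    return make_library({"REF": amps}, genes=list("ABCDE"))
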