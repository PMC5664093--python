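import numpy as np
import pandas as pd
import pytest

from pcafe.expression import ExpressionMatrix, SampleGroups


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """2 probes x 2 samples, values ((1,2),(3,4))."""
    return ExpressionMatrix(
        pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["p1", "p2"], columns=["s1", "s2"])
    )


@pytest.fixture
def balanced_groups():
    def make(n_a: int, n_b: int, labels=("a", "b")) -> tuple:
        ids = [f"s{i}" for i in range(n_a + n_b)]
        g = SampleGroups({s: (labels[0] if i < n_a else labels[1]) for i, s in enumerate(ids)})
        return ids, g

    return make


@pytest.fixture
def random_matrix():
    def make(n_probes: int, n_samples: int, seed: int = 0) -> ExpressionMatrix:
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            pd.DataFrame(
                rng.standard_normal((n_probes, n_samples)),
                index=[f"p{i}" for i in range(n_probes)],
                columns=[f"s{j}" for j in range(n_samples)],
            )
        )

    return make


def write_tsv(path, text: str) -> str:
    path.write_text(text)
    return str(path)
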