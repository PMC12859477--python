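import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from guidecall import BarcodeList, GuideCountMatrix, GuideLibrary

# pooled-screen fitting regime used across the mixture tests
MIXTURE_REGIME = dict(pi=0.1, w0=0.7, mu_lo=0.5, r_lo=1.0, mu_hi=100.0, r_hi=5.0)


def sample_mixture(n: int, seed: int, **kw) -> np.ndarray:
    """Draw mixture counts directly (independent of the fitted model's code)."""
    p = {**MIXTURE_REGIME, **kw}
    rng = np.random.default_rng(seed)
    x = np.zeros(n, dtype=np.int64)
    hi = rng.random(n) < p["pi"]
    x[hi] = rng.negative_binomial(p["r_hi"], p["r_hi"] / (p["r_hi"] + p["mu_hi"]), hi.sum())
    lo = ~hi
    nonzero = rng.random(lo.sum()) >= p["w0"]
    draws = np.zeros(lo.sum(), dtype=np.int64)
    draws[nonzero] = rng.negative_binomial(
        p["r_lo"], p["r_lo"] / (p["r_lo"] + p["mu_lo"]), nonzero.sum()
    )
    x[lo] = draws
    return x


@pytest.fixture
def toy_library() -> GuideLibrary:
    """Two dual-guide vectors (GATA5, NEUROG2) with fixed protospacers."""
    table = pd.DataFrame(
        {
            "guide_id": ["GATA5_PS1", "GATA5_PS2", "NEUROG2_PS1", "NEUROG2_PS2"],
            "protospacer": [
                "GATCGATCGATCGATCGATC",
                "TTTTGGGGCCCCAAAATTTT",
                "ACGTACGTACGTACGTACGT",
                "CCGGAATTCCGGAATTCCGG",
            ],
            "target": ["GATA5", "GATA5", "NEUROG2", "NEUROG2"],
            "vector_id": ["V_GATA5", "V_GATA5", "V_NEUROG2", "V_NEUROG2"],
        }
    )
    return GuideLibrary(table)


@pytest.fixture
def three_vector_library() -> GuideLibrary:
    """Three vectors: two gene-targeting, one non-targeting; six guides."""
    table = pd.DataFrame(
        {
            "guide_id": ["A_PS1", "A_PS2", "B_PS1", "B_PS2", "NT_PS1", "NT_PS2"],
            "protospacer": [
                "AAAACCCCGGGGTTTTAAAA",
                "CCCCGGGGTTTTAAAACCCC",
                "GGGGTTTTAAAACCCCGGGG",
                "TTTTAAAACCCCGGGGTTTT",
                "ACACACACACACACACACAC",
                "GTGTGTGTGTGTGTGTGTGT",
            ],
            "target": ["GENE_A", "GENE_A", "GENE_B", "GENE_B", "NT01", "NT01"],
            "vector_id": ["VA", "VA", "VB", "VB", "VNT", "VNT"],
        }
    )
    return GuideLibrary(table)


@pytest.fixture
def small_matrix() -> GuideCountMatrix:
    mat = sp.csr_matrix(np.array([[0, 3], [1, 0]], dtype=np.int64))
    return GuideCountMatrix(mat, ["AAAA", "CCCC"], ["g1", "g2"])


@pytest.fixture
def whitelist() -> BarcodeList:
    return BarcodeList(("AAAACCCCGGGGTTTT", "CCCCGGGGTTTTAAAA", "GGGGTTTTAAAACCCC"))
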