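import numpy as np
import pytest

from generank import EvidenceMatrix


@pytest.fixture
def small_csv(tmp_path):
    """Three-source gene-list upload: sources {A,B},{B,C},{C}, core {B}."""
    path = tmp_path / "evidence.csv"
    path.write_text("assoc,linkage,expr,core\nA,B,C,B\nB,C,,\n", encoding="utf-8")
    return path


def make_separable(n_core: int, n_other: int) -> EvidenceMatrix:
    """Core genes carry evidence only in category 1, others only in category 2.

    Any weight vector with w1 > w2 ranks every core gene above every other
    gene, so the objective optimum is (|C|+1)/(2M) exactly.
    """
    genes = [f"C{i:03d}" for i in range(n_core)] + [f"X{i:03d}" for i in range(n_other)]
    genes = sorted(genes)
    core = {g for g in genes if g.startswith("C")}
    indicator = np.array([[1, 0] if g in core else [0, 1] for g in genes], dtype=np.int8)
    return EvidenceMatrix(("cat1", "cat2"), tuple(genes), indicator, frozenset(core))


def make_random_matrix(rng: np.random.Generator, n_genes=30, n_cat=3, n_core=5) -> EvidenceMatrix:
    """Random valid matrix: uniform 0/1 rows, all-zero rows repaired."""
    genes = tuple(f"G{i:03d}" for i in range(n_genes))
    indicator = (rng.random((n_genes, n_cat)) < 0.4).astype(np.int8)
    for i in np.flatnonzero(indicator.sum(axis=1) == 0):
        indicator[i, rng.integers(n_cat)] = 1
    core = frozenset(rng.choice(genes, size=n_core, replace=False).tolist())
    cats = tuple(f"c{j}" for j in range(n_cat))
    return EvidenceMatrix(cats, genes, indicator, core)


@pytest.fixture
def separable_matrix():
    return make_separable(4, 16)
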