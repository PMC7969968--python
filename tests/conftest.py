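import numpy as np
import pandas as pd
import pytest

from regulonpulse.diffexpr import DEGSet
from regulonpulse.formats import COGAnnotation, CountMatrix, RegulatoryNetwork


@pytest.fixture
def tiny_network() -> RegulatoryNetwork:
    """Two sigma factors and four TFs over four genes, every mode present."""
    rows = [
        ("RpoD", "sigma", "g1", "activator"),
        ("RpoD", "sigma", "g2", "activator"),
        ("RpoD", "sigma", "g4", "activator"),
        ("RpoS", "sigma", "g1", "activator"),
        ("RpoS", "sigma", "g3", "activator"),
        ("MarA", "TF", "g1", "activator"),
        ("MarA", "TF", "g2", "repressor"),
        ("Fur", "TF", "g3", "repressor"),
        ("OxyR", "TF", "g2", "dual"),
        ("IscR", "TF", "g4", "unknown"),
    ]
    return RegulatoryNetwork(
        pd.DataFrame(rows, columns=["regulator", "reg_class", "target", "mode"])
    )


@pytest.fixture
def tiny_annotation() -> COGAnnotation:
    return COGAnnotation(
        {
            "g1": frozenset("J"),
            "g2": frozenset("CE"),
            "g3": frozenset(),
            "g4": frozenset("O"),
        }
    )


@pytest.fixture
def tiny_degs() -> DEGSet:
    return DEGSet("amp", "stat", frozenset({"g1"}), frozenset({"g2", "g3"}), 2.0, 0.1)


@pytest.fixture
def tiny_counts() -> CountMatrix:
    counts = pd.DataFrame(
        {"s1": [100, 50, 10], "s2": [200, 100, 20]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    design = pd.DataFrame(
        {"condition": ["a", "b"], "replicate": ["1", "1"]},
        index=pd.Index(["s1", "s2"], name="sample"),
    )
    return CountMatrix(counts, design)


def nb_counts(rng, mean, alpha):
    """NB draws with mean ``mean`` and variance ``mean + alpha*mean**2``."""
    n = 1.0 / np.asarray(alpha, dtype=float)
    return rng.negative_binomial(n, n / (n + np.asarray(mean, dtype=float)))


def matrix_from_arrays(counts, conditions_per_sample):
    """Assemble a CountMatrix from a raw array and per-sample condition labels."""
    genes = [f"g{i:04d}" for i in range(counts.shape[0])]
    reps: dict[str, int] = {}
    samples = []
    for cond in conditions_per_sample:
        reps[cond] = reps.get(cond, 0) + 1
        samples.append(f"{cond}_r{reps[cond]}")
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    design = pd.DataFrame(
        {
            "condition": list(conditions_per_sample),
            "replicate": [s.rsplit("_r", 1)[1] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(frame, design)
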