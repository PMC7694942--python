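import numpy as np
import pandas as pd
import pytest

import immunotype as it


@pytest.fixture
def small_expr() -> it.ExpressionMatrix:
    """4 genes x 2 samples with strictly decreasing values in each sample."""
    values = pd.DataFrame(
        [[4.0, 4.0], [3.0, 3.0], [2.0, 2.0], [1.0, 1.0]],
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
        columns=["A", "B"],
    )
    return it.ExpressionMatrix(values=values)


@pytest.fixture
def toy_sets() -> it.GeneSetCollection:
    return it.GeneSetCollection(sets={"top2": ["g1", "g2"], "bottom": ["g4"]})


@pytest.fixture(scope="session")
def small_cohort() -> it.SyntheticCohort:
    """A scaled-down cohort (20/stratum, 400 genes) for fast module tests."""
    spec = it.default_paperlike_spec(
        n_genes=700, n_per_stratum=(20, 20, 20), immune_set_size=8)
    return it.generate_cohort(spec, seed=101)


@pytest.fixture(scope="session")
def small_run(small_cohort) -> it.SubtypingRun:
    return it.immune_subtypes(small_cohort.expression, small_cohort.gene_sets,
                              small_cohort.immune_set_names)


def ssgsea_oracle(values: np.ndarray, gene_ids: list, set_genes: set,
                  alpha: float) -> float:
    """Exhaustive step-by-step running-sum re-computation for ONE sample.

    Independent of the vectorized implementation: explicit average ranks,
    explicit stable walk, explicit cumulative fractions.
    """
    n = len(values)
    # average ranks, largest value -> rank n
    order_asc = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order_asc[j + 1]] == values[order_asc[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order_asc[k]] = avg
        i = j + 1
    # walk: decreasing value, ties by input order (stable)
    walk = sorted(range(n), key=lambda i: (-values[i], i))
    in_weights = [abs(ranks[i]) ** alpha for i in walk if gene_ids[i] in set_genes]
    total_in = sum(in_weights)
    n_out = n - len(in_weights)
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for i in walk:
        if gene_ids[i] in set_genes:
            cum_in += abs(ranks[i]) ** alpha / total_in
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def math_oracle(vafs: np.ndarray) -> float:
    """Direct median/MAD computation, independent of the genomics module."""
    v = sorted(vafs)
    n = len(v)
    med = v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2
    dev = sorted(abs(x - med) for x in v)
    mad = 1.4826 * (dev[n // 2] if n % 2 else (dev[n // 2 - 1] + dev[n // 2]) / 2)
    return 100.0 * mad / med


def weighted_f_oracle(confusion: np.ndarray) -> float:
    """Weighted F1 straight from a confusion matrix (rows true, cols predicted)."""
    k = confusion.shape[0]
    supports = confusion.sum(axis=1)
    f1s = []
    for c in range(k):
        tp = confusion[c, c]
        prec = tp / confusion[:, c].sum() if confusion[:, c].sum() else 0.0
        rec = tp / supports[c] if supports[c] else 0.0
        f1s.append(0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec))
    return float(sum(s * f for s, f in zip(supports, f1s)) / supports.sum())
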