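"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pandas as pd
import pytest

from igaseq import CountTable, SampleManifest


def brute_force_unifrac(tree, present_a, present_b) -> float:
    """Unweighted UniFrac by per-branch XOR/OR enumeration.

    Walks every non-root branch, collects the tip set below it, and sums
    branch lengths over branches leading to exactly one (unique) or at
    least one (union) of the two presence sets.  Independent of any
    traversal-order optimization.
    """
    a, b = set(present_a), set(present_b)
    unique = union = 0.0
    for node in tree.traverse(include_self=False):
        clade = {tip.name for tip in node.tips()} or {node.name}
        length = node.length or 0.0
        in_a = bool(clade & a)
        in_b = bool(clade & b)
        if in_a != in_b:
            unique += length
        if in_a or in_b:
            union += length
    return unique / union if union > 0 else 0.0


def brute_force_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up from its definition.

    adj_(i) = min_{j >= i} min(1, m * p_(j) / j) over the sorted p's.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, m * p[order] / np.arange(1, m + 1))
    for i in range(m - 2, -1, -1):
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@pytest.fixture
def small_table() -> CountTable:
    data = pd.DataFrame(
        {"s1": [5, 2, 0], "s2": [0, 1, 4]},
        index=pd.Index(["T1", "T2", "T3"], name="taxon_id"))
    return CountTable(data)


@pytest.fixture
def paired_manifest() -> SampleManifest:
    rows = []
    for subj, group in (("A00", "axSpA"), ("A01", "axSpA"), ("H00", "HC"),
                        ("H01", "HC")):
        for frac in ("pos", "neg"):
            rows.append({"sample_id": f"{subj}_{frac}", "subject_id": subj,
                         "site": "fecal", "fraction": frac, "group": group,
                         "basdai": 4.0 if group == "axSpA" else 1.0})
    return SampleManifest(pd.DataFrame(rows))
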