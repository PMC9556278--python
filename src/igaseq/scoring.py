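"""The IgA coating index and enrichment/depletion calling.

For a taxon with relative abundance a+ in the IgA+ (coated) fraction and
a- in the IgA- (uncoated) fraction of the same subject, the coating
index is the log ratio

    index = -(log a+ - log a-) / (log a+ + log a-).

Both logs are negative for proportions in (0, 1), so the index is
bounded in [-1, 1]; it is antisymmetric under swapping the fractions and
invariant to the logarithm base (the base cancels).  Positive values
mean the taxon is preferentially IgA-coated (enriched in the IgA+
fraction).

Enrichment within a group is called by a two-sided one-sample Wilcoxon
signed-rank test of the per-subject index against 0 — the natural paired
test for this design — with Benjamini-Hochberg correction across taxa;
the direction of a significant call is the sign of the median index.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .qc import to_relative_abundance, DEFAULT_PSEUDOCOUNT
from .stats import bh_adjust, rank_sum_test, signed_rank_test
from .tables import PairedFractionTable, SampleManifest

logger = logging.getLogger(__name__)

DEFAULT_MIN_N = 5


def iga_index(p_pos: float, p_neg: float) -> float:
    """Coating index of one taxon in one subject.

    Arguments are the taxon's relative abundances in the IgA+ and IgA-
    fractions and must lie strictly inside (0, 1) (apply a pseudocount
    upstream if a fraction count can be zero).
    """
    p_pos = float(p_pos)
    p_neg = float(p_neg)
    for name, v in (("p_pos", p_pos), ("p_neg", p_neg)):
        if not 0.0 < v < 1.0:
            raise ValueError(
                f"{name}={v} is outside (0, 1); apply a pseudocount before "
                "computing the coating index")
    lp, ln = np.log(p_pos), np.log(p_neg)
    return float(-(lp - ln) / (lp + ln))


def iga_index_matrix(paired: PairedFractionTable,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-taxon, per-subject coating index (taxa x subjects).

    Relative abundances are computed per fraction with the pseudocount;
    cells where the taxon was undetected in BOTH fractions of a subject
    are missing (NaN) — double absence is no evidence about coating.
    """
    if pseudocount <= 0:
        raise ValueError("iga_index_matrix requires pseudocount > 0")
    rel_pos = to_relative_abundance(paired.counts_pos, pseudocount)
    rel_neg = to_relative_abundance(paired.counts_neg, pseudocount)
    lp = np.log(rel_pos.to_numpy())
    ln = np.log(rel_neg.to_numpy())
    idx = -(lp - ln) / (lp + ln)
    undetected = (paired.counts_pos.to_numpy() == 0) & \
                 (paired.counts_neg.to_numpy() == 0)
    idx[undetected] = np.nan
    return pd.DataFrame(idx, index=paired.taxon_ids, columns=paired.subject_ids)


def call_enrichment(index: pd.DataFrame, manifest: SampleManifest, group: str,
                    fdr_threshold: float = 0.05, min_n: int = DEFAULT_MIN_N
                    ) -> pd.DataFrame:
    """Per-taxon enrichment/depletion calls within one group.

    Columns: taxon_id, group, n, median_index, statistic, p, p_fdr,
    call in {enriched, depleted, ns, untested}.  Taxa with fewer than
    ``min_n`` subjects carrying a non-missing index are reported as
    untested (below n=5 the exact signed-rank test cannot reach p < 0.05
    two-sided).
    """
    meta = manifest.data
    subjects = meta.loc[meta["group"] == group, "subject_id"].unique()
    cols = [s for s in index.columns if s in set(subjects)]
    if not cols:
        raise ValueError(f"no subjects of group {group!r} in the index matrix")
    rows = []
    for taxon in index.index:
        vals = index.loc[taxon, cols].dropna().to_numpy(dtype=float)
        if len(vals) < min_n:
            logger.info("call_enrichment: %s untested in %s (n=%d < %d)",
                        taxon, group, len(vals), min_n)
            rows.append({"taxon_id": taxon, "group": group, "n": len(vals),
                         "median_index": np.nan, "statistic": np.nan,
                         "p": np.nan})
            continue
        stat, p = signed_rank_test(vals)
        rows.append({"taxon_id": taxon, "group": group, "n": len(vals),
                     "median_index": float(np.median(vals)),
                     "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p"])
    calls = []
    for _, row in out.iterrows():
        if np.isnan(row["p"]):
            calls.append("untested")
        elif row["p_fdr"] < fdr_threshold and row["median_index"] > 0:
            calls.append("enriched")
        elif row["p_fdr"] < fdr_threshold and row["median_index"] < 0:
            calls.append("depleted")
        else:
            calls.append("ns")
    out["call"] = calls
    return out


def compare_index_between_groups(index: pd.DataFrame, manifest: SampleManifest,
                                 min_n: int = DEFAULT_MIN_N) -> pd.DataFrame:
    """Two-sided rank-sum comparison of the coating index, axSpA vs HC.

    One row per taxon with enough subjects in both groups; BH across the
    tested taxa.
    """
    meta = manifest.data
    by_group = {}
    for group in ("axSpA", "HC"):
        subjects = meta.loc[meta["group"] == group, "subject_id"].unique()
        cols = [s for s in index.columns if s in set(subjects)]
        if not cols:
            raise ValueError(f"group {group!r} absent from the index matrix")
        by_group[group] = cols
    rows = []
    for taxon in index.index:
        x = index.loc[taxon, by_group["axSpA"]].dropna().to_numpy(dtype=float)
        y = index.loc[taxon, by_group["HC"]].dropna().to_numpy(dtype=float)
        if len(x) < min_n or len(y) < min_n:
            rows.append({"taxon_id": taxon, "n_axSpA": len(x), "n_HC": len(y),
                         "median_axSpA": np.nan, "median_HC": np.nan,
                         "statistic": np.nan, "p": np.nan})
            continue
        stat, p = rank_sum_test(x, y)
        rows.append({"taxon_id": taxon, "n_axSpA": len(x), "n_HC": len(y),
                     "median_axSpA": float(np.median(x)),
                     "median_HC": float(np.median(y)),
                     "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p"])
    return out


def shared_taxa_overlap(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                        call: str = "enriched") -> tuple[int, int, int]:
    """Partition counts (only in A, only in B, shared) of taxa with a call.

    Both call tables must cover the same taxon universe.
    """
    universe_a = set(calls_a["taxon_id"])
    universe_b = set(calls_b["taxon_id"])
    if universe_a != universe_b:
        raise ValueError("call tables cover different taxon universes")
    set_a = set(calls_a.loc[calls_a["call"] == call, "taxon_id"])
    set_b = set(calls_b.loc[calls_b["call"] == call, "taxon_id"])
    return (len(set_a - set_b), len(set_b - set_a), len(set_a & set_b))
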