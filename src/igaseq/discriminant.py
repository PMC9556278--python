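"""LEfSe-style three-step discriminant feature discovery.

The cascade identifies features (taxa, KO gene families, or MetaCyc
pathways) that discriminate two classes:

1. class step — a Kruskal-Wallis rank test per feature; features with
   p >= alpha_class are eliminated;
2. subclass step — within every subclass level shared by both classes
   (e.g. sex), a Wilcoxon rank-sum test must reach alpha_sub AND agree
   in direction with the class-level difference; a feature survives only
   if all testable pairings agree;
3. effect size — a bootstrapped, ridge-regularized two-class linear
   discriminant analysis on per-sample abundances scaled to a total of
   1e6; the per-feature score is

       mean over bootstraps of log10(1 + (|w_f * d| + |Delta_f|) / 2)

   where w is the unit-norm discriminant direction, d the separation of
   the class means along it, and Delta_f the raw class-mean difference
   of the feature.  Scores are signed by the enriched class; features
   are significant when they survive steps 1-2 and |score| >= the
   threshold (2.0 by default, the published LEfSe convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil, comb

import numpy as np
import pandas as pd

from .stats import kruskal_wallis_test, rank_sum_test

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
RELAXED_ALPHA = 0.10
DEFAULT_LDA_THRESHOLD = 2.0
DEFAULT_N_BOOT = 30
DEFAULT_SUBSAMPLE_FRAC = 2.0 / 3.0
SCALE_TOTAL = 1.0e6
RIDGE = 1e-6


@dataclass(frozen=True)
class CascadeConfig:
    alpha_class: float = DEFAULT_ALPHA
    alpha_sub: float = DEFAULT_ALPHA
    lda_threshold: float = DEFAULT_LDA_THRESHOLD
    n_boot: int = DEFAULT_N_BOOT
    subsample_frac: float = DEFAULT_SUBSAMPLE_FRAC
    seed: int = 0

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "CascadeConfig":
        if name == "strict":
            return cls(seed=seed)
        if name == "relaxed":
            return cls(alpha_class=RELAXED_ALPHA, seed=seed)
        raise ValueError(f"unknown preset {name!r}; use 'strict' or 'relaxed'")


def _check_inputs(features: pd.DataFrame, labels) -> pd.Series:
    labels = pd.Series(list(labels), index=features.columns)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 classes")
    for lv in levels:
        if (labels == lv).sum() < 2:
            raise ValueError(f"class {lv!r} has < 2 samples")
    return labels


def scale_features(features: pd.DataFrame, total: float = SCALE_TOTAL) -> pd.DataFrame:
    """Scale every sample (column) to the given total abundance."""
    sums = features.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive total abundance")
    return features * (total / sums)


def class_test(features: pd.DataFrame, labels) -> pd.Series:
    """Kruskal-Wallis p-value per feature (features x samples input)."""
    labels = _check_inputs(features, labels)
    levels = sorted(labels.unique())
    masks = [(labels == lv).to_numpy() for lv in levels]
    ps = {}
    arr = features.to_numpy(dtype=float)
    for i, feature in enumerate(features.index):
        groups = [arr[i, m] for m in masks]
        _, p = kruskal_wallis_test(groups)
        ps[feature] = p
    return pd.Series(ps, name="kw_p")


def _min_attainable_p(n1: int, n2: int) -> float:
    # smallest two-sided exact rank-sum p for tie-free data
    return 2.0 / comb(n1 + n2, n1)


def subclass_test(features: pd.DataFrame, labels, subclass_labels,
                  alpha_sub: float = DEFAULT_ALPHA) -> pd.Series:
    """Direction-consistency check across subclass pairings.

    For every subclass level present in both classes, the between-class
    rank-sum test must reach ``alpha_sub`` with the same sign as the
    class-level mean difference.  Pairings too small to ever reach
    ``alpha_sub`` (minimum attainable exact p above it) are skipped with
    a log line.  With no subclass labels, or no testable pairing, every
    feature passes (warning emitted).
    """
    labels = _check_inputs(features, labels)
    if subclass_labels is None:
        logger.warning("subclass_test: no subclass labels; step passes trivially")
        return pd.Series(True, index=features.index, name="subclass_pass")
    sub = pd.Series(list(subclass_labels), index=features.columns)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("subclass step expects exactly 2 classes")
    if sub.nunique() <= 1:
        logger.warning("subclass_test: single subclass level; behaves as no-subclass")
        return pd.Series(True, index=features.index, name="subclass_pass")
    pairings = []
    for s in sorted(sub.unique()):
        m0 = ((labels == levels[0]) & (sub == s)).to_numpy()
        m1 = ((labels == levels[1]) & (sub == s)).to_numpy()
        n0, n1 = int(m0.sum()), int(m1.sum())
        if n0 < 2 or n1 < 2 or _min_attainable_p(n0, n1) > alpha_sub:
            logger.info("subclass_test: skipping pairing %r (n=%d vs %d)", s, n0, n1)
            continue
        pairings.append((s, m0, m1))
    if not pairings:
        logger.warning("subclass_test: no testable pairing; step passes trivially")
        return pd.Series(True, index=features.index, name="subclass_pass")
    arr = features.to_numpy(dtype=float)
    class0 = (labels == levels[0]).to_numpy()
    class1 = (labels == levels[1]).to_numpy()
    out = {}
    for i, feature in enumerate(features.index):
        overall = np.sign(arr[i, class1].mean() - arr[i, class0].mean())
        ok = overall != 0
        for _, m0, m1 in pairings:
            if not ok:
                break
            _, p = rank_sum_test(arr[i, m0], arr[i, m1])
            direction = np.sign(arr[i, m1].mean() - arr[i, m0].mean())
            ok = (p < alpha_sub) and (direction == overall)
        out[feature] = bool(ok)
    return pd.Series(out, name="subclass_pass")


def lda_effect_size(features: pd.DataFrame, labels,
                    n_boot: int = DEFAULT_N_BOOT,
                    subsample_frac: float = DEFAULT_SUBSAMPLE_FRAC,
                    seed: int = 0) -> pd.DataFrame:
    """Bootstrapped LDA effect size per feature.

    ``features`` must already be scaled to per-sample totals of 1e6
    (see ``scale_features``).  Returns columns lda_score (signed,
    log10 scale) and enriched_class.  Deterministic given the seed.
    """
    labels = _check_inputs(features, labels)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("LDA step expects exactly 2 classes")
    x = features.to_numpy(dtype=float).T  # samples x features
    y = (labels == levels[1]).to_numpy()
    idx0 = np.flatnonzero(~y)
    idx1 = np.flatnonzero(y)
    n_feat = x.shape[1]
    rng = np.random.default_rng(seed)
    acc = np.zeros(n_feat)
    for _ in range(n_boot):
        s0 = rng.choice(idx0, size=max(2, ceil(subsample_frac * idx0.size)),
                        replace=False)
        s1 = rng.choice(idx1, size=max(2, ceil(subsample_frac * idx1.size)),
                        replace=False)
        x0, x1 = x[s0], x[s1]
        m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
        c0 = x0 - m0
        c1 = x1 - m1
        sw = (c0.T @ c0 + c1.T @ c1) / max(1, (x0.shape[0] + x1.shape[0] - 2))
        lam = RIDGE * np.trace(sw) / n_feat
        if lam <= 0:
            lam = RIDGE
        w = np.linalg.solve(sw + lam * np.eye(n_feat), m1 - m0)
        norm = np.linalg.norm(w)
        if norm == 0:
            continue
        w = w / norm
        d = abs(float((m1 - m0) @ w))
        coeff = np.abs(w * d)
        gm = np.abs(m1 - m0)
        acc += np.log10(1.0 + (coeff + gm) / 2.0)
    scores = acc / n_boot
    raw_diff = x[idx1].mean(axis=0) - x[idx0].mean(axis=0)
    sign = np.where(raw_diff >= 0, 1.0, -1.0)
    enriched = np.where(raw_diff >= 0, levels[1], levels[0])
    return pd.DataFrame({"lda_score": sign * scores, "enriched_class": enriched},
                        index=features.index)


def run_cascade(features: pd.DataFrame, labels, subclass_labels=None,
                config: CascadeConfig | None = None) -> pd.DataFrame:
    """Full three-step cascade; one row per input feature.

    Columns: feature_id, kw_p, subclass_pass, lda_score, enriched_class,
    significant.  Ordered by |lda_score| descending (the ranking order),
    untested features last.
    """
    cfg = config or CascadeConfig()
    scaled = scale_features(features)
    kw_p = class_test(scaled, labels)
    out = pd.DataFrame({"feature_id": features.index, "kw_p": kw_p.to_numpy()},
                       index=features.index)
    out["subclass_pass"] = False
    out["lda_score"] = np.nan
    out["enriched_class"] = ""
    survivors = kw_p.index[kw_p < cfg.alpha_class]
    if len(survivors):
        sub_pass = subclass_test(scaled.loc[survivors], labels, subclass_labels,
                                 alpha_sub=cfg.alpha_sub)
        out.loc[survivors, "subclass_pass"] = sub_pass
        finalists = sub_pass.index[sub_pass]
        if len(finalists):
            lda = lda_effect_size(scaled.loc[finalists], labels,
                                  n_boot=cfg.n_boot,
                                  subsample_frac=cfg.subsample_frac,
                                  seed=cfg.seed)
            out.loc[finalists, "lda_score"] = lda["lda_score"]
            out.loc[finalists, "enriched_class"] = lda["enriched_class"]
    out["significant"] = ((out["kw_p"] < cfg.alpha_class)
                          & out["subclass_pass"]
                          & (out["lda_score"].abs() >= cfg.lda_threshold))
    order = out["lda_score"].abs().fillna(-1.0)
    out = out.loc[order.sort_values(ascending=False, kind="stable").index]
    return out.reset_index(drop=True)


def overlap_significant(results_a: pd.DataFrame, results_b: pd.DataFrame
                        ) -> tuple[int, int, int]:
    """Partition counts of significant features between two analyses.

    Returns (only in A, only in B, shared).  Both result tables must
    cover the same feature universe.
    """
    ua = set(results_a["feature_id"])
    ub = set(results_b["feature_id"])
    if ua != ub:
        raise ValueError("result tables cover different feature universes")
    sa = set(results_a.loc[results_a["significant"], "feature_id"])
    sb = set(results_b.loc[results_b["significant"], "feature_id"])
    return (len(sa - sb), len(sb - sa), len(sa & sb))
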