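"""Community-level diversity analysis.

Alpha diversity (Observed richness, Shannon entropy with natural log,
Inverse Simpson), unweighted UniFrac beta diversity on a rooted
phylogeny, classical PCoA (Gower double-centering), and one-way
PERMANOVA with a seeded permutation null.

No rarefaction is performed anywhere: the depth filter upstream already
imposes a floor, and alpha metrics are computed on the full counts of
each sample.  Proportions for Shannon/Inverse Simpson use no
pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from skbio.diversity import beta_diversity

from .stats import bh_adjust, rank_sum_test
from .tables import CountTable, SampleManifest

logger = logging.getLogger(__name__)

ALPHA_METRICS = ("observed", "shannon", "invsimpson")


def alpha_diversity(table: CountTable, metric: str) -> pd.Series:
    """Per-sample alpha diversity.

    observed  : number of taxa with count > 0
    shannon   : -sum p_i ln p_i over p_i > 0 (natural log)
    invsimpson: 1 / sum p_i^2
    """
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; allowed: {list(ALPHA_METRICS)}")
    counts = table.data.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = table.data.columns[totals == 0][0]
        raise ValueError(f"sample {bad!r} is empty")
    if metric == "observed":
        values = (counts > 0).sum(axis=0).astype(float)
    else:
        p = counts / totals
        if metric == "shannon":
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(p > 0, p * np.log(p), 0.0)
            values = -terms.sum(axis=0)
        else:
            values = 1.0 / (p * p).sum(axis=0)
    return pd.Series(values, index=table.data.columns, name=metric)


def compare_alpha(alpha: pd.DataFrame, manifest: SampleManifest,
                  grouping: str = "group") -> pd.DataFrame:
    """Two-sided rank-sum comparison of each alpha metric between groups.

    ``alpha`` is samples x metrics (as from ``alpha_diversity`` columns
    stacked).  BH correction is applied across the metrics, i.e. the
    three indices form one comparison family.
    """
    meta = manifest.data.set_index("sample_id").loc[alpha.index]
    levels = sorted(meta[grouping].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, "
                         f"got {levels}")
    rows = []
    for metric in alpha.columns:
        x = alpha.loc[meta[grouping] == levels[0], metric].to_numpy()
        y = alpha.loc[meta[grouping] == levels[1], metric].to_numpy()
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"group with < 2 samples for metric {metric!r}")
        stat, p = rank_sum_test(x, y)
        rows.append({"metric": metric, "group1": levels[0], "group2": levels[1],
                     "n1": len(x), "n2": len(y), "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p"])
    return out


def unweighted_unifrac(table: CountTable, tree: skbio.TreeNode,
                       prune: bool = False) -> skbio.DistanceMatrix:
    """Unweighted UniFrac distances between all samples of a count table.

    Presence/absence is counts > 0.  Every taxon in the table must be a
    tree leaf; with ``prune=True`` taxa absent from the tree are dropped
    (logged) instead of raising.  Values lie in [0, 1].
    """
    leaves = {leaf.name for leaf in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in leaves]
    data = table.data
    if missing:
        if not prune:
            raise ValueError(
                f"{len(missing)} taxa missing from the tree (e.g. {missing[:3]}); "
                "pass prune=True to drop them")
        logger.warning("unweighted_unifrac: pruning %d taxa absent from tree",
                       len(missing))
        data = data.drop(index=missing)
        if data.empty:
            raise ValueError("no taxa left after pruning against the tree")
    presence = (data.to_numpy().T > 0).astype(int)
    return beta_diversity("unweighted_unifrac", presence, ids=list(data.columns),
                          taxa=list(data.index), tree=tree, validate=True)


@dataclass
class OrdinationResult:
    """PCoA embedding: coordinates on positive-eigenvalue axes only."""

    coordinates: pd.DataFrame       # samples x kept axes (PC1, PC2, ...)
    eigenvalues: np.ndarray         # all eigenvalues, descending
    proportion_explained: np.ndarray  # per kept axis, relative to positive sum


def pcoa(dm: skbio.DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Gower-center -0.5 * D^2, eigendecompose, and scale eigenvectors by
    sqrt(eigenvalue).  Negative eigenvalues (non-Euclidean input) are
    reported but carry no coordinates.
    """
    if isinstance(dm, skbio.DistanceMatrix):
        d = dm.data
        ids = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        ids = [str(i) for i in range(d.shape[0])]
        if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("pcoa requires a symmetric square distance matrix")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if n else 0.0
    positive = eigvals > tol
    n_pos = int(positive.sum())
    keep = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = eigvecs[:, :keep] * np.sqrt(eigvals[:keep])
    pos_sum = eigvals[positive].sum()
    prop = eigvals[:keep] / pos_sum if pos_sum > 0 else np.zeros(keep)
    frame = pd.DataFrame(coords, index=ids,
                         columns=[f"PC{i + 1}" for i in range(keep)])
    return OrdinationResult(frame, eigvals, prop)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"pseudo_F": self.pseudo_F, "R2": self.R2,
                              "p_value": self.p_value,
                              "n_permutations": self.n_permutations,
                              "seed": self.seed}])


def _permanova_f(d2: np.ndarray, labels: np.ndarray, n_groups: int,
                 ss_total: float) -> tuple[float, float]:
    n = d2.shape[0]
    ss_within = 0.0
    for g in range(n_groups):
        mask = labels == g
        m = int(mask.sum())
        if m < 2:
            continue
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * m)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(dm: skbio.DistanceMatrix, grouping, column: str | None = None,
              n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) with free label permutation.

    ``grouping`` is either a per-sample label sequence aligned with the
    distance matrix ids, or a SampleManifest (then ``column`` names the
    label column, default ``group``).  p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm), reproducible given the seed.
    """
    if isinstance(grouping, SampleManifest):
        meta = grouping.data.set_index("sample_id")
        labels_raw = [meta.loc[s, column or "group"] for s in dm.ids]
    else:
        labels_raw = list(grouping)
    if len(labels_raw) != len(dm.ids):
        raise ValueError("grouping length must match the distance matrix")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    levels = sorted(set(labels_raw))
    if len(levels) < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    labels = np.array([levels.index(v) for v in labels_raw])
    counts = np.bincount(labels, minlength=len(levels))
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 samples")
    d2 = dm.data ** 2
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    if ss_total <= 0:
        raise ValueError("degenerate distance matrix (all distances zero)")
    f_obs, r2 = _permanova_f(d2, labels, len(levels), ss_total)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_perm, _ = _permanova_f(d2, labels[perm], len(levels), ss_total)
        if f_perm >= f_obs:
            n_ge += 1
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, seed)
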