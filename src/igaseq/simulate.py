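"""Synthetic paired IgA+/IgA- cohort generator.

The generator emulates the IgA-SEQ design: each subject carries a latent
community composition pi_s ~ Dirichlet(alpha_base); each taxon t has a
latent IgA-coating probability

    theta_{s,t} = logistic(mu_t + beta_t * group_s + eps_{s,t}),
    eps_{s,t} ~ Normal(0, sigma_subject^2),

where group_s is 1 for patients (axSpA) and 0 for controls.  Sorting is
modelled compositionally: the IgA+ library sequences a community with
composition proportional to pi_s * theta_s and the IgA- library one
proportional to pi_s * (1 - theta_s) — 16S sequencing observes
composition, not absolute load.  Read counts are multinomial at a
negative-binomial depth around ``depth_mean``.  Disease activity is a
clipped linear readout of the coating of one designated taxon:

    BASDAI_s = clip(b0 + b1 * logit(theta_{s, basdai_taxon}) + Normal(0, sigma_b^2), 0, 10).

What it does not emulate: sequencing error and chimeras, taxon-taxon
ecological interactions, and site-specific community differences beyond
the parameters supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .tables import CountTable, SampleManifest

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_cohort",
           "null_cohort", "simulate_tree", "simulate_feature_table"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one paired-fraction cohort.

    Defaults are sized like the study cohorts this package targets:
    ~15 subjects per group, 50 taxa, mean library depth 30,000 reads
    with negative-binomial dispersion 0.3, a neutral coating baseline
    (mu = 0, i.e. theta = 1/2), subject-level coating noise of 1 logit,
    and a BASDAI linear model centred at 3.5 with unit residual SD.
    """

    n_per_group: int = 15
    n_taxa: int = 50
    depth_mean: float = 30_000.0
    depth_dispersion: float = 0.3
    alpha_base: np.ndarray | float | None = None   # Dirichlet concentration
    mu: np.ndarray | float = 0.0                   # baseline coating logit / taxon
    beta: np.ndarray | float = 0.0                 # group effect on coating logit
    sigma_subject: float = 1.0
    basdai_taxon: int | None = None
    b0: float = 3.5
    b1: float = 1.5
    sigma_b: float = 1.0
    carryover: float = 0.0                         # sort impurity, fraction mixed in
    site: str = "fecal"
    include_unsorted: bool = False
    seed: int = 0

    def _vector(self, value, name: str) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (self.n_taxa,)).copy()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} must be finite")
        return arr

    def resolved(self) -> "SimulationConfig":
        """Return a copy with all per-taxon parameters as explicit vectors."""
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0.0 <= self.carryover < 0.5:
            raise ValueError("carryover must lie in [0, 0.5)")
        alpha = self.alpha_base if self.alpha_base is not None else 1.0
        alpha = self._vector(alpha, "alpha_base")
        if np.any(alpha <= 0):
            raise ValueError("alpha_base must be strictly positive")
        return replace(self, alpha_base=alpha,
                       mu=self._vector(self.mu, "mu"),
                       beta=self._vector(self.beta, "beta"))


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated cohort.

    ``direction`` records the per-group expected enrichment direction of
    every taxon (sign of the mean coating logit in that group, 0 for a
    neutral taxon); ``pi`` and ``theta`` are the latent composition and
    coating probability per subject.
    """

    pi: pd.DataFrame       # subjects x taxa
    theta: pd.DataFrame    # subjects x taxa
    direction: pd.DataFrame  # groups x taxa, values in {-1, 0, +1}
    basdai_taxon: str | None
    config: SimulationConfig

    def planted(self, group: str = "axSpA") -> list[str]:
        row = self.direction.loc[group]
        return list(row.index[row != 0])


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return max(1, int(round(mean)))
    r = 1.0 / dispersion
    p = r / (r + mean)
    return max(1, int(rng.negative_binomial(r, p)))


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[CountTable, SampleManifest, SyntheticTruth]:
    """Draw one paired-fraction cohort; bit-reproducible given the seed."""
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    taxa = [f"T{i:03d}" for i in range(cfg.n_taxa)]
    subjects = [f"A{i:02d}" for i in range(cfg.n_per_group)] + \
               [f"H{i:02d}" for i in range(cfg.n_per_group)]
    groups = ["axSpA"] * cfg.n_per_group + ["HC"] * cfg.n_per_group

    counts: dict[str, np.ndarray] = {}
    rows = []
    pi_rows, theta_rows = [], []
    for subj, group in zip(subjects, groups):
        is_patient = 1.0 if group == "axSpA" else 0.0
        pi = rng.dirichlet(cfg.alpha_base)
        eps = rng.normal(0.0, cfg.sigma_subject, cfg.n_taxa)
        theta = expit(cfg.mu + cfg.beta * is_patient + eps)
        pi_rows.append(pi)
        theta_rows.append(theta)
        pos_raw = pi * theta
        neg_raw = pi * (1.0 - theta)
        if cfg.carryover > 0:
            pos_raw, neg_raw = ((1 - cfg.carryover) * pos_raw + cfg.carryover * neg_raw,
                                (1 - cfg.carryover) * neg_raw + cfg.carryover * pos_raw)
        for frac, comp in (("pos", pos_raw), ("neg", neg_raw)):
            total = comp.sum()
            if total <= 0:
                raise ValueError("degenerate composition (all mass zero)")
            depth = _nb_depth(rng, cfg.depth_mean, cfg.depth_dispersion)
            counts[f"{subj}_{frac}"] = rng.multinomial(depth, comp / total)
        if cfg.include_unsorted:
            depth = _nb_depth(rng, cfg.depth_mean, cfg.depth_dispersion)
            counts[f"{subj}_unsorted"] = rng.multinomial(depth, pi)
        if cfg.basdai_taxon is not None:
            signal = cfg.b1 * logit(theta[cfg.basdai_taxon])
        else:
            signal = 0.0
        basdai = float(np.clip(cfg.b0 + signal + rng.normal(0.0, cfg.sigma_b), 0.0, 10.0))
        i = int(subj[1:])
        sex = "F" if i % 2 else "M"
        fractions = ("pos", "neg", "unsorted") if cfg.include_unsorted else ("pos", "neg")
        for frac in fractions:
            rows.append({"sample_id": f"{subj}_{frac}", "subject_id": subj,
                         "site": cfg.site, "fraction": frac, "group": group,
                         "basdai": round(basdai, 4), "sex": sex})

    table = CountTable(pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id")))
    manifest = SampleManifest(pd.DataFrame(rows))
    mean_logit = {"axSpA": cfg.mu + cfg.beta, "HC": cfg.mu}
    direction = pd.DataFrame(
        {g: np.sign(v).astype(int) for g, v in mean_logit.items()}, index=taxa).T
    truth = SyntheticTruth(
        pi=pd.DataFrame(pi_rows, index=subjects, columns=taxa),
        theta=pd.DataFrame(theta_rows, index=subjects, columns=taxa),
        direction=direction,
        basdai_taxon=None if cfg.basdai_taxon is None else taxa[cfg.basdai_taxon],
        config=cfg,
    )
    return table, manifest, truth


def null_cohort(config: SimulationConfig
                ) -> tuple[CountTable, SampleManifest, SyntheticTruth]:
    """Cohort with every group effect removed (beta_t = 0 for all taxa)."""
    return simulate_cohort(replace(config, beta=0.0))


def simulate_feature_table(n_features: int = 40, n_per_class: int = 15,
                           planted=(), fold: float = 2.0,
                           sigma_log: float = 0.15, seed: int = 0
                           ) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Synthetic predicted-function (KO-like) feature table for two classes.

    Feature magnitudes are lognormal around per-feature baselines spread
    over ~1.5 decades so that no single feature dominates the per-sample
    total; the features at the ``planted`` indices are fixed at the low
    end of that range (differential gene families are typically minor
    components of the total) and multiplied by ``fold`` in the first
    class (axSpA).  ``sigma_log`` is the within-class SD on the natural
    log scale (0.15 ~= 15% CV).  Samples alternate sexes so the
    discriminant subclass step is exercised.

    Returns (features x samples DataFrame, class labels, sex subclass
    labels).
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    rng = np.random.default_rng(seed)
    base = rng.uniform(3.0, 4.5, n_features)  # log10 baseline abundance
    base[list(planted)] = 3.0
    n = 2 * n_per_class
    x = np.exp(np.log(10.0) * base[:, None]
               + rng.normal(0.0, sigma_log, (n_features, n)))
    for f in planted:
        x[f, :n_per_class] *= fold
    frame = pd.DataFrame(x, index=[f"K{i:03d}" for i in range(n_features)],
                         columns=[f"s{i:03d}" for i in range(n)])
    labels = ["axSpA"] * n_per_class + ["HC"] * n_per_class
    subclass = [("F" if i % 2 else "M") for i in range(n_per_class)] * 2
    return frame, labels, subclass


def simulate_tree(taxon_ids, seed: int = 0):
    """Random rooted bifurcating tree over the given taxa.

    Topology by recursive random bisection; branch lengths are
    0.05 + Exponential(mean 0.5).  Deterministic given the seed.
    """
    import skbio

    rng = np.random.default_rng(seed)
    ids = list(taxon_ids)
    if len(ids) < 2:
        raise ValueError("need at least two taxa for a tree")

    def build(leaves: list[str]) -> str:
        if len(leaves) == 1:
            return f"{leaves[0]}:{0.05 + rng.exponential(0.5):.6f}"
        k = int(rng.integers(1, len(leaves)))
        left, right = leaves[:k], leaves[k:]
        length = 0.05 + rng.exponential(0.5)
        return f"({build(left)},{build(right)}):{length:.6f}"

    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    k = int(rng.integers(1, len(shuffled)))
    newick = f"({build(shuffled[:k])},{build(shuffled[k:])});"
    return skbio.TreeNode.read([newick], format="newick")
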