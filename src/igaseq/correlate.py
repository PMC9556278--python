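"""Correlation of per-taxon statistics with disease activity (BASDAI).

Spearman rank correlation of a per-subject taxon statistic — the IgA
coating index or the relative abundance — against the BASDAI score,
with Benjamini-Hochberg adjustment across taxa.  The BH family is all
taxa tested at one site for one statistic type, mirroring a per-panel
adjustment.  Ties are handled by midranks.  Calls with FDR below the
significance threshold are labelled ``significant``; those below a
looser exploratory threshold (default 0.20) are labelled ``trend``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import bh_adjust, spearman_test
from .tables import SampleManifest

logger = logging.getLogger(__name__)

DEFAULT_MIN_N = 5
DEFAULT_FDR = 0.05
TREND_FDR = 0.20


def correlate_with_basdai(values: pd.DataFrame, manifest: SampleManifest,
                          min_n: int = DEFAULT_MIN_N,
                          statistic_type: str = "index",
                          fdr_threshold: float = DEFAULT_FDR,
                          trend_threshold: float = TREND_FDR) -> pd.DataFrame:
    """Per-taxon Spearman correlation with BASDAI.

    ``values`` is taxa x subjects.  Subjects with missing BASDAI are
    excluded; taxa with fewer than ``min_n`` remaining pairs, or with a
    constant statistic, are skipped (reported with NaN rho and a logged
    reason).  Returns taxon_id, statistic_type, n, rho, p, p_fdr, tier.
    """
    basdai = manifest.subject_attribute("basdai")
    subjects = [s for s in values.columns
                if s in basdai.index and not pd.isna(basdai[s])]
    if np.unique(basdai[subjects]).size <= 1 and len(subjects) >= min_n:
        raise ValueError("BASDAI is constant across subjects; rho undefined")
    rows = []
    for taxon in values.index:
        vals = values.loc[taxon, subjects].astype(float)
        ok = vals.notna()
        x = vals[ok].to_numpy()
        y = basdai[vals.index[ok]].to_numpy(dtype=float)
        if len(x) < min_n:
            logger.info("correlate_with_basdai: skipping %s (n=%d < %d)",
                        taxon, len(x), min_n)
            rows.append({"taxon_id": taxon, "statistic_type": statistic_type,
                         "n": len(x), "rho": np.nan, "p": np.nan})
            continue
        if np.unique(x).size == 1 or np.unique(y).size == 1:
            logger.info("correlate_with_basdai: skipping %s (constant values)", taxon)
            rows.append({"taxon_id": taxon, "statistic_type": statistic_type,
                         "n": len(x), "rho": np.nan, "p": np.nan})
            continue
        rho, p = spearman_test(x, y)
        rows.append({"taxon_id": taxon, "statistic_type": statistic_type,
                     "n": len(x), "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p"])
    tier = np.where(out["p_fdr"] < fdr_threshold, "significant",
                    np.where(out["p_fdr"] < trend_threshold, "trend", "ns"))
    tier = np.where(out["p"].isna(), "untested", tier)
    out["tier"] = tier
    return out
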