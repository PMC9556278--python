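"""Core data containers for paired-fraction 16S analysis.

The raw observable is a taxon x sample integer count table plus a sample
manifest that records, for every sequencing library, which subject it
came from, the body site (fecal or salivary), the sorted fraction
(IgA+ ``pos``, IgA- ``neg``, or ``unsorted``), the diagnostic group
(axSpA patient or healthy control), and the BASDAI disease-activity
score where available.  ``pair_fractions`` joins these into the
subject-level structure every IgA-SEQ statistic operates on: two count
matrices, one per fraction, aligned on both axes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITES = ("fecal", "salivary")
FRACTIONS = ("pos", "neg", "unsorted")
GROUPS = ("axSpA", "HC")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

MANIFEST_REQUIRED = ("sample_id", "subject_id", "site", "fraction", "group")
MANIFEST_OPTIONAL = ("basdai", "sex", "age")


class CountTable:
    """Nonnegative integer taxon x sample matrix (reads).

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are taxa, columns are samples, cells are read counts.
        Row/column order is preserved as given.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate taxon id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = data.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            flt = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(flt)) or np.any(flt != np.round(flt)):
                i, j = np.argwhere((flt != np.round(flt)) | ~np.isfinite(flt))[0]
                raise ValueError(
                    f"non-integer count at taxon {data.index[i]!r}, "
                    f"sample {data.columns[j]!r}"
                )
            data = data.astype(np.int64)
        if arr.size and (data.to_numpy() < 0).any():
            i, j = np.argwhere(data.to_numpy() < 0)[0]
            raise ValueError(
                f"negative count at taxon {data.index[i]!r}, "
                f"sample {data.columns[j]!r}"
            )
        self.data = data.astype(np.int64)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def depths(self) -> pd.Series:
        """Total reads per sample."""
        return self.data.sum(axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountTable({self.shape[0]} taxa x {self.shape[1]} samples)"


class SampleManifest:
    """Sample metadata: subject, site, fraction, group, BASDAI.

    At most one sample may exist per (subject, site, fraction); BASDAI
    may be missing (NaN).
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in MANIFEST_REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"manifest missing required column(s): {missing}")
        data = data.copy()
        if data["sample_id"].duplicated().any():
            dup = data.loc[data["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        for col, allowed in (("site", SITES), ("fraction", FRACTIONS), ("group", GROUPS)):
            bad = set(data[col].astype(str)) - set(allowed)
            if bad:
                raise ValueError(
                    f"unknown {col} token(s) {sorted(bad)}; allowed: {list(allowed)}"
                )
        key = data[["subject_id", "site", "fraction"]]
        if key.duplicated().any():
            row = key[key.duplicated()].iloc[0]
            raise ValueError(
                "more than one sample for (subject, site, fraction) = "
                f"({row['subject_id']!r}, {row['site']!r}, {row['fraction']!r})"
            )
        if "basdai" in data.columns:
            data["basdai"] = pd.to_numeric(data["basdai"], errors="raise")
            vals = data["basdai"].dropna()
            if ((vals < 0) | (vals > 10)).any():
                raise ValueError("basdai values must lie in [0, 10]")
        else:
            data["basdai"] = np.nan
        self.data = data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def samples_for(self, site: str | None = None, fraction: str | None = None,
                    group: str | None = None) -> pd.DataFrame:
        sel = self.data
        if site is not None:
            sel = sel[sel["site"] == site]
        if fraction is not None:
            sel = sel[sel["fraction"] == fraction]
        if group is not None:
            sel = sel[sel["group"] == group]
        return sel

    def subject_attribute(self, attribute: str) -> pd.Series:
        """Per-subject value of a subject-level column (first non-null)."""
        grouped = self.data.groupby("subject_id")[attribute]
        return grouped.apply(lambda s: s.dropna().iloc[0] if s.notna().any() else np.nan)

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleManifest) and self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleManifest({len(self.data)} samples)"


class TaxonomyMap:
    """taxon_id -> ranked lineage (kingdom..genus, optional species)."""

    def __init__(self, data: pd.DataFrame):
        if "taxon_id" in data.columns:
            data = data.set_index("taxon_id")
        ranks = [r for r in RANKS if r in data.columns]
        if not ranks:
            raise ValueError(f"taxonomy needs at least one rank column of {RANKS}")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate taxon_id in taxonomy: {dup!r}")
        self.data = data
        self.ranks = ranks

    def lineage(self, taxon_id: str) -> dict:
        if taxon_id not in self.data.index:
            raise KeyError(f"taxon {taxon_id!r} has no taxonomy entry")
        return self.data.loc[taxon_id].to_dict()


@dataclass
class PairedFractionTable:
    """Subject-level join of the IgA+ and IgA- fraction counts.

    Both matrices are taxa x subjects with identical axis labels; every
    subject has both fractions.
    """

    counts_pos: pd.DataFrame
    counts_neg: pd.DataFrame
    site: str = "fecal"
    sample_ids_pos: dict = field(default_factory=dict)
    sample_ids_neg: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts_pos.index.equals(self.counts_neg.index):
            raise ValueError("fraction matrices disagree on taxon axis")
        if not self.counts_pos.columns.equals(self.counts_neg.columns):
            raise ValueError("fraction matrices disagree on subject axis")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.counts_pos.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts_pos.index)

    def depths(self) -> pd.DataFrame:
        """Per-subject read depth for each fraction (columns pos, neg)."""
        return pd.DataFrame(
            {"pos": self.counts_pos.sum(axis=0), "neg": self.counts_neg.sum(axis=0)}
        )

    def total_counts(self) -> int:
        return int(self.counts_pos.to_numpy().sum() + self.counts_neg.to_numpy().sum())


def pair_fractions(table: CountTable, manifest: SampleManifest, site: str
                   ) -> PairedFractionTable:
    """Assemble the paired IgA+/IgA- table for one body site.

    Only subjects possessing both a ``pos`` and a ``neg`` sample at the
    given site are retained; subjects lacking a fraction are logged and
    dropped.  Subjects are emitted in sorted order and taxa in the count
    table's order, so the output is invariant to input permutations.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}; allowed: {list(SITES)}")
    pos = manifest.samples_for(site=site, fraction="pos").set_index("subject_id")
    neg = manifest.samples_for(site=site, fraction="neg").set_index("subject_id")
    in_table = set(table.sample_ids)
    pos = pos[pos["sample_id"].isin(in_table)]
    neg = neg[neg["sample_id"].isin(in_table)]
    subjects = sorted(set(pos.index) & set(neg.index))
    dropped = sorted((set(pos.index) | set(neg.index)) - set(subjects))
    for subj in dropped:
        logger.info("pair_fractions: dropping subject %s (incomplete pair at %s)",
                    subj, site)
    if not subjects:
        raise ValueError(f"no subject has both fractions at site {site!r}")
    pos_samples = {s: pos.loc[s, "sample_id"] for s in subjects}
    neg_samples = {s: neg.loc[s, "sample_id"] for s in subjects}
    counts_pos = table.data[[pos_samples[s] for s in subjects]].copy()
    counts_pos.columns = subjects
    counts_neg = table.data[[neg_samples[s] for s in subjects]].copy()
    counts_neg.columns = subjects
    return PairedFractionTable(counts_pos, counts_neg, site=site,
                               sample_ids_pos=pos_samples, sample_ids_neg=neg_samples)
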