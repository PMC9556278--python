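"""Sample retention, taxonomic aggregation, prevalence filtering and
conversion to relative abundance.

The retention rule mirrors the sequencing-depth criterion used for
IgA-SEQ libraries: a subject is kept only if BOTH the IgA+ and the IgA-
library reached ``min_reads`` (default 7,500; the threshold is
inclusive).  Zero handling for downstream log-ratio statistics is a
per-cell pseudocount added before normalization.
"""

from __future__ import annotations

import logging

import pandas as pd

from .tables import CountTable, PairedFractionTable, TaxonomyMap, RANKS

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 7500
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_MIN_SUBJECTS = 3


def filter_by_depth(paired: PairedFractionTable, min_reads: int = DEFAULT_MIN_READS,
                    ) -> tuple[PairedFractionTable, list[str]]:
    """Keep subjects whose depth is >= min_reads in both fractions.

    Returns the filtered table and the list of dropped subjects.
    Raises ValueError if nothing survives.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = paired.depths()
    keep = depths.index[(depths["pos"] >= min_reads) & (depths["neg"] >= min_reads)]
    dropped = [s for s in paired.subject_ids if s not in set(keep)]
    for subj in dropped:
        logger.info("filter_by_depth: dropping %s (pos=%d, neg=%d < %d)",
                    subj, depths.loc[subj, "pos"], depths.loc[subj, "neg"], min_reads)
    if len(keep) == 0:
        raise ValueError(f"filter_by_depth removed every subject at min_reads={min_reads}")
    out = PairedFractionTable(
        paired.counts_pos[list(keep)], paired.counts_neg[list(keep)], site=paired.site,
        sample_ids_pos={s: paired.sample_ids_pos.get(s) for s in keep},
        sample_ids_neg={s: paired.sample_ids_neg.get(s) for s in keep})
    return out, dropped


def aggregate_taxonomy(table: CountTable, taxonomy: TaxonomyMap, rank: str) -> CountTable:
    """Sum counts over taxa sharing the lineage prefix down to ``rank``.

    ``rank='asv'`` is the identity.  Taxa unclassified at the requested
    rank are pooled per nearest classified ancestor into rows labelled
    ``unclassified_<parent>``.  Row labels are the lineage prefix joined
    with ';' so that homonymous names under different parents stay
    separate.  Total counts are conserved at every rank.
    """
    if rank == "asv":
        return table
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; allowed: {list(RANKS) + ['asv']}")
    use_ranks = [r for r in RANKS[: RANKS.index(rank) + 1] if r in taxonomy.ranks]
    if rank not in taxonomy.ranks:
        raise ValueError(f"taxonomy map has no column for rank {rank!r}")
    labels = []
    for taxon in table.taxon_ids:
        if taxon not in taxonomy.data.index:
            raise KeyError(f"taxon {taxon!r} missing from taxonomy map")
        lineage = taxonomy.data.loc[taxon, use_ranks]
        values = [None if pd.isna(v) or str(v).strip() == "" else str(v)
                  for v in lineage]
        if values[-1] is None:
            classified = [v for v in values if v is not None]
            parent = classified[-1] if classified else "root"
            prefix = classified + [f"unclassified_{parent}"]
        else:
            # truncate at the first gap so the prefix is well defined
            prefix = []
            for v in values:
                if v is None:
                    prefix.append(f"unclassified_{prefix[-1] if prefix else 'root'}")
                    break
                prefix.append(v)
        labels.append(";".join(prefix))
    grouped = table.data.groupby(pd.Index(labels, name="taxon_id"), sort=True).sum()
    return CountTable(grouped)


def prevalence_filter(paired: PairedFractionTable, min_subjects: int = DEFAULT_MIN_SUBJECTS
                      ) -> tuple[PairedFractionTable, list[str]]:
    """Keep taxa detected (count > 0 in either fraction) in >= min_subjects subjects.

    Returns the filtered table and the list of dropped taxa.
    """
    if min_subjects < 0:
        raise ValueError("min_subjects must be >= 0")
    detected = (paired.counts_pos > 0) | (paired.counts_neg > 0)
    n_subjects = detected.sum(axis=1)
    keep = n_subjects.index[n_subjects >= min_subjects]
    dropped = [t for t in paired.taxon_ids if t not in set(keep)]
    for taxon in dropped:
        logger.info("prevalence_filter: dropping %s (detected in %d < %d subjects)",
                    taxon, n_subjects[taxon], min_subjects)
    out = PairedFractionTable(
        paired.counts_pos.loc[list(keep)], paired.counts_neg.loc[list(keep)],
        site=paired.site, sample_ids_pos=paired.sample_ids_pos,
        sample_ids_neg=paired.sample_ids_neg)
    return out, dropped


def to_relative_abundance(counts, pseudocount: float = 0.0) -> pd.DataFrame:
    """Column-normalize counts to proportions after adding a pseudocount.

    Accepts a CountTable or a taxa x samples DataFrame.  With
    pseudocount > 0 every entry is strictly positive, which is what the
    log-ratio coating index requires.
    """
    if isinstance(counts, CountTable):
        counts = counts.data
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    shifted = counts.astype(float) + pseudocount
    sums = shifted.sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(
            f"sample {bad!r} has zero total count; use pseudocount > 0")
    return shifted / sums
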