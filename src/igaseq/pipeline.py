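"""Orchestration of the full per-site workflow.

One run analyses one body site: QC (pairing, depth filter, prevalence
filter) -> diversity (alpha, UniFrac/PCoA/PERMANOVA when a tree is
supplied) -> IgA scoring (index matrix, per-group enrichment calls,
between-group comparison, overlap) -> BASDAI correlation -> LEfSe-style
discriminant analysis per fraction (taxa, plus an external
predicted-function table when supplied).  All stochastic stages are
seeded deterministically from the run seed; a run is byte-reproducible
given identical inputs and configuration.  Emitted files never contain
timestamps for that reason; timestamped logging goes to the logger
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as iio
from . import qc as iqc
from .correlate import correlate_with_basdai
from .discriminant import CascadeConfig, overlap_significant, run_cascade
from .diversity import (ALPHA_METRICS, alpha_diversity, compare_alpha, pcoa,
                        permanova, unweighted_unifrac)
from .scoring import (call_enrichment, compare_index_between_groups,
                      iga_index_matrix, shared_taxa_overlap)
from .tables import CountTable, pair_fractions

logger = logging.getLogger(__name__)

STAGES = ("qc", "diversity", "scoring", "correlation", "discriminant")


def _version() -> str:
    try:
        return _pkg_version("igaseq")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    counts: str
    manifest: str
    outdir: str
    site: str = "fecal"
    tree: str | None = None
    taxonomy: str | None = None
    rank: str = "asv"
    function_table: str | None = None
    min_reads: int = iqc.DEFAULT_MIN_READS
    pseudocount: float = iqc.DEFAULT_PSEUDOCOUNT
    min_subjects: int = iqc.DEFAULT_MIN_SUBJECTS
    fdr_threshold: float = 0.05
    n_perm: int = 999
    lefse_preset: str = "strict"
    prune: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is a required configuration field")
        for name in ("fdr_threshold",):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("counts", "manifest", "tree", "taxonomy", "function_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunReport:
    entries: dict = field(default_factory=dict)

    def add(self, key: str, value) -> None:
        self.entries[key] = value

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"key": list(self.entries),
                             "value": [str(v) for v in self.entries.values()]})


def _stage(report: RunReport, outdir: Path, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (outdir / f"FAILED_{name}").write_text(f"stage {name} failed: {exc}\n")
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False
    return _Ctx()


def run_full_analysis(config: RunConfig) -> RunReport:
    """Execute every stage for one site and write result TSVs.

    Raises RuntimeError naming the failing stage; outputs of completed
    stages are left intact next to a ``FAILED_<stage>`` marker.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.add("igaseq_version", _version())
    report.add("seed", config.seed)
    report.add("site", config.site)
    for key in ("min_reads", "pseudocount", "min_subjects", "fdr_threshold",
                "n_perm", "lefse_preset", "rank"):
        report.add(key, getattr(config, key))

    table = iio.read_count_table(config.counts)
    manifest = iio.read_manifest(config.manifest)
    tree = iio.read_tree(config.tree) if config.tree else None
    if config.rank != "asv":
        if config.taxonomy is None:
            raise RuntimeError("rank aggregation requires a taxonomy file")
        taxonomy = iio.read_taxonomy(config.taxonomy)
        table = iqc.aggregate_taxonomy(table, taxonomy, config.rank)
    report.add("input_taxa", table.shape[0])
    report.add("input_samples", table.shape[1])

    with _stage(report, outdir, "qc"):
        paired = pair_fractions(table, manifest, config.site)
        n_paired = len(paired.subject_ids)
        paired, dropped_subjects = iqc.filter_by_depth(paired, config.min_reads)
        paired, dropped_taxa = iqc.prevalence_filter(paired, config.min_subjects)
        qc_log = pd.DataFrame(
            [{"kind": "subject", "id": s, "reason": f"depth<{config.min_reads}"}
             for s in dropped_subjects] +
            [{"kind": "taxon", "id": t, "reason": f"prevalence<{config.min_subjects}"}
             for t in dropped_taxa], columns=["kind", "id", "reason"])
        iio.write_result_table(qc_log, outdir / "qc_log.tsv")
        pos = paired.counts_pos.copy()
        pos.index.name = "taxon_id"
        iio.write_result_table(pos, outdir / "qc_counts_pos.tsv", index=True)
        neg = paired.counts_neg.copy()
        neg.index.name = "taxon_id"
        iio.write_result_table(neg, outdir / "qc_counts_neg.tsv", index=True)
        report.add("qc_subjects_paired", n_paired)
        report.add("qc_subjects_kept", len(paired.subject_ids))
        report.add("qc_taxa_kept", len(paired.taxon_ids))

    subjects = set(paired.subject_ids)
    site_meta = manifest.samples_for(site=config.site)
    site_meta = site_meta[site_meta["subject_id"].isin(subjects)
                          & site_meta["sample_id"].isin(table.sample_ids)]

    with _stage(report, outdir, "diversity"):
        site_table = CountTable(table.data[list(site_meta["sample_id"])])
        alpha = pd.DataFrame({m: alpha_diversity(site_table, m)
                              for m in ALPHA_METRICS})
        alpha.index.name = "sample_id"
        iio.write_result_table(alpha, outdir / "alpha_diversity.tsv", index=True)
        tests = []
        for fraction in ("pos", "neg", "unsorted"):
            frac_ids = list(site_meta.loc[site_meta["fraction"] == fraction,
                                          "sample_id"])
            frac_groups = site_meta.set_index("sample_id").loc[frac_ids, "group"]
            if len(frac_ids) < 4 or frac_groups.nunique() < 2:
                continue
            t = compare_alpha(alpha.loc[frac_ids], manifest)
            t.insert(0, "fraction", fraction)
            tests.append(t)
        if tests:
            iio.write_result_table(pd.concat(tests, ignore_index=True),
                                   outdir / "alpha_tests.tsv")
        if tree is not None:
            perm_rows = []
            for fraction in ("pos", "neg"):
                frac_ids = list(site_meta.loc[site_meta["fraction"] == fraction,
                                              "sample_id"])
                sub = CountTable(table.data[frac_ids])
                dm = unweighted_unifrac(sub, tree, prune=config.prune)
                dm_frame = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
                dm_frame.index.name = "sample_id"
                iio.write_result_table(dm_frame, outdir / f"unifrac_{fraction}.tsv",
                                       index=True)
                ordination = pcoa(dm)
                coords = ordination.coordinates.copy()
                coords.index.name = "sample_id"
                iio.write_result_table(coords, outdir / f"pcoa_{fraction}.tsv",
                                       index=True)
                res = permanova(dm, manifest, column="group",
                                n_perm=config.n_perm, seed=config.seed + 11)
                row = res.as_frame()
                row.insert(0, "fraction", fraction)
                perm_rows.append(row)
            iio.write_result_table(pd.concat(perm_rows, ignore_index=True),
                                   outdir / "permanova.tsv")

    with _stage(report, outdir, "scoring"):
        index = iga_index_matrix(paired, config.pseudocount)
        out_index = index.copy()
        out_index.index.name = "taxon_id"
        iio.write_result_table(out_index, outdir / "iga_index.tsv", index=True)
        calls = {}
        for group in ("axSpA", "HC"):
            calls[group] = call_enrichment(index, manifest, group,
                                           fdr_threshold=config.fdr_threshold)
        both = pd.concat(calls.values(), ignore_index=True)
        iio.write_result_table(both, outdir / "enrichment_calls.tsv")
        between = compare_index_between_groups(index, manifest)
        iio.write_result_table(between, outdir / "index_group_comparison.tsv")
        overlap_rows = []
        for call in ("enriched", "depleted"):
            a, b, shared = shared_taxa_overlap(calls["axSpA"], calls["HC"], call)
            overlap_rows.append({"call": call, "n_only_axSpA": a,
                                 "n_only_HC": b, "n_shared": shared})
        iio.write_result_table(pd.DataFrame(overlap_rows),
                               outdir / "enrichment_overlap.tsv")
        report.add("scoring_taxa", len(index.index))

    with _stage(report, outdir, "correlation"):
        corr_index = correlate_with_basdai(index, manifest, statistic_type="index",
                                           fdr_threshold=config.fdr_threshold)
        # abundance target: unsorted libraries when present, else the
        # mean of the two sorted fractions' relative abundances
        unsorted = site_meta[site_meta["fraction"] == "unsorted"]
        if len(unsorted) > 0:
            sub = table.data[list(unsorted["sample_id"])].copy()
            sub.columns = list(unsorted["subject_id"])
            abundance = iqc.to_relative_abundance(sub.loc[paired.taxon_ids],
                                                  config.pseudocount)
        else:
            rel_pos = iqc.to_relative_abundance(paired.counts_pos, config.pseudocount)
            rel_neg = iqc.to_relative_abundance(paired.counts_neg, config.pseudocount)
            abundance = (rel_pos + rel_neg) / 2.0
        corr_abund = correlate_with_basdai(abundance, manifest,
                                           statistic_type="abundance",
                                           fdr_threshold=config.fdr_threshold)
        iio.write_result_table(pd.concat([corr_index, corr_abund],
                                         ignore_index=True),
                               outdir / "basdai_correlation.tsv")

    with _stage(report, outdir, "discriminant"):
        cascade_cfg = CascadeConfig.preset(config.lefse_preset,
                                           seed=(config.seed + 23) % (2 ** 31))
        meta = site_meta.set_index("sample_id")
        results = {}
        for fraction, counts in (("pos", paired.counts_pos),
                                 ("neg", paired.counts_neg)):
            sample_ids = [paired.sample_ids_pos[s] if fraction == "pos"
                          else paired.sample_ids_neg[s]
                          for s in paired.subject_ids]
            labels = [meta.loc[sid, "group"] for sid in sample_ids]
            sub = (meta.loc[sample_ids, "sex"].tolist()
                   if "sex" in meta.columns else None)
            feats = counts.astype(float)
            res = run_cascade(feats, labels, subclass_labels=sub,
                              config=cascade_cfg)
            iio.write_result_table(res, outdir / f"discriminant_taxa_{fraction}.tsv")
            results[fraction] = res
        a, b, shared = overlap_significant(results["pos"], results["neg"])
        iio.write_result_table(
            pd.DataFrame([{"n_only_pos": a, "n_only_neg": b, "n_shared": shared}]),
            outdir / "discriminant_taxa_overlap.tsv")
        if config.function_table:
            ftab = iio.read_count_table(config.function_table)
            fresults = {}
            for fraction in ("pos", "neg"):
                sample_ids = [paired.sample_ids_pos[s] if fraction == "pos"
                              else paired.sample_ids_neg[s]
                              for s in paired.subject_ids]
                present = [sid for sid in sample_ids if sid in ftab.sample_ids]
                if len(present) < 4:
                    continue
                labels = [meta.loc[sid, "group"] for sid in present]
                sub = (meta.loc[present, "sex"].tolist()
                       if "sex" in meta.columns else None)
                res = run_cascade(ftab.data[present].astype(float), labels,
                                  subclass_labels=sub, config=cascade_cfg)
                iio.write_result_table(
                    res, outdir / f"discriminant_function_{fraction}.tsv")
                fresults[fraction] = res
            if len(fresults) == 2:
                a, b, shared = overlap_significant(fresults["pos"], fresults["neg"])
                iio.write_result_table(
                    pd.DataFrame([{"n_only_pos": a, "n_only_neg": b,
                                   "n_shared": shared}]),
                    outdir / "discriminant_function_overlap.tsv")

    file_report = generate_report(outdir)
    for key, value in report.entries.items():
        file_report.entries.setdefault(key, value)
    iio.write_result_table(file_report.as_frame(), outdir / "report.tsv")
    return file_report


def generate_report(run_dir) -> RunReport:
    """Consolidated report of a (possibly partial) run directory.

    Lists every emitted TSV with its data row count and flags failed or
    missing stages; every number is recomputable from the files.
    """
    run_dir = Path(run_dir)
    if not run_dir.is_dir() or not any(run_dir.iterdir()):
        raise ValueError(f"run directory {run_dir} is missing or empty")
    report = RunReport()
    for marker in sorted(run_dir.glob("FAILED_*")):
        report.add(f"failed_stage:{marker.name[7:]}", marker.read_text().strip())
    files = sorted(p for p in run_dir.glob("*.tsv") if p.name != "report.tsv")
    for path in files:
        with open(path) as fh:
            n_rows = sum(1 for line in fh if line.strip() and not
                         line.startswith("#")) - 1
        report.add(f"rows:{path.name}", max(n_rows, 0))
    stage_markers = {"qc": "qc_log.tsv", "scoring": "iga_index.tsv",
                     "diversity": "alpha_diversity.tsv",
                     "correlation": "basdai_correlation.tsv",
                     "discriminant": "discriminant_taxa_pos.tsv"}
    names = {p.name for p in files}
    for stage, probe in stage_markers.items():
        report.add(f"stage:{stage}",
                   "complete" if probe in names else "missing")
    return report
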