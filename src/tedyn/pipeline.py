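"""End-to-end pipeline: simulate -> cluster -> abundance -> age -> expression
-> methylation -> joined reports, with a single flat config and deterministic
TSV/JSON outputs (reruns under the same config are byte-identical).

Every stage threshold of the analysis lives in :class:`PipelineConfig`;
unknown config keys are rejected.  Machine-readable outputs are TSV and JSON
only; logging goes to stderr.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    cluster_age,
    methylation_divergence as md,
    read_clustering as rc,
    repeat_abundance as ra,
    synthetic_data as sd,
    te_expression as te,
)

logger = logging.getLogger("tedyn")

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All inputs, thresholds and the seed of a pipeline run."""

    accessions: list[str] = field(default_factory=lambda: ["11", "8", "12", "13", "3"])
    seed: int = 0
    # simulation
    read_length: int = 125
    reads_per_accession: int = 800
    background_genome_length: int = 60_000
    n_loci: int = 300
    positions_per_locus: int = 5
    coverage_mean: int = 100
    true_dmr_fraction: float = 0.015
    partial_dmr_fraction: float = 0.17
    # clustering
    min_overlap: float = 0.55
    min_identity: float = 0.90
    min_fraction: float = 0.002
    # abundance
    g_monoploid: float = 865.0
    ploidy: int = 3
    # age classification
    bin_width: float = 0.001
    b_tol: float = 0.001
    optimum_cut: float = 0.99
    min_pairs: int = 20
    # expression
    pseudocount: float = 0.1
    outlier_k: float = 3.0
    axis: str = "rpm"
    # methylation
    min_coverage: int = 50
    contexts: list[str] = field(default_factory=lambda: ["CG"])
    verbosity: str = "INFO"

    _RANGES = {
        "min_overlap": (0.0, 1.0),
        "min_identity": (0.0, 1.0),
        "min_fraction": (0.0, 1.0),
        "bin_width": (1e-6, 0.1),
        "optimum_cut": (0.9, 1.0),
        "true_dmr_fraction": (0.0, 1.0),
        "partial_dmr_fraction": (0.0, 1.0),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.axis not in ("rpm", "fpkm"):
            raise ValueError("axis must be 'rpm' or 'fpkm'")
        if self.g_monoploid <= 0 or self.ploidy <= 0:
            raise ValueError("g_monoploid and ploidy must be > 0")
        if self.min_coverage < 1 or self.min_pairs < 1:
            raise ValueError("min_coverage and min_pairs must be >= 1")
        if self.b_tol < 0 or self.pseudocount <= 0 or self.outlier_k <= 0:
            raise ValueError("b_tol, pseudocount, outlier_k must be positive")
        if self.reads_per_accession <= 0 or self.read_length <= 0:
            raise ValueError("reads_per_accession and read_length must be > 0")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**data)
        config.validate()
        return config

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def sim_config(self) -> sd.SimulationConfig:
        return sd.SimulationConfig(
            accessions=list(self.accessions),
            read_length=self.read_length,
            reads_per_accession=self.reads_per_accession,
            background_genome_length=self.background_genome_length,
            seed=self.seed,
            n_loci=self.n_loci,
            positions_per_locus=self.positions_per_locus,
            coverage_mean=self.coverage_mean,
            true_dmr_fraction=self.true_dmr_fraction,
            partial_dmr_fraction=self.partial_dmr_fraction,
        )


def configure_logging(verbosity: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("tedyn")
    root.handlers[:] = [handler]
    root.setLevel(getattr(logging, verbosity.upper(), logging.INFO))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------


def cluster_accession(
    reads: list[tuple[str, str]], config: PipelineConfig
) -> rc.ClusteringResult:
    return rc.build_clusters(
        reads, min_overlap_frac=config.min_overlap, min_identity=config.min_identity
    )


def make_table1(abundance: pd.DataFrame, level: str = "superfamily") -> pd.DataFrame:
    """Abundance summary in the classic layout: one row per accession and
    annotation with cluster counts, young-cluster counts, Mb and % genome."""
    cols = [
        "accession", "te_class", "order", "superfamily",
        "n_clusters", "n_clusters_young", "size_mb", "percent_genome",
    ]
    have = [c for c in cols if c in abundance.columns]
    return ra.round_for_report(abundance)[have]


def make_table2(
    dmr_calls: pd.DataFrame,
    annotations: pd.DataFrame,
    expression: pd.DataFrame,
    accessions: list[str] | None = None,
) -> pd.DataFrame:
    """Differentially methylated TEs with per-accession %CGm, DNA and RNA
    content; missing expression cells carry the ``#N/A`` marker."""
    return md.join_te_expression(dmr_calls, annotations, expression, accessions)


def run_pipeline(config: PipelineConfig, outdir: Path) -> dict:
    """Execute every stage and write the report bundle; returns the summary."""
    config.validate()
    configure_logging(config.verbosity)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    summary: dict = {"config": config.to_dict()}

    # --- simulate ---------------------------------------------------------
    logger.info("stage simulate: seed=%d", config.seed)
    specs = sd.default_family_specs(list(config.accessions))
    sim = sd.simulate_genome(specs, config.sim_config())
    sd.write_reads_fasta(sim, outdir / "reads")
    _write_tsv(sim.truth, outdir / "read_truth.tsv")
    truth_map = sim.truth_map()

    # --- cluster / abundance / age per accession --------------------------
    membership_rows = []
    abundance_frames = []
    age_rows = []
    young_by_acc = {}
    counts_by_acc = {}
    for acc in config.accessions:
        logger.info("stage cluster: accession %s", acc)
        result = cluster_accession(sim.reads[acc], config)
        clusters = rc.annotate_from_truth(result.clusters, truth_map, sim.family_lineages)
        for c in clusters:
            membership_rows.extend((r, c.cluster_id, acc) for r in c.read_ids)
        kept = rc.filter_clusters(
            clusters, min_fraction=config.min_fraction, total_reads=result.total_reads
        )
        merged = rc.merge_by_annotation(kept)
        categories = {}
        for c in merged:
            cat = cluster_age.classify_identities(
                c.pair_identities,
                bin_width=config.bin_width,
                b_tol=config.b_tol,
                optimum_cut=config.optimum_cut,
                min_pairs=config.min_pairs,
            )
            if cat is not None:
                categories[c.cluster_id] = cat.category
            age_rows.append(
                {
                    "accession": acc,
                    "cluster_id": c.cluster_id,
                    "annotation": c.annotation.label(),
                    "n_pairs": len(c.pair_identities),
                    "category": cat.category if cat else 0,
                    "is_young": bool(cat and cat.is_young),
                }
            )
        total_bases = sum(len(seq) for _, seq in sim.reads[acc])
        abundance_frames.append(
            ra.records_from_clusters(
                merged, acc, total_bases, categories, config.g_monoploid
            )
        )
        cats = [v for v in categories.values()]
        young_by_acc[acc] = cluster_age.young_fraction(cats) if cats else 0.0
        counts_by_acc[acc] = {
            c.annotation.label(): c.n_reads for c in merged if c.annotation.te_class != "unclassified"
        }

    membership = pd.DataFrame(membership_rows, columns=["read_id", "cluster_id", "accession"])
    _write_tsv(membership.sort_values(["accession", "cluster_id", "read_id"]), outdir / "cluster_membership.tsv")
    abundance = pd.concat(abundance_frames, ignore_index=True)
    _write_tsv(ra.round_for_report(abundance), outdir / "cluster_summary.tsv")
    agg = ra.aggregate(abundance, level="superfamily", g_monoploid=config.g_monoploid)
    _write_tsv(make_table1(agg), outdir / "table1.tsv")
    _write_tsv(pd.DataFrame(age_rows), outdir / "cluster_age.tsv")
    summary["young_fraction_percent"] = {a: round(v, 1) for a, v in young_by_acc.items()}
    summary["sampled_genome_fraction_percent"] = round(
        ra.sampled_genome_fraction(
            config.reads_per_accession, config.read_length, config.ploidy, config.g_monoploid
        ),
        6,
    )

    # --- abundance G-test --------------------------------------------------
    counts = pd.DataFrame(counts_by_acc).T.fillna(0.0)
    counts = counts.loc[:, (counts.sum(axis=0) > 0)]
    counts = counts.loc[counts.sum(axis=1) > 0]
    if counts.shape[0] >= 2 and counts.shape[1] >= 2:
        g, dof, p = ra.abundance_g_test(counts)
        summary["abundance_g_test"] = {"G": round(g, 4), "df": dof, "p": p}

    # --- expression --------------------------------------------------------
    logger.info("stage expression")
    dna_counts = sd.dna_counts_from_truth(sim.truth)
    expr_counts = sd.simulate_expression(specs, dna_counts, config.sim_config())
    expr = te.normalize(expr_counts, pseudocount=config.pseudocount)
    _write_tsv(expr, outdir / "expression.tsv")
    regressions = {}
    for acc in config.accessions:
        try:
            fit = te.dna_rna_regression(expr, acc, axis=config.axis)
        except ValueError:
            continue
        regressions[acc] = {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "p_value": fit.p_value,
            "n_clusters": fit.n_clusters,
        }
    summary["expression_regressions"] = regressions
    summary["expression_outliers"] = te.flag_outliers(expr, k=config.outlier_k)

    # --- methylation -------------------------------------------------------
    logger.info("stage methylation")
    te_families = sorted(
        s.family_id for s in specs if s.annotation.te_class in ("I", "II")
    )
    meth = sd.simulate_methylation(config.sim_config(), te_families=te_families)
    _write_tsv(meth.table, outdir / "methylation.tsv")
    _write_tsv(meth.locus_truth[["locus_id", "kind", "detail"]], outdir / "locus_annotation.tsv")
    filtered = md.filter_positions(
        meth.table, min_coverage=config.min_coverage, contexts=tuple(config.contexts)
    )
    accs = list(config.accessions)
    dmps = md.dmp_table(filtered, accs)
    dmrs = md.dmr_table(filtered, accs)
    _write_tsv(dmps, outdir / "dmp.tsv")
    _write_tsv(dmrs, outdir / "dmr.tsv")
    summary["methylation"] = md.summarize(dmrs, meth.locus_truth)
    summary["methylation"]["filtered_positions"] = len(filtered)
    table2 = md.join_te_expression(dmrs, meth.locus_truth, expr, accs)
    _write_tsv(table2, outdir / "table2.tsv")

    # --- digests -----------------------------------------------------------
    digests = {
        p.relative_to(outdir).as_posix(): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "report.json"
    }
    summary["digests"] = digests
    _write_json(summary, outdir / "report.json")
    logger.info("pipeline complete: %s", outdir)
    return summary
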