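"""Genome-occupancy accounting of repeat clusters against a monoploid genome.

In low-coverage sampling, the fraction of read bases falling in a repeat
cluster estimates the fraction of the genome that family occupies, so
occupancy in Mb is (cluster read bases / total read bases) x G, with G the
monoploid genome size (865 Mb for the dandelion studied here).  Occupancy is
computed from read-base FRACTIONS scaled by the monoploid size, not from raw
read-base sums — only that reading makes a 27.35 % fraction equal 236.6 Mb.

Also here: aggregation of per-cluster records to class/order/superfamily
level with totals, the sampled-genome-fraction bookkeeping (reads x length /
ploidy x G), and a likelihood-ratio G-test for read-count differences between
accessions (plain likelihood-ratio chi-square, no Yates/Williams correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .read_clustering import AnnotationLineage, Cluster
from .cluster_age import YOUNG_CATEGORIES

DEFAULT_G_MONOPLOID_MB = 865.0
DEFAULT_PLOIDY = 3

_LEVELS = ("class", "order", "superfamily", "family")
_LEVEL_COLS = {"class": 1, "order": 2, "superfamily": 3, "family": 4}


@dataclass
class AbundanceRecord:
    accession: str
    annotation: AnnotationLineage
    size_mb: float
    percent_genome: float
    n_clusters: int
    n_clusters_young: int


def genome_size_mb(
    cluster_read_bases: float,
    total_read_bases: float,
    g_monoploid: float = DEFAULT_G_MONOPLOID_MB,
) -> float:
    """Mb of monoploid genome occupied by a cluster's read-base fraction."""
    if total_read_bases <= 0:
        raise ValueError("total_read_bases must be > 0")
    if cluster_read_bases < 0:
        raise ValueError("cluster_read_bases must be >= 0")
    return cluster_read_bases / total_read_bases * g_monoploid


def percent_of_genome(size_mb: float, g_monoploid: float = DEFAULT_G_MONOPLOID_MB) -> float:
    if g_monoploid <= 0:
        raise ValueError("g_monoploid must be > 0")
    return size_mb / g_monoploid * 100.0


def sampled_genome_fraction(
    n_reads: float,
    read_length_bp: float,
    ploidy: int = DEFAULT_PLOIDY,
    g_monoploid_mb: float = DEFAULT_G_MONOPLOID_MB,
) -> float:
    """Percent of the (ploidy x monoploid) genome covered by sampled bases."""
    if ploidy <= 0 or g_monoploid_mb <= 0:
        raise ValueError("ploidy and genome size must be > 0")
    return n_reads * read_length_bp / (ploidy * g_monoploid_mb * 1e6) * 100.0


def records_from_clusters(
    clusters: list[Cluster],
    accession: str,
    total_read_bases: float,
    categories: dict[str, int] | None = None,
    g_monoploid: float = DEFAULT_G_MONOPLOID_MB,
) -> pd.DataFrame:
    """Per-cluster abundance table for one accession.

    ``categories`` maps cluster_id to its age category (1-6); clusters absent
    from the map count as not-young.  One row per (merged) cluster, keeping
    ``n_members`` as the cluster count behind each annotation.
    """
    categories = categories or {}
    rows = []
    for c in clusters:
        size = genome_size_mb(c.total_read_bases, total_read_bases, g_monoploid)
        cat = categories.get(c.cluster_id)
        rows.append(
            {
                "accession": accession,
                "te_class": c.annotation.te_class,
                "order": c.annotation.order,
                "superfamily": c.annotation.superfamily,
                "family": c.annotation.family,
                "size_mb": size,
                "percent_genome": percent_of_genome(size, g_monoploid),
                "n_clusters": c.n_members,
                "n_clusters_young": c.n_members if cat in YOUNG_CATEGORIES else 0,
                "n_reads": c.n_reads,
            }
        )
    return pd.DataFrame(rows)


def aggregate(
    records: pd.DataFrame,
    level: str = "superfamily",
    g_monoploid: float = DEFAULT_G_MONOPLOID_MB,
    totals: bool = True,
) -> pd.DataFrame:
    """Sum abundance within annotation groups at the requested level, per accession.

    A TOTAL row per accession is appended unless ``totals`` is False.
    """
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}")
    if records.empty:
        return records.copy()
    keys = ["accession"] + ["te_class", "order", "superfamily", "family"][: _LEVEL_COLS[level]]
    num = ["size_mb", "n_clusters", "n_clusters_young"]
    if "n_reads" in records.columns:
        num = num + ["n_reads"]
    agg = records.groupby(keys, sort=True, as_index=False)[num].sum()
    agg["percent_genome"] = agg["size_mb"] / g_monoploid * 100.0
    if totals:
        tot = records.groupby("accession", sort=True, as_index=False)[num].sum()
        tot["te_class"] = "TOTAL"
        for col in keys[2:]:
            tot[col] = ""
        tot["percent_genome"] = tot["size_mb"] / g_monoploid * 100.0
        agg = pd.concat([agg, tot[agg.columns]], ignore_index=True)
    return agg


def round_for_report(df: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Mb and % rounded for tabular reports (2 decimals by default)."""
    out = df.copy()
    for col in ("size_mb", "percent_genome"):
        if col in out.columns:
            out[col] = out[col].round(decimals)
    return out


def abundance_g_test(counts: pd.DataFrame) -> tuple[float, int, float]:
    """Likelihood-ratio G-test on an accession x annotation read-count table.

    G = 2 sum O ln(O/E) with expectations from the row/column marginals;
    df = (rows-1)(cols-1); p from the chi-square upper tail.  Raises on an
    all-zero row or column (the expectation is undefined there).
    """
    obs = counts.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"empty row: {counts.index[i]!r}")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"empty column: {counts.columns[j]!r}")
    g, p, dof, _ = chi2_contingency(obs, lambda_="log-likelihood", correction=False)
    return float(g), int(dof), float(p)
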