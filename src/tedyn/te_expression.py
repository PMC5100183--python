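"""Transcription of repeat clusters versus their genomic abundance.

Per-cluster genomic (DNA) and transcriptomic (RNA) read counts are normalized
to reads-per-million (RPM) within each accession and library, and to FPKM
using the cluster representative length; transcription level is summarized as
log2((rna_fpkm + eps) / (dna_fpkm + eps)) with a pseudocount eps (default
0.1 FPKM) guarding zeros.  Per accession, a simple linear regression of RNA
on DNA abundance (RPM axes by default, matching scatter-plot convention; FPKM
switchable) tests whether transcription tracks copy number.  Clusters whose
log ratio exceeds median + k*MAD (raw, unscaled MAD; k = 3) are flagged as
low-abundance/high-expression outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_OUTLIER_K = 3.0

_REQUIRED = ["cluster_id", "accession", "dna_count", "rna_count", "rep_length"]


@dataclass
class RegressionResult:
    accession: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_clusters: int


def normalize(counts: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Add RPM, FPKM and log2 RNA/DNA ratio columns.

    RPM = count / library total x 1e6 per accession and library (DNA and RNA
    totals separate); FPKM additionally divides by representative length in
    kb.  Raises if a library total is zero or lengths are non-positive.
    """
    missing = [c for c in _REQUIRED if c not in counts.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (counts["rep_length"] <= 0).any():
        raise ValueError("rep_length must be > 0")
    df = counts.copy()
    for kind in ("dna", "rna"):
        totals = df.groupby("accession")[f"{kind}_count"].transform("sum")
        if (totals == 0).any():
            bad = sorted(df.loc[totals == 0, "accession"].unique())
            raise ValueError(f"zero {kind.upper()} library total for accessions {bad}")
        df[f"{kind}_rpm"] = df[f"{kind}_count"] / totals * 1e6
        df[f"{kind}_fpkm"] = df[f"{kind}_rpm"] / (df["rep_length"] / 1000.0)
    df["log_ratio"] = np.log2(
        (df["rna_fpkm"] + pseudocount) / (df["dna_fpkm"] + pseudocount)
    )
    return df


def dna_rna_regression(
    table: pd.DataFrame, accession: str, axis: str = "rpm"
) -> RegressionResult:
    """OLS of RNA abundance on DNA abundance across one accession's clusters."""
    if axis not in ("rpm", "fpkm"):
        raise ValueError("axis must be 'rpm' or 'fpkm'")
    sub = table[table["accession"] == accession]
    if len(sub) < 3:
        raise ValueError(f"insufficient clusters for {accession!r}: need >= 3")
    x = sub[f"dna_{axis}"].to_numpy(dtype=float)
    y = sub[f"rna_{axis}"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    return RegressionResult(
        accession=accession,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_clusters=len(sub),
    )


def flag_outliers(
    table: pd.DataFrame, k: float = DEFAULT_OUTLIER_K, accession: str | None = None
) -> list[str]:
    """Clusters with log_ratio above median + k*MAD (per accession if given)."""
    sub = table if accession is None else table[table["accession"] == accession]
    if sub.empty:
        return []
    lr = sub["log_ratio"].to_numpy(dtype=float)
    med = float(np.median(lr))
    mad = float(stats.median_abs_deviation(lr, scale=1.0))
    flagged = sub.loc[sub["log_ratio"] > med + k * mad, "cluster_id"]
    return sorted(flagged.unique())
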