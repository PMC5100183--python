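"""Qualitative CG-methylation divergence from reduced-representation bisulfite data.

Input is a per-position count table (``locus_id  position  context
<acc>_total  <acc>_methylated ...``) as produced downstream of a
reference-free RRBS pipeline.  Positions are filtered to a high-confidence
subset covered at >= ``min_coverage`` (default 50x) in EVERY accession and in
the requested contexts (default CG only).  Because plant CG methylation is
strongly bimodal, quantitative proportions are collapsed to three qualitative
levels: low (< 25 %), intermediate (25-75 %, boundaries inclusive) and high
(> 75 %).

A position (DMP) or locus (DMR; per-accession unweighted mean over its
filtered CG positions) is then:

* ``true``       if both low and high occur among accessions,
* ``partial``    if exactly the adjacent pair {low, intermediate} or
                 {intermediate, high} occurs,
* ``invariant``  if a single level occurs.

"Variable" loci are partial + true.  Summaries report variable fractions and
the annotation breakdown (TE / transcript / unknown); the TE subset can be
joined with per-accession expression to a wide report, missing cells marked
``#N/A``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_MIN_COVERAGE = 50
DEFAULT_CONTEXTS = ("CG",)

LOW, INTERMEDIATE, HIGH = "low", "intermediate", "high"
NA_MARKER = "#N/A"


@dataclass
class DmCall:
    unit: str  # "position" | "region"
    locus_id: str
    position: int | None
    levels: dict[str, str]  # accession -> level
    call: str  # "invariant" | "partial" | "true"


def accessions_of(table: pd.DataFrame) -> list[str]:
    """Accession labels inferred from the ``<acc>_total`` column pairs."""
    accs = [c[: -len("_total")] for c in table.columns if c.endswith("_total")]
    missing = [a for a in accs if f"{a}_methylated" not in table.columns]
    if missing or not accs:
        raise ValueError("malformed methylation table: need <acc>_total/<acc>_methylated pairs")
    return accs


def filter_positions(
    table: pd.DataFrame,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    contexts: tuple[str, ...] = DEFAULT_CONTEXTS,
    required_accessions: list[str] | None = None,
) -> pd.DataFrame:
    """Positions covered >= min_coverage (inclusive) in every required accession."""
    accs = required_accessions or accessions_of(table)
    keep = table["context"].isin(contexts)
    for a in accs:
        keep &= table[f"{a}_total"] >= min_coverage
    return table.loc[keep].reset_index(drop=True)


def level_of(proportion: float) -> str:
    """Collapse a methylation proportion to low / intermediate / high."""
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion {proportion} outside [0, 1]")
    if proportion < 0.25:
        return LOW
    if proportion > 0.75:
        return HIGH
    return INTERMEDIATE


def call_levels(position: pd.Series, accessions: list[str]) -> dict[str, str]:
    """Per-accession qualitative level of one position (methylated / total)."""
    return {
        a: level_of(position[f"{a}_methylated"] / position[f"{a}_total"])
        for a in accessions
    }


def _call_from_levels(levels: dict[str, str]) -> str:
    present = set(levels.values())
    if LOW in present and HIGH in present:
        return "true"
    if len(present) == 2:
        return "partial"
    return "invariant"


def call_dmp(position: pd.Series, accessions: list[str]) -> DmCall:
    levels = call_levels(position, accessions)
    return DmCall(
        unit="position",
        locus_id=str(position["locus_id"]),
        position=int(position["position"]),
        levels=levels,
        call=_call_from_levels(levels),
    )


def call_dmr(locus_positions: pd.DataFrame, accessions: list[str], weighted: bool = False) -> DmCall:
    """Locus-level call from per-accession mean methylation over its positions.

    The mean is unweighted by coverage by default (``weighted=True`` switches
    to a coverage-weighted mean).
    """
    if locus_positions.empty:
        raise ValueError("locus has no filtered positions")
    levels = {}
    for a in accessions:
        props = locus_positions[f"{a}_methylated"] / locus_positions[f"{a}_total"]
        if weighted:
            mean = float(
                locus_positions[f"{a}_methylated"].sum() / locus_positions[f"{a}_total"].sum()
            )
        else:
            mean = float(props.mean())
        levels[a] = level_of(mean)
    return DmCall(
        unit="region",
        locus_id=str(locus_positions["locus_id"].iloc[0]),
        position=None,
        levels=levels,
        call=_call_from_levels(levels),
    )


def dmp_table(filtered: pd.DataFrame, accessions: list[str] | None = None) -> pd.DataFrame:
    accs = accessions or accessions_of(filtered)
    rows = []
    for _, pos in filtered.iterrows():
        call = call_dmp(pos, accs)
        row = {"locus_id": call.locus_id, "position": call.position, "call": call.call}
        row.update({f"{a}_level": call.levels[a] for a in accs})
        rows.append(row)
    return pd.DataFrame(rows)


def dmr_table(
    filtered: pd.DataFrame, accessions: list[str] | None = None, weighted: bool = False
) -> pd.DataFrame:
    """One row per locus with >= 1 filtered position: mean proportions, levels, call."""
    accs = accessions or accessions_of(filtered)
    rows = []
    for locus, grp in filtered.groupby("locus_id", sort=True):
        call = call_dmr(grp, accs, weighted=weighted)
        row = {"locus_id": locus, "n_positions": len(grp), "call": call.call}
        for a in accs:
            props = grp[f"{a}_methylated"] / grp[f"{a}_total"]
            row[f"{a}_mean"] = float(props.mean())
            row[f"{a}_level"] = call.levels[a]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(dmr_calls: pd.DataFrame, annotations: pd.DataFrame | None = None) -> dict:
    """Counts and percentages of invariant/partial/true DMRs, plus annotation mix.

    ``annotations`` maps ``locus_id`` to ``kind`` (TE / transcript / unknown).
    Percentages are reported to 1 decimal; an empty input yields zeros rather
    than division errors.
    """
    n = len(dmr_calls)
    counts = dmr_calls["call"].value_counts().to_dict() if n else {}
    n_partial = int(counts.get("partial", 0))
    n_true = int(counts.get("true", 0))
    n_variable = n_partial + n_true
    out = {
        "filtered_loci": n,
        "invariant": int(counts.get("invariant", 0)),
        "partial": n_partial,
        "true": n_true,
        "variable": n_variable,
        "variable_percent": round(100.0 * n_variable / n, 1) if n else 0.0,
    }
    if annotations is not None:
        ann = annotations.set_index("locus_id")["kind"]
        variable = dmr_calls.loc[dmr_calls["call"] != "invariant", "locus_id"]
        kinds = ann.reindex(variable).fillna("unknown")
        for kind in ("TE", "transcript", "unknown"):
            k = int((kinds == kind).sum())
            out[f"variable_{kind}"] = k
            out[f"variable_{kind}_percent"] = (
                round(100.0 * k / n_variable, 1) if n_variable else 0.0
            )
    return out


def join_te_expression(
    dmr_calls: pd.DataFrame,
    annotations: pd.DataFrame,
    expression: pd.DataFrame,
    accessions: list[str] | None = None,
) -> pd.DataFrame:
    """Wide per-TE report: mean CG proportion, DNA and RNA content per accession.

    Variable DMRs annotated as TE are joined to the expression table via the
    annotation ``detail`` (the TE family / cluster id); cells with no
    expression row for that accession are marked ``#N/A``.
    """
    accs = accessions or sorted(
        {c[: -len("_mean")] for c in dmr_calls.columns if c.endswith("_mean")}
    )
    ann = annotations.set_index("locus_id")
    expr = expression.set_index(["cluster_id", "accession"])
    rows = []
    variable = dmr_calls[dmr_calls["call"] != "invariant"]
    for _, dmr in variable.iterrows():
        locus = dmr["locus_id"]
        if locus not in ann.index or ann.loc[locus, "kind"] != "TE":
            continue
        detail = ann.loc[locus, "detail"]
        row: dict = {"locus_id": locus, "te_annotation": detail, "call": dmr["call"]}
        for a in accs:
            row[f"{a}_cgm"] = round(float(dmr[f"{a}_mean"]), 2)
            key = (detail, a)
            if key in expr.index:
                row[f"{a}_dna"] = round(float(expr.loc[key, "dna_rpm"]), 2)
                row[f"{a}_rna"] = round(float(expr.loc[key, "rna_rpm"]), 2)
            else:
                row[f"{a}_dna"] = NA_MARKER
                row[f"{a}_rna"] = NA_MARKER
        rows.append(row)
    return pd.DataFrame(rows)
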