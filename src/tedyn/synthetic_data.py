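"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates low-coverage genome sampling of a polyploid plant whose
repeat compartment is a mixture of transposable-element families of differing
age.  Each family is a random consensus; each genomic copy is the consensus
with i.i.d. substitutions at a per-site ``divergence`` rate (uniform over the
three alternative bases), so the expected pairwise identity between two copies
is (1-d)^2 + d^2/3 ~= 1 - 2d — divergence is the proxy for family age.
Reads are uniform random substrings (default 125 bp), reverse-complemented
with probability 0.5, and carry truth labels.

Also generated: per-cluster DNA/RNA count tables with a weak positive DNA-RNA
relationship plus optional low-abundance/high-expression outlier families, and
per-locus bisulfite count tables with bimodal CG methylation and planted
among-accession level shifts (partial: low<->intermediate or
intermediate<->high; true: low<->high).

Substitution-only mutation (no indels) keeps pairwise identity analytically
checkable; Poisson/Binomial noise models are the simplest generative
stand-ins.  None of this models real LTR structure (TSDs, PBS) or bisulfite
conversion error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .read_clustering import AnnotationLineage, CHLOROPLAST, revcomp

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass
class FamilySpec:
    """One repeat family: consensus, per-accession copy numbers, age, expression.

    ``divergence`` is the per-site substitution probability applied
    independently to every copy (bounded by 0.25, the random-sequence limit);
    ``expression_rate`` is the expected RNA reads per DNA read.
    """

    family_id: str
    annotation: AnnotationLineage
    copies_per_accession: dict[str, int]
    consensus_length: int
    divergence: float
    expression_rate: float = 0.0

    def validate(self, accessions: list[str], read_length: int) -> None:
        if not 0.0 <= self.divergence <= 0.25:
            raise ValueError(f"{self.family_id}: divergence {self.divergence} outside [0, 0.25]")
        if self.consensus_length < read_length:
            raise ValueError(
                f"{self.family_id}: consensus ({self.consensus_length} bp) shorter than read length"
            )
        if set(self.copies_per_accession) != set(accessions):
            raise ValueError(f"{self.family_id}: copies_per_accession keys != accessions")
        if any(v < 0 for v in self.copies_per_accession.values()):
            raise ValueError(f"{self.family_id}: negative copy number")
        if self.expression_rate < 0:
            raise ValueError(f"{self.family_id}: negative expression_rate")


@dataclass
class SimulationConfig:
    """Study-design knobs shared by all three generators."""

    accessions: list[str] = field(default_factory=lambda: ["11", "8", "12", "13", "3"])
    read_length: int = 125
    reads_per_accession: int = 800  # scaled-down stand-in for 5 M reads/accession
    background_genome_length: int = 60_000
    seed: int = 0
    # methylation table
    n_loci: int = 300
    positions_per_locus: int = 5
    coverage_mean: int = 100
    true_dmr_fraction: float = 0.015
    partial_dmr_fraction: float = 0.17

    def validate(self) -> None:
        if self.reads_per_accession <= 0:
            raise ValueError("reads_per_accession must be > 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be > 0")
        for name in ("true_dmr_fraction", "partial_dmr_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.true_dmr_fraction + self.partial_dmr_fraction > 1.0:
            raise ValueError("DMR fractions sum above 1")
        if self.coverage_mean <= 0 or self.n_loci <= 0 or self.positions_per_locus <= 0:
            raise ValueError("counts must be positive")


def default_family_specs(accessions: list[str] | None = None) -> list[FamilySpec]:
    """Repeat families mirroring the study system at small scale.

    An LTR-dominated compartment: abundant young Copia (Maximus/SIRE) and
    Gypsy (Chromovirus) families — the Chromovirus copy number higher in the
    second clade (accessions 12, 13, 3) — an older diverged Gypsy (Ogre/Tat),
    a low-abundance but highly transcribed Copia (Ale II) outlier, DNA
    transposons, a LINE, rDNA, a tandem repeat, and a chloroplast contaminant
    that downstream filtering must exclude.
    """
    acc = accessions or ["11", "8", "12", "13", "3"]
    if len(acc) != 5:
        # clade structure needs 5 accessions; otherwise give every accession
        # the mean copy number
        def clade(first: int, second: int) -> dict[str, int]:
            return {a: (first + second) // 2 for a in acc}
    else:

        def clade(first: int, second: int) -> dict[str, int]:
            return {acc[0]: first, acc[1]: first, acc[2]: second, acc[3]: second, acc[4]: second}

    flat = lambda n: {a: n for a in acc}
    L = AnnotationLineage
    return [
        FamilySpec("copia_sire", L("I", "LTR", "Copia", "Maximus-SIRE"), flat(55), 800, 0.004, 0.3),
        FamilySpec("copia_ale", L("I", "LTR", "Copia", "AleII"), flat(10), 600, 0.004, 12.0),
        FamilySpec("gypsy_chromo", L("I", "LTR", "Gypsy", "Chromovirus"), clade(35, 80), 800, 0.004, 0.2),
        FamilySpec("gypsy_ogre", L("I", "LTR", "Gypsy", "Ogre-Tat"), flat(45), 800, 0.04, 0.05),
        FamilySpec("hat", L("II", "TIR", "hAT", "hAT-Tip100"), clade(14, 28), 500, 0.02, 0.4),
        FamilySpec("line_l1", L("I", "LINE", "L1", "L1-1"), flat(9), 600, 0.05, 0.1),
        FamilySpec("rdna_45s", L("rDNA", "rDNA", "45S", "45S-1"), clade(6, 16), 700, 0.01, 1.5),
        FamilySpec("tandem_sat", L("tandem", "satellite", "Sat1", "Sat1-1"), flat(8), 400, 0.02, 0.0),
        FamilySpec("chloro", CHLOROPLAST, flat(18), 1200, 0.001, 0.0),
    ]


# ---------------------------------------------------------------------------
# genome / read simulation
# ---------------------------------------------------------------------------


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Apply i.i.d. substitutions at rate ``divergence`` (always to a new base)."""
    if divergence == 0.0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < divergence)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_family_copies(
    rng: np.random.Generator, consensus: str, divergences: list[float]
) -> list[str]:
    """One mutated copy per entry of ``divergences`` (per-copy age mixtures)."""
    return [mutate(rng, consensus, d) for d in divergences]


def sample_read(rng: np.random.Generator, source: str, read_length: int) -> str:
    """Uniform random substring, reverse-complemented with probability 0.5."""
    start = int(rng.integers(0, len(source) - read_length + 1))
    read = source[start : start + read_length]
    if rng.random() < 0.5:
        read = revcomp(read)
    return read


def simulate_cluster_reads(
    rng: np.random.Generator,
    divergences: list[float],
    n_reads: int,
    consensus_length: int = 500,
    read_length: int = 125,
) -> list[tuple[str, str]]:
    """Reads of a single standalone family (used for classifier experiments)."""
    consensus = random_sequence(rng, consensus_length)
    copies = simulate_family_copies(rng, consensus, divergences)
    reads = []
    for i in range(n_reads):
        copy = copies[int(rng.integers(0, len(copies)))]
        reads.append((f"r{i:04d}", sample_read(rng, copy, read_length)))
    return reads


@dataclass
class GenomeSimulation:
    reads: dict[str, list[tuple[str, str]]]  # accession -> [(read_id, seq)]
    truth: pd.DataFrame  # read_id, accession, family_id ("" = background)
    family_lineages: dict[str, AnnotationLineage]
    consensi: dict[str, str]

    def truth_map(self) -> dict[str, str]:
        return dict(zip(self.truth["read_id"], self.truth["family_id"]))


def simulate_genome(
    spec_list: list[FamilySpec], config: SimulationConfig
) -> GenomeSimulation:
    """Per-accession read pools with truth labels.

    Each accession's sequence pool is a unique background plus every family
    copy; reads are drawn from sources with probability proportional to the
    number of valid start positions.  Identical (specs, config) including the
    seed reproduce the output exactly.
    """
    config.validate()
    for spec in spec_list:
        spec.validate(config.accessions, config.read_length)
    rng = np.random.default_rng(config.seed)
    consensi = {s.family_id: random_sequence(rng, s.consensus_length) for s in spec_list}
    reads: dict[str, list[tuple[str, str]]] = {}
    rows = []
    for acc in config.accessions:
        sources: list[tuple[str, str]] = [("", random_sequence(rng, config.background_genome_length))]
        for spec in spec_list:
            for _ in range(spec.copies_per_accession[acc]):
                sources.append((spec.family_id, mutate(rng, consensi[spec.family_id], spec.divergence)))
        weights = np.array(
            [max(len(s) - config.read_length + 1, 0) for _, s in sources], dtype=float
        )
        weights /= weights.sum()
        acc_reads = []
        for i in range(config.reads_per_accession):
            src = int(rng.choice(len(sources), p=weights))
            family_id, seq = sources[src]
            read_id = f"{acc}_{i:06d}"
            acc_reads.append((read_id, sample_read(rng, seq, config.read_length)))
            rows.append((read_id, acc, family_id))
        reads[acc] = acc_reads
    truth = pd.DataFrame(rows, columns=["read_id", "accession", "family_id"])
    lineages = {s.family_id: s.annotation for s in spec_list}
    return GenomeSimulation(reads, truth, lineages, consensi)


def write_reads_fasta(sim: GenomeSimulation, outdir: Path) -> dict[str, Path]:
    """One FASTA per accession; read IDs encode accession and serial."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for acc, recs in sim.reads.items():
        path = outdir / f"reads_{acc}.fasta"
        SeqIO.write(
            (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in recs),
            str(path),
            "fasta",
        )
        paths[acc] = path
    return paths


def read_reads_fasta(path: Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------


def dna_counts_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Per-family, per-accession genomic read counts from the truth table."""
    counts = (
        truth[truth["family_id"] != ""]
        .groupby(["family_id", "accession"], sort=True)
        .size()
        .reset_index(name="dna_count")
        .rename(columns={"family_id": "cluster_id"})
    )
    return counts


def simulate_expression(
    spec_list: list[FamilySpec],
    dna_counts: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-cluster DNA and RNA read counts per accession.

    RNA count ~ Poisson(expression_rate x DNA count).  Outlier behaviour
    (low DNA abundance, very high transcription) is encoded in the specs as a
    high ``expression_rate`` on a low-copy family.
    """
    rng = np.random.default_rng([config.seed, 101])
    rates = {s.family_id: s.expression_rate for s in spec_list}
    lengths = {s.family_id: s.consensus_length for s in spec_list}
    df = dna_counts.copy()
    missing = set(df["cluster_id"]) - set(rates)
    if missing:
        raise ValueError(f"no spec for clusters {sorted(missing)}")
    df["rna_count"] = [
        int(rng.poisson(rates[cid] * dna)) if rates[cid] > 0 else 0
        for cid, dna in zip(df["cluster_id"], df["dna_count"])
    ]
    df["rep_length"] = [lengths[cid] for cid in df["cluster_id"]]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# methylation simulation
# ---------------------------------------------------------------------------

_LEVEL_DRAWS = {
    "low": (0.02, 0.12),
    "intermediate": (0.40, 0.60),
    "high": (0.88, 0.98),
}


def _draw_proportion(rng: np.random.Generator, level: str) -> float:
    lo, hi = _LEVEL_DRAWS[level]
    return float(rng.uniform(lo, hi))


@dataclass
class MethylationSimulation:
    table: pd.DataFrame  # locus_id position context <acc>_total <acc>_methylated ...
    locus_truth: pd.DataFrame  # locus_id kind detail dmr_class


def simulate_methylation(
    config: SimulationConfig,
    te_families: list[str] | None = None,
) -> MethylationSimulation:
    """Per-position bisulfite count table plus locus annotation/truth map.

    Per locus and accession a methylation proportion is drawn near 0 or near 1
    (bimodal CG methylation); planted loci carry among-accession level shifts:
    'partial' (low<->intermediate or intermediate<->high) and 'true'
    (low<->high).  Coverage ~ Poisson(coverage_mean) truncated to >= 1;
    methylated ~ Binomial(coverage, p).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 202])
    accs = config.accessions
    n = config.n_loci
    n_true = round(n * config.true_dmr_fraction)
    n_partial = round(n * config.partial_dmr_fraction)
    classes = ["true"] * n_true + ["partial"] * n_partial + ["invariant"] * (n - n_true - n_partial)
    kinds = rng.choice(["TE", "transcript", "unknown"], size=n, p=[0.26, 0.41, 0.33])
    te_families = te_families or ["TE_family"]
    rows = []
    truth_rows = []
    for li in range(n):
        locus = f"locus{li:05d}"
        cls = classes[li]
        base = "low" if rng.random() < 0.5 else "high"
        levels = {a: base for a in accs}
        n_shift = int(rng.integers(1, max(2, len(accs))))
        shifted = rng.choice(accs, size=n_shift, replace=False)
        if cls == "true":
            other = "high" if base == "low" else "low"
            for a in shifted:
                levels[a] = other
        elif cls == "partial":
            for a in shifted:
                levels[a] = "intermediate"
        props = {a: _draw_proportion(rng, levels[a]) for a in accs}
        npos = int(rng.integers(max(1, config.positions_per_locus - 2), config.positions_per_locus + 3))
        for p in range(npos):
            row = {"locus_id": locus, "position": p + 1, "context": "CG"}
            for a in accs:
                cov = 0
                while cov < 1:
                    cov = int(rng.poisson(config.coverage_mean))
                row[f"{a}_total"] = cov
                row[f"{a}_methylated"] = int(rng.binomial(cov, props[a]))
            rows.append(row)
        kind = str(kinds[li])
        detail = (
            te_families[li % len(te_families)]
            if kind == "TE"
            else (f"transcript{li:05d}" if kind == "transcript" else "")
        )
        truth_rows.append((locus, kind, detail, cls))
    table = pd.DataFrame(rows)
    locus_truth = pd.DataFrame(truth_rows, columns=["locus_id", "kind", "detail", "dmr_class"])
    return MethylationSimulation(table, locus_truth)


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)


# ---------------------------------------------------------------------------
# classifier benchmark conditions
# ---------------------------------------------------------------------------

#: Per-copy divergence compositions used in classifier recovery experiments.
#: Young: all copies at d = 0.0025, i.e. pairwise divergence ~0.005 — read
#: pairs above the 99 % identity optimum cut.  Old: a proliferation burst at
#: d = 0.03 (pairwise ~0.06, identity hump ~0.94 inside the histogram window)
#: plus a small ancient tail at d = 0.06 whose pairs fall mostly below the
#: window.  40 copies keep same-copy read pairs (identity ~1) a negligible
#: fraction, as in real high-copy-number families.
AGE_CONDITIONS: dict[str, list[float]] = {
    "young": [0.0025] * 40,
    "old": [0.03] * 34 + [0.06] * 6,
}


def age_condition_divergences(kind: str) -> list[float]:
    """Per-copy divergences of the named benchmark condition (young / old)."""
    try:
        return list(AGE_CONDITIONS[kind])
    except KeyError:
        raise ValueError(f"unknown condition {kind!r}") from None
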