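"""Similarity-graph clustering of unassembled genomic reads into repeat families.

Low-coverage genome sampling turns repeat abundance into read abundance: a
repeat family present in many copies contributes many near-identical reads,
which form a dense component in a read-similarity graph.  Reads are connected
when their best overlap alignment covers at least ``min_overlap_frac`` of the
shorter read with at least ``min_identity`` matching columns (defaults 0.55 and
0.90).  Connected components with two or more reads are repeat clusters;
singletons are reported as unclustered.

The overlap aligner is an exact free-end-gap dynamic program (match +1,
mismatch 0, gap -1; diagonal-preferred tie-breaking), so on substitution-only
data the optimum is the best ungapped overlap.  ``N`` never matches.  A
shared-k-mer prefilter (k = 8) skips read pairs that cannot reach 90 %
identity over an admissible overlap: any alignment with at most 10 % non-match
columns over >= 69 columns contains a run of >= 8 consecutive matched columns,
i.e. an exact shared 8-mer, so the prefilter is lossless at these thresholds.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP_FRAC = 0.55
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_FRACTION = 0.002
PREFILTER_K = 8

# ---------------------------------------------------------------------------
# sequence encoding
# ---------------------------------------------------------------------------

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _CODE[ord(_ch)] = _i
    _CODE[ord(_ch.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_BASES = "ACGTN"


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    if not seq:
        raise ValueError("empty sequence")
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][::-1].copy()


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


# ---------------------------------------------------------------------------
# overlap alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapHit:
    """Accepted overlap between two reads.

    ``overlap_length`` is the shorter of the two read spans inside the aligned
    region (equal to the number of alignment columns when the alignment is
    ungapped), so it never exceeds either read length.  ``identity`` is
    matches / alignment columns, gap columns counting as mismatches.
    """

    read_a: str
    read_b: str
    overlap_length: int
    identity: float
    orientation: str  # "same" | "reverse"
    matches: int
    columns: int


@njit(cache=False)
def _overlap_dp(a, b):  # pragma: no cover - exercised via python wrapper
    """Free-end-gap overlap DP; returns (score, matches, columns, ups, lefts).

    Score: match +1, mismatch 0, gap -1.  Ties broken diagonal > up > left,
    end cell chosen by score, then matches, then fewest columns, scanning the
    last column top-down then the last row left-right.
    """
    n = a.shape[0]
    m = b.shape[0]
    S = np.zeros((n + 1, m + 1), dtype=np.int32)
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    C = np.zeros((n + 1, m + 1), dtype=np.int32)
    U = np.zeros((n + 1, m + 1), dtype=np.int32)
    V = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            match = 1 if (ai == b[j - 1] and ai < 4) else 0
            sd = S[i - 1, j - 1] + match
            su = S[i - 1, j] - 1
            sl = S[i, j - 1] - 1
            if sd >= su and sd >= sl:
                S[i, j] = sd
                M[i, j] = M[i - 1, j - 1] + match
                C[i, j] = C[i - 1, j - 1] + 1
                U[i, j] = U[i - 1, j - 1]
                V[i, j] = V[i - 1, j - 1]
            elif su >= sl:
                S[i, j] = su
                M[i, j] = M[i - 1, j]
                C[i, j] = C[i - 1, j] + 1
                U[i, j] = U[i - 1, j] + 1
                V[i, j] = V[i - 1, j]
            else:
                S[i, j] = sl
                M[i, j] = M[i, j - 1]
                C[i, j] = C[i, j - 1] + 1
                U[i, j] = U[i, j - 1]
                V[i, j] = V[i, j - 1] + 1
    bs = -(1 << 30)
    bm = 0
    bc = 0
    bu = 0
    bv = 0
    for i in range(1, n + 1):
        s = S[i, m]
        if s > bs or (s == bs and (M[i, m] > bm or (M[i, m] == bm and C[i, m] < bc))):
            bs, bm, bc, bu, bv = s, M[i, m], C[i, m], U[i, m], V[i, m]
    for j in range(1, m + 1):
        s = S[n, j]
        if s > bs or (s == bs and (M[n, j] > bm or (M[n, j] == bm and C[n, j] < bc))):
            bs, bm, bc, bu, bv = s, M[n, j], C[n, j], U[n, j], V[n, j]
    return bs, bm, bc, bu, bv


def _align_metrics(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(matches, columns, overlap_length) of the best overlap alignment."""
    _, matches, columns, ups, lefts = _overlap_dp(a, b)
    overlap_length = columns - max(ups, lefts)
    return int(matches), int(columns), int(overlap_length)


def pairwise_overlap(
    read_a: str | tuple[str, str],
    read_b: str | tuple[str, str],
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    orientations: tuple[str, ...] = ("same", "reverse"),
) -> OverlapHit | None:
    """Best acceptable overlap between two reads, or None.

    Reads may be given as plain sequences or ``(read_id, sequence)`` pairs.
    A hit requires overlap_length >= min_overlap_frac * min(read lengths) and
    identity >= min_identity; both orientations are tried and the accepted one
    with the higher identity (then more matches, "same" preferred on ties)
    is returned.  The result is symmetric in its two arguments.
    """
    id_a, seq_a = read_a if isinstance(read_a, tuple) else ("a", read_a)
    id_b, seq_b = read_b if isinstance(read_b, tuple) else ("b", read_b)
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    a = encode(seq_a)
    b = encode(seq_b)
    # canonical argument order makes acceptance exactly symmetric
    swapped = (len(seq_b), seq_b) < (len(seq_a), seq_a)
    x, y = (b, a) if swapped else (a, b)
    min_len = min(len(a), len(b))
    need = min_overlap_frac * min_len
    best = None  # (identity, matches, same-orientation flag, overlap, columns, orient)
    for orient in orientations:
        yy = y if orient == "same" else revcomp_codes(y)
        matches, columns, overlap_length = _align_metrics(x, yy)
        if columns == 0 or overlap_length < need:
            continue
        identity = matches / columns
        if identity < min_identity:
            continue
        cand = (identity, matches, 1 if orient == "same" else 0, overlap_length, columns, orient)
        if best is None or cand[:3] > best[:3]:
            best = cand
    if best is None:
        return None
    identity, matches, _, overlap_length, columns, orient = best
    return OverlapHit(
        read_a=id_a,
        read_b=id_b,
        overlap_length=overlap_length,
        identity=identity,
        orientation=orient,
        matches=matches,
        columns=columns,
    )


# ---------------------------------------------------------------------------
# k-mer prefilter
# ---------------------------------------------------------------------------


def _kmer_set(codes: np.ndarray, k: int = PREFILTER_K) -> set[int]:
    """Integer-encoded k-mers of a read; windows containing N are skipped."""
    if len(codes) < k:
        return set()
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    valid = (win < 4).all(axis=1)
    if not valid.any():
        return set()
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win[valid] @ pow4
    return set(vals.tolist())


def candidate_pairs(
    codes_list: list[np.ndarray], k: int = PREFILTER_K
) -> dict[tuple[int, int], tuple[bool, bool]]:
    """Read-index pairs sharing an exact k-mer, with orientation flags.

    Returns ``{(i, j): (same, reverse)}`` with i < j; ``same`` means the pair
    shares a forward k-mer, ``reverse`` that one read shares a k-mer with the
    other's reverse complement.  Lossless for the default overlap thresholds
    at k = 8 (see module docstring).
    """
    fwd = [_kmer_set(c, k) for c in codes_list]
    rev = [_kmer_set(revcomp_codes(c), k) for c in codes_list]
    index: dict[int, list[int]] = defaultdict(list)
    for i, ks in enumerate(fwd):
        for km in ks:
            index[km].append(i)
    pairs: dict[tuple[int, int], list[bool]] = defaultdict(lambda: [False, False])
    for lst in index.values():
        if len(lst) > 1:
            for i, j in itertools.combinations(lst, 2):
                pairs[(i, j)][0] = True
    for i, ks in enumerate(rev):
        for km in ks:
            for j in index.get(km, ()):
                if j != i:
                    pairs[(min(i, j), max(i, j))][1] = True
    return {p: (f[0], f[1]) for p, f in pairs.items()}


# ---------------------------------------------------------------------------
# annotation lineages
# ---------------------------------------------------------------------------

_TE_CLASSES = {"I", "II", "tandem", "rDNA", "unclassified", "chloroplast"}


@dataclass(frozen=True, order=True)
class AnnotationLineage:
    """Hierarchical repeat annotation: class / order / superfamily / family.

    ``te_class`` is one of I (retrotransposons), II (DNA transposons), tandem,
    rDNA, unclassified or chloroplast; lower ranks may be empty but may not
    skip a rank (a family implies a superfamily implies an order).
    """

    te_class: str
    order: str = ""
    superfamily: str = ""
    family: str = ""

    def __post_init__(self):
        if self.te_class not in _TE_CLASSES:
            raise ValueError(f"unknown te_class {self.te_class!r}")
        ranks = (self.order, self.superfamily, self.family)
        seen_empty = False
        for r in ranks:
            if r == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(f"gap in annotation lineage {ranks}")

    def truncate(self, level: str) -> "AnnotationLineage":
        if level == "class":
            return AnnotationLineage(self.te_class)
        if level == "order":
            return AnnotationLineage(self.te_class, self.order)
        if level == "superfamily":
            return AnnotationLineage(self.te_class, self.order, self.superfamily)
        if level == "family":
            return self
        raise ValueError(f"unknown level {level!r}")

    def label(self) -> str:
        parts = [self.te_class, self.order, self.superfamily, self.family]
        return "/".join(p for p in parts if p)


UNCLASSIFIED = AnnotationLineage("unclassified")
CHLOROPLAST = AnnotationLineage("chloroplast")


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    cluster_id: str
    read_ids: tuple[str, ...]
    total_read_bases: int
    read_fraction: float
    annotation: AnnotationLineage = UNCLASSIFIED
    n_members: int = 1  # source clusters folded in by merge_by_annotation
    pair_identities: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


@dataclass
class ClusteringResult:
    clusters: list[Cluster]
    unclustered: tuple[str, ...]
    total_reads: int


def _assign_ids(groups: list[Cluster]) -> list[Cluster]:
    """Cluster IDs by descending read count, ties by smallest member read ID."""
    groups = sorted(groups, key=lambda c: (-c.n_reads, min(c.read_ids)))
    return [replace(c, cluster_id=f"CL{i + 1}") for i, c in enumerate(groups)]


def build_clusters(
    reads: list[tuple[str, str]],
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    use_prefilter: bool = True,
) -> ClusteringResult:
    """Cluster reads into connected components of the similarity graph.

    ``reads`` is a list of (read_id, sequence).  Components with >= 2 reads
    become clusters; singletons are reported unclustered.  Edge identities of
    accepted overlaps are kept per cluster (``pair_identities``) — because the
    prefilter is lossless these are exactly the all-vs-all accepted pairs.
    """
    if not reads:
        return ClusteringResult([], (), 0)
    ids = [r[0] for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read IDs")
    codes = [encode(seq) for _, seq in reads]
    n = len(reads)
    if use_prefilter:
        cand = candidate_pairs(codes)
    else:
        cand = {
            (i, j): (True, True) for i, j in itertools.combinations(range(n), 2)
        }
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for (i, j), (same, rev) in cand.items():
        orients = tuple(
            o for o, flag in (("same", same), ("reverse", rev)) if flag
        )
        hit = pairwise_overlap(
            (ids[i], reads[i][1]),
            (ids[j], reads[j][1]),
            min_overlap_frac=min_overlap_frac,
            min_identity=min_identity,
            orientations=orients,
        )
        if hit is not None:
            graph.add_edge(i, j, identity=hit.identity)
    total = n
    groups: list[Cluster] = []
    unclustered: list[str] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            unclustered.extend(ids[i] for i in comp)
            continue
        members = sorted(comp)
        identities = np.sort(
            np.array(
                [graph.edges[e]["identity"] for e in graph.subgraph(comp).edges],
                dtype=float,
            )
        )
        groups.append(
            Cluster(
                cluster_id="",
                read_ids=tuple(sorted(ids[i] for i in members)),
                total_read_bases=int(sum(len(codes[i]) for i in members)),
                read_fraction=len(members) / total,
                pair_identities=identities,
            )
        )
    clusters = _assign_ids(groups)
    logger.info(
        "clustered %d reads into %d clusters (%d unclustered)",
        total,
        len(clusters),
        len(unclustered),
    )
    return ClusteringResult(clusters, tuple(sorted(unclustered)), total)


def annotate_clusters(
    clusters: list[Cluster], annotation: dict[str, AnnotationLineage]
) -> list[Cluster]:
    """Attach supplied annotations (cluster_id -> lineage); others stay unclassified."""
    return [
        replace(c, annotation=annotation.get(c.cluster_id, c.annotation))
        for c in clusters
    ]


def annotate_from_truth(
    clusters: list[Cluster],
    read_truth: dict[str, str],
    family_lineages: dict[str, AnnotationLineage],
) -> list[Cluster]:
    """Annotate each cluster by the majority true family of its reads.

    Reads mapping to no family (background) vote for "unclassified"; ties are
    broken lexicographically by family label for determinism.
    """
    out = []
    for c in clusters:
        votes = Counter(read_truth.get(r, "") for r in c.read_ids)
        top = max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]
        lineage = family_lineages.get(top, UNCLASSIFIED)
        out.append(replace(c, annotation=lineage))
    return out


def filter_clusters(
    clusters: list[Cluster],
    min_fraction: float = DEFAULT_MIN_FRACTION,
    total_reads: int | None = None,
) -> list[Cluster]:
    """High-abundance clusters: chloroplast removed, then >= min_fraction kept.

    The abundance threshold is applied against nuclear input reads, i.e. the
    denominator excludes reads in chloroplast-annotated clusters; the boundary
    is inclusive.  ``total_reads`` defaults to the reads implied by the
    clusters' stored fractions.
    """
    if not clusters:
        return []
    if total_reads is None:
        c0 = max(clusters, key=lambda c: c.n_reads)
        total_reads = round(c0.n_reads / c0.read_fraction) if c0.read_fraction else 0
    chloro = [c for c in clusters if c.annotation.te_class == "chloroplast"]
    nuclear_total = total_reads - sum(c.n_reads for c in chloro)
    if nuclear_total <= 0:
        return []
    kept = [
        c
        for c in clusters
        if c.annotation.te_class != "chloroplast"
        and c.n_reads / nuclear_total >= min_fraction
    ]
    return kept


def merge_by_annotation(clusters: list[Cluster]) -> list[Cluster]:
    """Merge clusters with identical full annotation lineage.

    Read sets, bases and fractions are summed; ``n_members`` counts the source
    clusters so per-annotation cluster counts survive the merge.  The result
    is independent of input order (fresh IDs by size, members sorted).
    """
    by_lineage: dict[AnnotationLineage, list[Cluster]] = defaultdict(list)
    for c in clusters:
        by_lineage[c.annotation].append(c)
    merged = []
    for lineage, group in by_lineage.items():
        read_ids = tuple(sorted(r for c in group for r in c.read_ids))
        identities = np.sort(np.concatenate([c.pair_identities for c in group]))
        merged.append(
            Cluster(
                cluster_id="",
                read_ids=read_ids,
                total_read_bases=sum(c.total_read_bases for c in group),
                read_fraction=sum(c.read_fraction for c in group),
                annotation=lineage,
                n_members=sum(c.n_members for c in group),
                pair_identities=identities,
            )
        )
    return _assign_ids(merged)
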