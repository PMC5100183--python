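"""Repeat-family age classification from pairwise-identity histograms.

Within a repeat cluster, the distribution of pairwise read identities reflects
the age structure of the family: recently proliferated copies are nearly
identical (mass piled against 100 %), while older families have diverged by
mutation accumulation (mass shifted left or already below the 90 % window).

Per cluster, all accepted pairwise overlap identities are binned on
[0.90, 1.00] (default bin width 0.001), a linear (Y = a + bX) and a quadratic
(Y = a + bX + cX^2) model are fitted by ordinary least squares, the winner is
chosen by BIC, and the cluster is assigned one of six shape categories:

1. increasing linear (linear wins, b > b_tol)          -> young
2. flat linear (linear wins, |b| <= b_tol)             -> old
3. decreasing linear (linear wins, b < -b_tol)         -> old
4. upward parabola (quadratic wins, c > 0)             -> young
5. downward parabola, optimum <= optimum_cut           -> old
6. downward parabola, optimum  > optimum_cut (0.99)    -> young

X is identity as a fraction and Y is relative frequency (both configurable
conventions); b_tol = 0.001 applies on that scale.  "Upward/downward" is the
sign of the quadratic coefficient c.  BIC uses the Gaussian-residual form
n ln(rss/n) + k ln(n); exact ties prefer the linear model (parsimony).
Clusters with fewer than ``min_pairs`` (default 20) identities are not
classified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .read_clustering import (
    DEFAULT_MIN_IDENTITY,
    DEFAULT_MIN_OVERLAP_FRAC,
    candidate_pairs,
    encode,
    pairwise_overlap,
)

DEFAULT_BIN_WIDTH = 0.001
DEFAULT_B_TOL = 0.001
DEFAULT_OPTIMUM_CUT = 0.99
DEFAULT_MIN_PAIRS = 20
YOUNG_CATEGORIES = frozenset({1, 4, 6})

_RSS_FLOOR = 1e-12
_BIC_TIE = 1e-12


@dataclass
class IdentityHistogram:
    """Binned pairwise identities of one cluster on [lo, hi]."""

    cluster_id: str
    bin_edges: np.ndarray
    y: np.ndarray  # relative frequency, sums to 1
    n_pairs: int

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass
class RegressionFit:
    model: str  # "linear" | "quadratic"
    a: float
    b: float
    c: float
    rss: float
    n: int
    k: int
    bic: float


@dataclass
class AgeCategory:
    category: int  # 1..6
    is_young: bool


def pairwise_identities(
    reads: list[tuple[str, str]],
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    use_prefilter: bool = True,
) -> np.ndarray:
    """Identity of the best accepted overlap for every unordered read pair.

    Uses the same overlap-acceptance criteria as read clustering; self pairs
    are excluded and pairs with no acceptable overlap are omitted.
    """
    if len(reads) < 2:
        raise ValueError("insufficient pairs: need >= 2 reads")
    if use_prefilter:
        cand = candidate_pairs([encode(seq) for _, seq in reads])
    else:
        n = len(reads)
        cand = {(i, j): (True, True) for i in range(n) for j in range(i + 1, n)}
    out = []
    for (i, j), (same, rev) in sorted(cand.items()):
        orients = tuple(o for o, f in (("same", same), ("reverse", rev)) if f)
        hit = pairwise_overlap(
            reads[i], reads[j],
            min_overlap_frac=min_overlap_frac,
            min_identity=min_identity,
            orientations=orients,
        )
        if hit is not None:
            out.append(hit.identity)
    return np.sort(np.array(out, dtype=float))


def build_identity_histogram(
    identities: np.ndarray | list[float],
    lo: float = 0.90,
    hi: float = 1.00,
    bin_width: float = DEFAULT_BIN_WIDTH,
    cluster_id: str = "",
) -> IdentityHistogram:
    """Left-closed right-open bins on [lo, hi], last bin closed; Y sums to 1."""
    identities = np.asarray(identities, dtype=float)
    if identities.size == 0:
        raise ValueError("no identities to bin")
    nbins = round((hi - lo) / bin_width)
    edges = lo + np.arange(nbins + 1) * bin_width
    edges[-1] = hi
    inside = identities[(identities >= lo) & (identities <= hi)]
    if inside.size == 0:
        raise ValueError("no identities inside the histogram window")
    counts, _ = np.histogram(inside, bins=edges)
    y = counts / counts.sum()
    return IdentityHistogram(cluster_id, edges, y, int(inside.size))


def _ols_fit(X: np.ndarray, y: np.ndarray, degree: int) -> RegressionFit:
    design = np.vander(X, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = max(float(resid @ resid), _RSS_FLOOR)
    n = len(y)
    k = degree + 1
    bic = n * np.log(rss / n) + k * np.log(n)
    a, b = float(coef[0]), float(coef[1])
    c = float(coef[2]) if degree == 2 else 0.0
    return RegressionFit(
        model="linear" if degree == 1 else "quadratic",
        a=a, b=b, c=c, rss=rss, n=n, k=k, bic=float(bic),
    )


def fit_models(h: IdentityHistogram) -> tuple[RegressionFit, RegressionFit]:
    """OLS linear and quadratic fits of Y on bin midpoints (all bins)."""
    X = h.midpoints
    y = h.y
    if len(X) < 4:
        raise ValueError("insufficient bins: need >= 4")
    return _ols_fit(X, y, 1), _ols_fit(X, y, 2)


def classify(
    linear_fit: RegressionFit,
    quadratic_fit: RegressionFit,
    b_tol: float = DEFAULT_B_TOL,
    optimum_cut: float = DEFAULT_OPTIMUM_CUT,
) -> AgeCategory:
    """Apply the six-category shape rules to the BIC-selected model."""
    use_linear = linear_fit.bic <= quadratic_fit.bic + _BIC_TIE
    if not use_linear and quadratic_fit.c == 0.0:
        # degenerate quadratic: interpret with the linear rules
        use_linear = True
        linear_fit = RegressionFit(
            "linear", quadratic_fit.a, quadratic_fit.b, 0.0,
            quadratic_fit.rss, quadratic_fit.n, 2, quadratic_fit.bic,
        )
    if use_linear:
        b = linear_fit.b
        if b > b_tol:
            category = 1
        elif b < -b_tol:
            category = 3
        else:
            category = 2
    else:
        c = quadratic_fit.c
        if c > 0:
            category = 4
        else:
            optimum = -quadratic_fit.b / (2.0 * c)
            category = 6 if optimum > optimum_cut else 5
    return AgeCategory(category, category in YOUNG_CATEGORIES)


def classify_identities(
    identities: np.ndarray | list[float],
    bin_width: float = DEFAULT_BIN_WIDTH,
    b_tol: float = DEFAULT_B_TOL,
    optimum_cut: float = DEFAULT_OPTIMUM_CUT,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> AgeCategory | None:
    """Histogram + fits + classification; None if fewer than min_pairs identities."""
    identities = np.asarray(identities, dtype=float)
    identities = identities[(identities >= 0.90) & (identities <= 1.00)]
    if identities.size < min_pairs:
        return None
    h = build_identity_histogram(identities, bin_width=bin_width)
    lin, quad = fit_models(h)
    return classify(lin, quad, b_tol=b_tol, optimum_cut=optimum_cut)


def young_fraction(categories: list[int]) -> float:
    """Percent of classified clusters in the young categories {1, 4, 6}."""
    if not categories:
        raise ValueError("no classified clusters")
    young = sum(1 for c in categories if c in YOUNG_CATEGORIES)
    return 100.0 * young / len(categories)
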