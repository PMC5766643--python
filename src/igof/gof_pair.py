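"""Per-pair contingency structures and the Pearson goodness-of-fit statistic.

For two biallelic variants (alleles A/a and B/b, lowercase = minor) there are
nine two-locus genotype categories, laid out row-major::

    index   0     1     2     3     4     5     6     7     8
    cat   AABB  AABb  AAbb  AaBB  AaBb  Aabb  aaBB  aaBb  aabb

i.e. category ``3*a + b`` where ``a`` and ``b`` are the minor-allele counts
(0, 1, 2) at the first and second variant.  Cases and controls are tallied
separately; the goodness-of-fit statistic compares each group's observed
category counts with the expectation under the pooled category frequencies,
so it is sensitive to both main effects and interaction effects and makes no
linkage-equilibrium assumption between the two variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

__all__ = [
    "CATEGORY_LABELS",
    "PairTable",
    "AlleleTable",
    "GofResult",
    "build_pair_table",
    "expected_counts",
    "classify_pair",
    "gof_statistic",
    "allele_table",
]

CATEGORY_LABELS = (
    "AABB", "AABb", "AAbb",
    "AaBB", "AaBb", "Aabb",
    "aaBB", "aaBb", "aabb",
)

#: expected-count threshold separating common from low-frequency variant pairs
MIN_EXPECTED_COMMON = 5.0

#: degrees of freedom of the asymptotic null of C^2 for a full 3x3 table
COMMON_DF = 8


@dataclass(frozen=True)
class PairTable:
    """Case/control genotype counts for one variant pair.

    ``n`` and ``m`` are the nine case and control category counts in the
    canonical order above; ``N`` and ``M`` are the group totals.
    """

    n: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.n, dtype=np.int64)
        m = np.asarray(self.m, dtype=np.int64)
        if n.shape != (9,) or m.shape != (9,):
            raise ValueError("PairTable requires nine case and nine control counts")
        if (n < 0).any() or (m < 0).any():
            raise ValueError("genotype counts must be non-negative")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "m", m)

    @property
    def N(self) -> int:
        return int(self.n.sum())

    @property
    def M(self) -> int:
        return int(self.m.sum())


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele-pair counts derived from a :class:`PairTable`.

    Entries follow the fast-epistasis construction: each individual
    contributes four alleles for the pair, e.g. an AaBb individual
    contributes one to each of AB, Ab, aB and ab.  Case entries sum to 4N,
    control entries to 4M.
    """

    case: tuple  # (N_AB, N_Ab, N_aB, N_ab)
    control: tuple  # (M_AB, M_Ab, M_aB, M_ab)

    @property
    def n_ab(self) -> int:
        """Doubly-minor allele-pair count in cases."""
        return self.case[3]

    @property
    def m_ab(self) -> int:
        """Doubly-minor allele-pair count in controls."""
        return self.control[3]


@dataclass(frozen=True)
class GofResult:
    """Goodness-of-fit outcome for one variant pair."""

    c2: float
    d: int  # number of categories with pooled frequency > 0
    pair_class: str  # "common" | "LF"
    p_chi2: float | None  # present iff common (8-df chi-square tail)
    expected_n: np.ndarray = field(repr=False)
    expected_m: np.ndarray = field(repr=False)


def build_pair_table(g1, g2, phen) -> PairTable:
    """Tally the nine two-locus genotype categories by affection status.

    ``g1``/``g2`` are per-sample minor-allele counts for the two variants,
    aligned with ``phen``; entries equal to the missing marker (-1) at either
    variant drop that individual from this pair's table (pairwise deletion).
    """
    g1 = np.asarray(g1, dtype=np.int64)
    g2 = np.asarray(g2, dtype=np.int64)
    status = np.asarray(phen.status, dtype=bool)
    if g1.shape != g2.shape or g1.shape != status.shape:
        raise ValueError(
            f"alignment error: genotype vectors of length {g1.shape}/{g2.shape} "
            f"vs {status.shape} phenotypes"
        )
    valid = (g1 >= 0) & (g2 >= 0)
    if ((g1[valid] > 2) | (g2[valid] > 2)).any():
        raise ValueError("non-missing genotype entries must be in {0, 1, 2}")
    cat = 3 * g1[valid] + g2[valid]
    case = status[valid]
    n = np.bincount(cat[case], minlength=9)
    m = np.bincount(cat[~case], minlength=9)
    return PairTable(n=n, m=m)


def expected_counts(t: PairTable):
    """Expected category counts under pooled frequencies.

    ``f_i = (n_i + m_i) / (N + M)``; ``E(n_i) = N f_i``, ``E(m_i) = M f_i``.
    The expectations conserve the group totals exactly.
    """
    total = t.N + t.M
    if total <= 0:
        raise ValueError("degenerate input: table contains no individuals")
    f = (t.n + t.m) / total
    return t.N * f, t.M * f


def classify_pair(t: PairTable) -> str:
    """``"common"`` iff every one of the 18 expected counts is >= 5, else ``"LF"``."""
    e_n, e_m = expected_counts(t)
    min_e = min(e_n.min(), e_m.min())
    return "common" if min_e >= MIN_EXPECTED_COMMON else "LF"


def gof_statistic(t: PairTable) -> GofResult:
    """Pearson goodness-of-fit statistic C^2 for a variant pair.

    The sum runs over categories with pooled frequency > 0 (empty categories
    contribute nothing and are excluded from the degrees-of-freedom count
    ``d``).  For common pairs — which by construction have all nine
    categories populated — the 8-df chi-square survival function supplies
    the per-pair p-value; LF pairs carry no per-pair p-value.
    """
    if t.N < 1 or t.M < 1:
        raise ValueError("gof_statistic requires at least one case and one control")
    e_n, e_m = expected_counts(t)
    nz = (t.n + t.m) > 0
    d = int(nz.sum())
    c2 = float(
        (((t.n[nz] - e_n[nz]) ** 2) / e_n[nz]).sum()
        + (((t.m[nz] - e_m[nz]) ** 2) / e_m[nz]).sum()
    )
    pair_class = classify_pair(t)
    p = float(chi2.sf(c2, COMMON_DF)) if pair_class == "common" else None
    return GofResult(c2=c2, d=d, pair_class=pair_class, p_chi2=p,
                     expected_n=e_n, expected_m=e_m)


# Table-2 coefficients: allele-pair count = 4*double-homozygote + 2*single-het
# neighbours + double-het, per group.  Index order is the canonical category
# layout at the top of the module.
_ALLELE_WEIGHTS = {
    # (cat of 4x, cats of 2x, cat of 1x)
    "AB": (0, (1, 3), 4),
    "Ab": (2, (1, 5), 4),
    "aB": (6, (3, 7), 4),
    "ab": (8, (5, 7), 4),
}


def _allele_counts(x: np.ndarray) -> tuple:
    out = []
    for w4, (w2a, w2b), w1 in _ALLELE_WEIGHTS.values():
        out.append(int(4 * x[w4] + 2 * x[w2a] + 2 * x[w2b] + x[w1]))
    return tuple(out)


def allele_table(t: PairTable) -> AlleleTable:
    """Collapse a :class:`PairTable` to 2x2 allele-pair counts per group."""
    return AlleleTable(case=_allele_counts(t.n), control=_allele_counts(t.m))
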