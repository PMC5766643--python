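"""Gene-pair level interaction tests: IGOF_common, IGOF_LF, IGOF_combined.

For a pair of genes, every between-gene variant pair is tabulated and
classified (common vs low-frequency by the expected-count-of-5 rule):

* IGOF_common — common pairs whose 8-df chi-square p-value falls below the
  truncation threshold tau form the set Omega; the statistic is the sum of
  inverse-normal transforms ``I_common = sum Phi^-1(1 - p_j)`` (oriented so
  larger = stronger evidence).
* IGOF_LF — LF pairs whose doubly-minor allele-pair count is strictly
  larger in cases than in controls form the set Psi; the statistic is the
  plain sum of their C^2 values.
* IGOF_combined — the two component p-values merged with the extended
  Simes rule ``min(2 min(p_c, p_L), max(p_c, p_L))``.

Both component p-values come from label permutations (the whole statistic,
including the re-selection of Omega and Psi, is recomputed from each
shuffled label vector), run adaptively and gated by cheap analytic
screening approximations (see :mod:`igof.pvalue_engine`): ``p_N`` gates the
common branch, ``p_D`` then the Satterthwaite–Welch ``p_SW`` (fitted to
1,000 permuted statistics, which are reused in the subsequent adaptive
run) gate the LF branch.  A branch whose screening p-value misses the
elevated threshold ``m * alpha``, or whose selection set is empty, gets a
p-value of 1 without (further) permutation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import chi2

from . import gof_pair
from .genotypes import MISSING, GeneMap, GenotypeMatrix, Phenotype
from .pvalue_engine import (
    DegenerateNullError,
    approx_p_common,
    approx_p_lf_df,
    satterthwaite_welch,
    two_stage_gate,
)

__all__ = [
    "IgofConfig",
    "IgofResult",
    "select_common_pairs",
    "i_common",
    "select_lf_pairs",
    "i_lf",
    "combine_pvalues",
    "test_gene_pair",
]

_CHUNK = 64
_MIN_P = 1e-300  # clamp for chi-square tails before the normal quantile


@dataclass(frozen=True)
class IgofConfig:
    """Tuning knobs of the gene-pair tests.

    tau: per-pair p-value truncation threshold for common pairs.
    m: screening multiplier; permutations run only when the screening
       p-value is below ``m * alpha``.
    alpha: significance level the (b, r) budget is tuned for.
    b, r: adaptive-permutation budget and exceedance cutoff.
    sw_permutations: permutations used to moment-match p_SW.
    seed: master seed; each gene pair derives its own stream from
          (seed, gene1, gene2) so results do not depend on scan order.
    """

    tau: float = 0.05
    m: float = 10.0
    alpha: float = 0.01
    b: int = 2500
    r: int = 36
    sw_permutations: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.b >= self.r >= 1:
            raise ValueError("require b >= r >= 1")


@dataclass
class IgofResult:
    """Full outcome of one gene-pair test.

    ``p_n``/``p_d``/``p_sw`` are screening quantities only; the reportable
    p-values are ``p_common``, ``p_lf`` and ``p_combined``.
    """

    gene1: str
    gene2: str
    n_common: int
    n_lf: int
    k: int  # |Omega|
    l: int  # |Psi|
    i_common: float  # nan when Omega empty
    i_lf: float  # nan when Psi empty
    p_n: float  # screening; nan when not computed
    p_d: float
    p_sw: float
    p_common: float
    p_lf: float
    p_combined: float
    perms_common: int
    perms_lf: int
    exceed_common: int
    exceed_lf: int

    TSV_COLUMNS = (
        "gene1", "gene2", "n_common", "n_lf", "k", "l",
        "i_common", "i_lf", "screen_p_n", "screen_p_d", "screen_p_sw",
        "p_common", "p_lf", "p_combined",
        "perms_common", "perms_lf", "exceed_common", "exceed_lf",
    )

    def to_row(self) -> list:
        def fmt(x):
            if isinstance(x, float):
                return "NA" if np.isnan(x) else format(x, ".6g")
            return str(x)

        return [fmt(v) for v in (
            self.gene1, self.gene2, self.n_common, self.n_lf, self.k, self.l,
            self.i_common, self.i_lf, self.p_n, self.p_d, self.p_sw,
            self.p_common, self.p_lf, self.p_combined,
            self.perms_common, self.perms_lf,
            self.exceed_common, self.exceed_lf,
        )]


# ------------------------------------------------------------ building blocks

def select_common_pairs(results, tau: float):
    """Indices of common-pair results with p-value strictly below tau."""
    out = []
    for j, res in enumerate(results):
        if res.p_chi2 is None:
            raise ValueError(f"result {j} carries no chi-square p-value")
        if res.p_chi2 < tau:
            out.append(j)
    return out


def i_common(selected_pvalues) -> float:
    """``I_common = sum_j Phi^-1(1 - p_j)`` over the truncated set.

    Oriented so that smaller p-values contribute larger positive terms;
    an empty selection is signalled to the caller (p_common is then 1
    without permutation).
    """
    p = np.asarray(list(selected_pvalues), dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty selection: no common pairs passed tau")
    return float(-ndtri(np.clip(p, _MIN_P, 1.0)).sum())


def select_lf_pairs(case_tables, control_tables=None):
    """Indices of LF pairs with strictly more doubly-minor allele pairs in
    cases than controls (ties excluded).

    Accepts either a list of :class:`~igof.gof_pair.AlleleTable` or two
    parallel lists of case/control count 4-tuples.
    """
    out = []
    if control_tables is None:
        for j, at in enumerate(case_tables):
            if at.n_ab > at.m_ab:
                out.append(j)
    else:
        for j, (ct, mt) in enumerate(zip(case_tables, control_tables)):
            if ct[3] > mt[3]:
                out.append(j)
    return out


def i_lf(selected_c2) -> float:
    """``I_LF = sum_j C^2_j`` over the selected LF pairs."""
    c2 = np.asarray(list(selected_c2), dtype=np.float64)
    if c2.size == 0:
        raise ValueError("empty selection: no LF pairs selected")
    return float(c2.sum())


def combine_pvalues(p_common: float, p_lf: float) -> float:
    """Extended Simes combination of the two component p-values."""
    for p in (p_common, p_lf):
        if not 0 < p <= 1:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    return min(2.0 * min(p_common, p_lf), max(p_common, p_lf))


# ------------------------------------------------------------- fast evaluator

class _FastEvaluator:
    """Vectorised between-gene pair statistics without missing genotypes.

    All label-independent structure is precomputed once: pooled category
    totals, expected counts, and the common/LF classification (invariant
    under label permutation because pooled frequencies and the group sizes
    are).  Each individual's non-reference genotype combinations are
    encoded as a sparse event matrix mapping individuals to contingency
    cells, so the case counts for a whole chunk of permuted label vectors
    come from a single dense-sparse product; the goodness-of-fit statistic
    is then accumulated category by category as a quadratic in the case
    counts (the control counts are the fixed totals minus the case
    counts, so they never need materialising).
    """

    def __init__(self, G1: np.ndarray, G2: np.ndarray, labels: np.ndarray,
                 tau: float):
        from scipy import sparse

        G1 = np.ascontiguousarray(G1, dtype=np.int8)
        G2 = np.ascontiguousarray(G2, dtype=np.int8)
        if (G1 == MISSING).any() or (G2 == MISSING).any():
            raise ValueError("fast path requires complete genotypes")
        self.ns, self.v1 = G1.shape
        self.v2 = G2.shape[1]
        self.P = self.v1 * self.v2
        self.labels = np.asarray(labels, dtype=bool)
        self.N = int(self.labels.sum())
        self.M = self.ns - self.N

        # --- sparse event matrix ---------------------------------------------
        # column blocks: [4*P quadrant cells (a,b in {1,2}^2) | g1 margins |
        # g2 margins]; entry (individual, code) counts that individual's
        # contributions to the cell.
        r1, c1 = np.nonzero(G1)
        a1 = G1[r1, c1].astype(np.int64)
        r2, c2 = np.nonzero(G2)
        a2 = G2[r2, c2].astype(np.int64)
        k2 = np.bincount(r2, minlength=self.ns)
        starts2 = np.concatenate(([0], np.cumsum(k2)[:-1]))
        reps = k2[r1]
        left = np.repeat(np.arange(r1.size), reps)
        block_start = np.concatenate(([0], np.cumsum(reps)))[:-1]
        within = np.arange(int(reps.sum())) - np.repeat(block_start, reps)
        right = starts2[r1[left]] + within
        pair = c1[left] * self.v2 + c2[right]
        ab = (a1[left] - 1) * 2 + (a2[right] - 1)
        pair_code = ab * self.P + pair
        m1_code = 4 * self.P + (a1 - 1) * self.v1 + c1
        m2_code = 4 * self.P + 2 * self.v1 + (a2 - 1) * self.v2 + c2
        ev_ind = np.concatenate([r1[left], r1, r2])
        ev_code = np.concatenate([pair_code, m1_code, m2_code])
        self.ncols = 4 * self.P + 2 * self.v1 + 2 * self.v2
        self.events = sparse.csr_matrix(
            (np.ones(ev_code.size, dtype=np.float32), (ev_ind, ev_code)),
            shape=(self.ns, self.ncols),
        )

        # --- pooled totals and label-invariant coefficients ------------------
        tot_cols = np.asarray(self.events.sum(axis=0)).ravel().astype(np.float64)
        sh = (self.v1, self.v2)
        T4 = tot_cols[: 4 * self.P].reshape(4, *sh)
        TR = tot_cols[4 * self.P: 4 * self.P + 2 * self.v1].reshape(2, self.v1)
        TC = tot_cols[4 * self.P + 2 * self.v1:].reshape(2, self.v2)
        tot9 = np.empty((9, *sh))
        tot9[4], tot9[5], tot9[7], tot9[8] = T4
        tot9[3] = TR[0][:, None] - T4[0] - T4[1]
        tot9[6] = TR[1][:, None] - T4[2] - T4[3]
        tot9[1] = TC[0][None, :] - T4[0] - T4[2]
        tot9[2] = TC[1][None, :] - T4[1] - T4[3]
        tot9[0] = self.ns - tot9[1:].sum(axis=0)
        self.tot9 = tot9

        f = tot9 / self.ns
        En = self.N * f
        Em = self.M * f
        self.d = (tot9 > 0).sum(axis=0).reshape(self.P)
        min_e = np.minimum(En, Em).min(axis=0).reshape(self.P)
        self.common_mask = min_e >= gof_pair.MIN_EXPECTED_COMMON
        self.n_common = int(self.common_mask.sum())
        self.n_lf = self.P - self.n_common
        self.lf_mask3 = (~self.common_mask).reshape(sh)
        self.common_idx = np.nonzero(self.common_mask)[0]

        # C^2 per category is quadratic in the case count x:
        #   (x-En)^2/En + ((tot-x)-Em)^2/Em = A x^2 - B x + const
        # with A = 1/En + 1/Em, B = 2(1 + (tot-Em)/Em), const = En + (tot-Em)^2/Em
        # (empty categories contribute zero: A = B = const = 0).
        nz = tot9 > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            iEn = np.where(nz, 1.0 / np.where(nz, En, 1.0), 0.0)
            iEm = np.where(nz, 1.0 / np.where(nz, Em, 1.0), 0.0)
        Bm = tot9 - Em
        self.coefA = (iEn + iEm).astype(np.float32)
        self.coefB = (2.0 * (nz + Bm * iEm)).astype(np.float32)
        self.const0 = (En + Bm * Bm * iEm).sum(axis=0).astype(np.float32)
        self.Tab = (4 * tot9[8] + 2 * tot9[5] + 2 * tot9[7]
                    + tot9[4]).astype(np.float32)
        self.c2_tau = float(chi2.isf(tau, gof_pair.COMMON_DF))

    def _chunk_c2(self, S: np.ndarray):
        """(C^2, case N_ab) per pair for each label row: ((c,v1,v2) x2)."""
        cnt = S.astype(np.float32) @ self.events  # (c, ncols)
        cnt = np.asarray(cnt)
        c = S.shape[0]
        sh = (c, self.v1, self.v2)
        K = cnt[:, : 4 * self.P].reshape(c, 4, self.v1, self.v2)
        R = cnt[:, 4 * self.P: 4 * self.P + 2 * self.v1].reshape(c, 2, self.v1)
        C = cnt[:, 4 * self.P + 2 * self.v1:].reshape(c, 2, self.v2)
        n4, n5, n7, n8 = K[:, 0], K[:, 1], K[:, 2], K[:, 3]
        n3 = R[:, 0][:, :, None] - n4 - n5
        n6 = R[:, 1][:, :, None] - n7 - n8
        n1 = C[:, 0][:, None, :] - n4 - n7
        n2 = C[:, 1][:, None, :] - n5 - n8
        n0 = np.float32(self.N) - (n1 + n2 + n3 + n4 + n5 + n6 + n7 + n8)
        c2 = np.broadcast_to(self.const0, sh).copy()
        for cat, x in enumerate((n0, n1, n2, n3, n4, n5, n6, n7, n8)):
            c2 += x * (self.coefA[cat] * x - self.coefB[cat])
        nab = 4.0 * n8 + 2.0 * n5 + 2.0 * n7 + n4
        return c2, nab

    def _i_common_rows(self, c2flat: np.ndarray) -> np.ndarray:
        """I_common per row from flattened (c, P) statistics."""
        ic = np.zeros(c2flat.shape[0])
        if self.common_idx.size:
            c2c = c2flat[:, self.common_idx]
            sel = c2c > self.c2_tau
            if sel.any():
                rows, cols = np.nonzero(sel)
                p = np.clip(
                    chi2.sf(c2c[rows, cols].astype(np.float64),
                            gof_pair.COMMON_DF), _MIN_P, 1.0)
                np.add.at(ic, rows, -ndtri(p))
        return ic

    def perm_stats(self, S, need_common=True, need_lf=True):
        """(I_common, I_LF) per label row, with full re-selection."""
        c2, nab = self._chunk_c2(np.asarray(S, dtype=bool))
        ic = il = None
        if need_common:
            ic = self._i_common_rows(c2.reshape(S.shape[0], self.P))
        if need_lf:
            psi = (2.0 * nab > self.Tab) & self.lf_mask3
            il = (c2 * psi).sum(axis=(1, 2)).astype(np.float64)
        return ic, il

    def observed(self):
        c2, nab = self._chunk_c2(self.labels[None, :])
        c2flat = c2.reshape(1, self.P)
        k = 0
        i_common_obs = np.nan
        if self.common_idx.size:
            c2c = c2flat[0, self.common_idx]
            sel = c2c > self.c2_tau
            k = int(sel.sum())
            if k:
                p = np.clip(chi2.sf(c2c[sel].astype(np.float64),
                                    gof_pair.COMMON_DF), _MIN_P, 1.0)
                i_common_obs = float(-ndtri(p).sum())
        psi = ((2.0 * nab > self.Tab) & self.lf_mask3)[0]
        l = int(psi.sum())
        i_lf_obs = float(c2[0][psi].sum()) if l else np.nan
        sum_d = int(self.d.reshape(self.v1, self.v2)[psi].sum()) if l else 0
        return dict(i_common=i_common_obs, k=k, i_lf=i_lf_obs, l=l,
                    sum_d=sum_d, n_common=self.n_common, n_lf=self.n_lf)


# -------------------------------------------------------- reference evaluator

class _ReferenceEvaluator:
    """Plain per-pair implementation; handles missing genotypes.

    Individuals missing at either variant of a pair are dropped from that
    pair's table only (pairwise deletion), so the classification and the
    expected counts are re-derived for every permutation — with
    missingness they depend on which labels land on the complete cases.
    """

    def __init__(self, G1, G2, labels, tau):
        self.G1 = np.asarray(G1, dtype=np.int8)
        self.G2 = np.asarray(G2, dtype=np.int8)
        self.labels = np.asarray(labels, dtype=bool)
        self.tau = tau
        self.pairs = [(i, j) for i in range(self.G1.shape[1])
                      for j in range(self.G2.shape[1])]
        # pooled classification for reporting (observed labels)
        stats = self._pair_stats(self.labels)
        self.n_common = sum(1 for s in stats if s["class"] == "common")
        self.n_lf = len(stats) - self.n_common

    def _pair_stats(self, status):
        phen = _StatusView(status)
        out = []
        for i, j in self.pairs:
            t = gof_pair.build_pair_table(self.G1[:, i], self.G2[:, j], phen)
            if t.N < 1 or t.M < 1:
                raise ValueError(
                    f"variant pair ({i},{j}) leaves no usable cases/controls"
                )
            res = gof_pair.gof_statistic(t)
            at = gof_pair.allele_table(t)
            out.append({"class": res.pair_class, "c2": res.c2, "d": res.d,
                        "p": res.p_chi2, "n_ab": at.n_ab, "m_ab": at.m_ab})
        return out

    def _stats_from(self, status):
        stats = self._pair_stats(status)
        zs = [-float(ndtri(max(s["p"], _MIN_P)))
              for s in stats if s["class"] == "common" and s["p"] < self.tau]
        ic = float(np.sum(zs)) if zs else 0.0
        lf_sel = [s for s in stats
                  if s["class"] == "LF" and s["n_ab"] > s["m_ab"]]
        il = float(np.sum([s["c2"] for s in lf_sel])) if lf_sel else 0.0
        return stats, zs, lf_sel, ic, il

    def perm_stats(self, S, need_common=True, need_lf=True):
        ic = np.zeros(S.shape[0])
        il = np.zeros(S.shape[0])
        for idx in range(S.shape[0]):
            _, _, _, a, b = self._stats_from(S[idx])
            ic[idx] = a
            il[idx] = b
        return (ic if need_common else None), (il if need_lf else None)

    def observed(self):
        stats, zs, lf_sel, ic, il = self._stats_from(self.labels)
        k = len(zs)
        l = len(lf_sel)
        return dict(
            i_common=ic if k else np.nan, k=k,
            i_lf=il if l else np.nan, l=l,
            sum_d=int(np.sum([s["d"] for s in lf_sel])) if l else 0,
            n_common=self.n_common, n_lf=self.n_lf,
        )


class _StatusView:
    """Minimal phenotype stand-in carrying only the status vector."""

    def __init__(self, status):
        self.status = np.asarray(status, dtype=bool)


# ------------------------------------------------------------- orchestration

def _branch_scan(exceed: np.ndarray, R: int, base_B: int, r: int):
    """Advance one branch through a chunk of exceedance flags.

    Returns (new_R, stop_B or None): stop_B is the permutation index at
    which the r-th exceedance occurred.
    """
    cum = R + np.cumsum(exceed)
    hit = np.nonzero(cum >= r)[0]
    if hit.size:
        return r, base_B + int(hit[0]) + 1
    return int(cum[-1]) if exceed.size else R, None


def _run_gene_pair(ev, labels, cfg: IgofConfig, rng, gene1, gene2) -> IgofResult:
    obs = ev.observed()
    n_common, n_lf = obs["n_common"], obs["n_lf"]
    k, l = obs["k"], obs["l"]

    p_n = p_d = p_sw = np.nan
    p_common = p_lf = 1.0
    perms_c = perms_l = 0
    Rc = Rl = 0

    common_active = False
    if k >= 1:
        p_n = approx_p_common(obs["i_common"], n_common, k)
        common_active = two_stage_gate(p_n, cfg.m, cfg.alpha)

    lf_active = False
    if l >= 1:
        p_d = approx_p_lf_df(obs["i_lf"], max(obs["sum_d"], 1))
        lf_active = two_stage_gate(p_d, cfg.m, cfg.alpha)

    n_sw = min(cfg.sw_permutations, cfg.b)
    sw_draws = np.empty(n_sw) if lf_active else None
    lf_phase = "sw" if lf_active else None
    lf_hit_B = None

    labels = np.asarray(labels, dtype=bool)
    B = 0
    common_done_p = None
    lf_done_p = None
    while common_active or lf_active:
        c = min(_CHUNK, cfg.b - B)
        if c <= 0:
            break
        S = rng.permuted(np.tile(labels, (c, 1)), axis=1)
        ic, il = ev.perm_stats(S, need_common=common_active,
                               need_lf=lf_active)
        if common_active:
            Rc, stop = _branch_scan(ic > obs["i_common"], Rc, B, cfg.r)
            if stop is not None:
                common_done_p = cfg.r / stop
                perms_c = stop
                common_active = False
            elif B + c >= cfg.b:
                common_done_p = (Rc + 1) / (cfg.b + 1)
                perms_c = cfg.b
                common_active = False
            else:
                perms_c = B + c
        if lf_active:
            exceed = il > obs["i_lf"]
            if lf_phase == "sw":
                take = min(c, n_sw - B)
                sw_draws[B:B + take] = il[:take]
                if lf_hit_B is None:
                    Rl, stop = _branch_scan(exceed[:take], Rl, B, cfg.r)
                    lf_hit_B = stop
                if B + take >= n_sw:
                    perms_l = n_sw
                    try:
                        p_sw = satterthwaite_welch(obs["i_lf"], sw_draws)
                        proceed = two_stage_gate(p_sw, cfg.m, cfg.alpha)
                    except DegenerateNullError:
                        proceed = True  # fall back to plain permutation
                    if not proceed:
                        lf_done_p = 1.0
                        lf_active = False
                    elif lf_hit_B is not None:
                        lf_done_p = cfg.r / lf_hit_B
                        perms_l = lf_hit_B
                        lf_active = False
                    elif n_sw >= cfg.b:
                        lf_done_p = (Rl + 1) / (cfg.b + 1)
                        perms_l = cfg.b
                        lf_active = False
                    else:
                        lf_phase = "adaptive"
                        # exceedances in the remainder of this chunk count
                        rest = exceed[take:]
                        if rest.size:
                            Rl, stop = _branch_scan(rest, Rl, n_sw, cfg.r)
                            if stop is not None:
                                lf_done_p = cfg.r / stop
                                perms_l = stop
                                lf_active = False
                            else:
                                perms_l = B + c
            else:
                Rl, stop = _branch_scan(exceed, Rl, B, cfg.r)
                if stop is not None:
                    lf_done_p = cfg.r / stop
                    perms_l = stop
                    lf_active = False
                else:
                    perms_l = B + c
            if lf_active and B + c >= cfg.b:
                lf_done_p = (Rl + 1) / (cfg.b + 1)
                perms_l = cfg.b
                lf_active = False
        B += c

    if k >= 1 and common_done_p is not None:
        p_common = common_done_p
    if l >= 1 and lf_done_p is not None:
        p_lf = lf_done_p

    return IgofResult(
        gene1=gene1, gene2=gene2, n_common=n_common, n_lf=n_lf, k=k, l=l,
        i_common=obs["i_common"], i_lf=obs["i_lf"],
        p_n=p_n, p_d=p_d, p_sw=p_sw,
        p_common=p_common, p_lf=p_lf,
        p_combined=combine_pvalues(p_common, p_lf),
        perms_common=perms_c, perms_lf=perms_l,
        exceed_common=Rc, exceed_lf=Rl,
    )


def _pair_rng(seed: int, gene1: str, gene2: str) -> np.random.Generator:
    """Per-pair generator derived from (seed, gene1, gene2)."""
    entropy = (int(seed), zlib.crc32(str(gene1).encode()),
               zlib.crc32(str(gene2).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def test_gene_pair(geno: GenotypeMatrix, phen: Phenotype, gene_map: GeneMap,
                   gene1: str, gene2: str, cfg: IgofConfig | None = None,
                   ) -> IgofResult:
    """Run the three IGOF tests for one gene pair.

    Builds all between-gene variant-pair tables, classifies them, computes
    the observed statistics, screens, and permutes adaptively where gated.
    Uses the vectorised engine when the two genes' genotypes are complete,
    and the per-pair reference engine (with pairwise deletion) otherwise.
    """
    cfg = cfg or IgofConfig()
    for g in (gene1, gene2):
        if g not in gene_map:
            raise KeyError(f"gene {g!r} not present in the gene map")
        if not gene_map[g]:
            raise ValueError(f"gene {g!r} has zero usable variants")
    G1 = geno.columns(gene_map[gene1])
    G2 = geno.columns(gene_map[gene2])
    labels = phen.status
    if (G1 == MISSING).any() or (G2 == MISSING).any():
        ev = _ReferenceEvaluator(G1, G2, labels, cfg.tau)
    else:
        ev = _FastEvaluator(G1, G2, labels, cfg.tau)
    rng = _pair_rng(cfg.seed, gene1, gene2)
    return _run_gene_pair(ev, labels, cfg, rng, gene1, gene2)
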