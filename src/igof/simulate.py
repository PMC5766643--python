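"""Self-contained case-control epistasis simulator.

Replaces the external haplotype/phenotype simulation chain with three
pieces:

* a haplotype-pool generator producing ~10,000 haplotypes per region with
  a heavily rare-skewed frequency spectrum (by default ~80% of sites with
  MAF < 1%) and optional distance-decaying linkage disequilibrium.
  Haplotypes are drawn from a Gaussian-copula latent field: each
  haplotype's latent vector follows an AR(1) process across sites and a
  site carries the minor allele when the latent value falls below the
  site-specific normal quantile of its target frequency.  This keeps the
  per-site frequency marginals exact for arbitrarily rare variants while
  the latent autocorrelation tunes LD ("strong"/"weak"/"none").
* logistic penetrance models: a baseline-only null, additive
  main+interaction models on minor-allele counts, coded two-locus
  interaction models (additive / XOR / classical epistasis / the
  "color" model), and explicit penetrance-table lookups for pure
  epistasis scenarios.  The baseline is solved so the population
  prevalence matches the target (5% by default).
* case-control rejection sampling, with optional population
  stratification (multiple diverged pools combined with fixed
  per-population case/control allocations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtri

from .genotypes import GenotypeMatrix, Phenotype

__all__ = [
    "MafSpectrum",
    "HaplotypePool",
    "PenetranceModel",
    "SimScenario",
    "generate_haplotype_pool",
    "sample_genotypes",
    "interaction_coding",
    "lf_effect_size",
    "penetrance",
    "calibrate_alpha0",
    "sample_case_control",
    "stratified_sample",
    "power_pair_class",
    "read_penetrance_table",
    "write_penetrance_table",
    "ScenarioSampler",
]

LD_RHO = {"none": 0.0, "weak": 0.90, "strong": 0.98}

#: two-locus interaction codings, indexed by (minor count at i, at j)
CODING_TABLES = {
    "additive": np.array([[0, 0, 0], [0, 1, 2], [0, 2, 4]], dtype=np.float64),
    "xor": np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.float64),
    "classical": np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=np.float64),
    "color": np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=np.float64),
}


@dataclass(frozen=True)
class MafSpectrum:
    """Rare-skewed site-frequency spectrum.

    A site is "rare" (target MAF below ``rare_cut``) with probability
    ``rare_fraction``, matching deep-resequencing regions where most
    discovered variants are rare.  Within the rare band the frequency is
    ``min_maf * (rare_cut/min_maf)^(u^rare_shape)`` for uniform ``u``:
    ``rare_shape`` = 1 is log-uniform (a neutral 1/f spectrum) and larger
    values skew further towards near-singletons, as population growth
    does; the default 2.5 makes roughly half the rare sites
    sub-10^-3.5, which also reproduces the observed share of
    low-frequency variant pairs whose doubly-minor allele counts break
    ties between cases and controls (~5-8%).  The common band is
    log-uniform on [rare_cut, max_maf].
    """

    rare_fraction: float = 0.8
    min_maf: float = 1e-4  # one copy in a 10,000-haplotype pool
    rare_cut: float = 0.01
    max_maf: float = 0.5
    rare_shape: float = 2.5

    def draw(self, n_sites: int, rng: np.random.Generator) -> np.ndarray:
        rare = rng.random(n_sites) < self.rare_fraction
        u = rng.random(n_sites)
        log_rare = np.exp(math.log(self.min_maf)
                          + u ** self.rare_shape
                          * math.log(self.rare_cut / self.min_maf))
        log_common = np.exp(math.log(self.rare_cut)
                            + u * math.log(self.max_maf / self.rare_cut))
        return np.where(rare, log_rare, log_common)


@dataclass
class HaplotypePool:
    """Binary haplotype matrix (haplotype x site) with realized MAFs."""

    haplotypes: np.ndarray  # uint8
    mafs: np.ndarray  # realized pool minor-allele frequency per site
    region: str = "region1"

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def subset(self, sites) -> "HaplotypePool":
        sites = np.asarray(sites)
        return HaplotypePool(haplotypes=self.haplotypes[:, sites],
                             mafs=self.mafs[sites], region=self.region)


def generate_haplotype_pool(n_sites: int, n_haplotypes: int = 10_000,
                            maf_spectrum: MafSpectrum | None = None,
                            ld_profile: str | float = "none",
                            seed=None, region: str = "region1",
                            ) -> HaplotypePool:
    """Generate one region's haplotype pool.

    ``ld_profile`` is one of ``"none"``/``"weak"``/``"strong"`` or a float
    giving the per-adjacent-site latent autocorrelation directly.
    """
    if n_sites < 1 or n_haplotypes < 2:
        raise ValueError("need n_sites >= 1 and n_haplotypes >= 2")
    spectrum = maf_spectrum or MafSpectrum()
    rho = LD_RHO[ld_profile] if isinstance(ld_profile, str) else float(ld_profile)
    rng = np.random.default_rng(seed)
    target = spectrum.draw(n_sites, rng)
    z = rng.standard_normal((n_haplotypes, n_sites))
    if rho > 0.0:
        w = math.sqrt(1.0 - rho * rho)
        for s in range(1, n_sites):
            z[:, s] = rho * z[:, s - 1] + w * z[:, s]
    hap = (z < ndtri(target)).astype(np.uint8)
    freq = hap.mean(axis=0)
    flip = freq > 0.5
    hap[:, flip] = 1 - hap[:, flip]
    freq = np.where(flip, 1.0 - freq, freq)
    return HaplotypePool(haplotypes=hap, mafs=freq, region=region)


def sample_genotypes(pool: HaplotypePool, n_individuals: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Random-mating diploids: two pool haplotypes drawn uniformly with
    replacement per individual; returns the (n x sites) count matrix."""
    if pool.n_haplotypes < 1:
        raise ValueError("empty haplotype pool")
    idx = rng.integers(pool.n_haplotypes, size=(2, n_individuals))
    g = pool.haplotypes[idx[0]] + pool.haplotypes[idx[1]]
    return g.astype(np.int8)


def interaction_coding(g_i, g_j, coding: str):
    """Two-locus interaction covariate x_ij for genotype codes in {0,1,2}."""
    try:
        table = CODING_TABLES[coding]
    except KeyError:
        raise ValueError(f"unknown interaction coding {coding!r}") from None
    g_i = np.asarray(g_i, dtype=np.int64)
    g_j = np.asarray(g_j, dtype=np.int64)
    if ((g_i < 0) | (g_i > 2) | (g_j < 0) | (g_j > 2)).any():
        raise ValueError("genotype codes must lie in {0, 1, 2}")
    return table[g_i, g_j]


def lf_effect_size(maf_i: float, maf_j: float) -> float:
    """Interaction log-odds-ratio for an LF pair: 0.3 |log10(maf_i * maf_j)|."""
    if not (0 < maf_i <= 0.5 and 0 < maf_j <= 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    return 0.3 * abs(math.log10(maf_i * maf_j))


def power_pair_class(maf_p: float, maf_q: float, n_group: int = 1000) -> str:
    """Design-time pair class: LF iff the expected doubly-homozygous-minor
    count ``n_group * p^2 q^2`` is strictly below 5."""
    if not (0 < maf_p <= 0.5 and 0 < maf_q <= 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    if n_group < 1:
        raise ValueError("n_group must be >= 1")
    return "LF" if n_group * (maf_p * maf_q) ** 2 < 5 else "common"


@dataclass
class PenetranceModel:
    """Disease model: logistic main/interaction effects or a lookup table.

    ``main_effects`` is a list of (variant index, log-OR); ``interaction_
    effects`` a list of (i, j, log-OR, coding).  When ``table`` is given
    (a 3^L probability grid over ``table_variants``) the penetrance is a
    direct lookup and the logistic terms are ignored.
    """

    alpha0: float = float(logit(0.05))
    main_effects: list = field(default_factory=list)
    interaction_effects: list = field(default_factory=list)
    table: np.ndarray | None = None
    table_variants: list | None = None

    def linear_predictor(self, geno: np.ndarray) -> np.ndarray:
        """Effect terms (without the baseline) for genotype rows."""
        lp = np.zeros(geno.shape[0])
        for idx, beta in self.main_effects:
            lp += beta * geno[:, idx]
        for i, j, beta, coding in self.interaction_effects:
            lp += beta * interaction_coding(geno[:, i], geno[:, j], coding)
        return lp


def penetrance(geno: np.ndarray, model: PenetranceModel) -> np.ndarray:
    """P(affected | genotype row) for each row of ``geno``."""
    geno = np.atleast_2d(np.asarray(geno))
    if model.table is not None:
        loci = model.table_variants
        if loci is None or len(loci) != model.table.ndim:
            raise ValueError("penetrance table requires matching table_variants")
        sub = geno[:, loci]
        if (sub < 0).any():
            raise ValueError("missing genotype at a causal variant")
        return model.table[tuple(sub[:, c] for c in range(sub.shape[1]))]
    needed = [i for i, _ in model.main_effects]
    needed += [i for i, j, _, _ in model.interaction_effects]
    needed += [j for i, j, _, _ in model.interaction_effects]
    if needed and (geno[:, sorted(set(needed))] < 0).any():
        raise ValueError("missing genotype at a causal variant")
    return expit(model.alpha0 + model.linear_predictor(geno))


def calibrate_alpha0(pool: HaplotypePool, model: PenetranceModel,
                     prevalence: float = 0.05, rng=None,
                     n_mc: int = 20_000, tol: float = 1e-3,
                     ) -> PenetranceModel:
    """Solve the baseline logit so population prevalence hits the target.

    Monte-Carlo: the effect terms are evaluated on ``n_mc`` genotypes drawn
    from the pool and the baseline is root-found so the mean penetrance
    equals ``prevalence`` (within ``tol``, i.e. 0.1 percentage point by
    default).
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if model.table is not None:
        return model  # tables carry their own prevalence
    if not model.main_effects and not model.interaction_effects:
        return replace(model, alpha0=float(logit(prevalence)))
    rng = rng or np.random.default_rng(0)
    g = sample_genotypes(pool, n_mc, rng)
    lp = model.linear_predictor(g)

    def gap(a0):
        return float(expit(a0 + lp).mean() - prevalence)

    centre = float(logit(prevalence))
    a0 = brentq(gap, centre - 25.0, centre + 25.0, xtol=tol / 10.0)
    return replace(model, alpha0=float(a0))


def sample_case_control(pool: HaplotypePool, model: PenetranceModel,
                        n_cases: int, n_controls: int,
                        rng: np.random.Generator,
                        batch: int = 8192, max_draws: int | None = None,
                        ):
    """Rejection-sample a case-control panel from the pool.

    Individuals are drawn, labelled affected with probability equal to
    their penetrance, and accepted until both bins are full.  Returns
    (case genotype rows, control genotype rows) as count matrices.
    """
    if max_draws is None:
        max_draws = 2_000 * (n_cases + n_controls) + 1_000_000
    cases, controls = [], []
    have_ca = have_co = 0
    drawn = 0
    while have_ca < n_cases or have_co < n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case/control sampling did not terminate after {drawn} draws; "
                "penetrance is numerically degenerate for this model"
            )
        g = sample_genotypes(pool, batch, rng)
        drawn += batch
        aff = rng.random(batch) < penetrance(g, model)
        if have_ca < n_cases:
            take = g[aff][: n_cases - have_ca]
            cases.append(take)
            have_ca += take.shape[0]
        if have_co < n_controls:
            take = g[~aff][: n_controls - have_co]
            controls.append(take)
            have_co += take.shape[0]
    return np.concatenate(cases), np.concatenate(controls)


def stratified_sample(pools, proportions, model: PenetranceModel,
                      n_cases: int, n_controls: int,
                      rng: np.random.Generator):
    """Sample from a mixture of diverged pools with fixed allocations.

    Per-population case and control counts are ``round(proportion * n)``
    (largest-remainder rounding), mirroring designs that recruit each
    population's cases and controls in fixed numbers; the IGOF tests do
    not model the resulting structure, which is the point of the
    stratification scenarios.
    """
    proportions = np.asarray(proportions, dtype=np.float64)
    if len(pools) != proportions.size:
        raise ValueError("one proportion per pool required")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    n_sites = {p.n_sites for p in pools}
    if len(n_sites) != 1:
        raise ValueError("pools must share the same site count")

    def allocate(total):
        raw = proportions * total
        base = np.floor(raw).astype(int)
        rem = total - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
        return base

    ca_alloc, co_alloc = allocate(n_cases), allocate(n_controls)
    cases, controls = [], []
    for pool, nc, nm in zip(pools, ca_alloc, co_alloc):
        if nc == 0 and nm == 0:
            continue
        ca, co = sample_case_control(pool, model, int(nc), int(nm), rng)
        cases.append(ca)
        controls.append(co)
    return np.concatenate(cases), np.concatenate(controls)


# ------------------------------------------------------ penetrance table I/O

def _genotype_token(locus: int, count: int) -> str:
    u = chr(ord("A") + locus)
    return (u + u, u + u.lower(), u.lower() + u.lower())[count]


def write_penetrance_table(table: np.ndarray, path) -> None:
    """Write a 3^L penetrance grid: header 'L' then one line per genotype."""
    L = table.ndim
    with open(path, "w") as fh:
        fh.write(f"{L}\n")
        for idx in np.ndindex(*table.shape):
            label = ",".join(_genotype_token(l, c) for l, c in enumerate(idx))
            fh.write(f"{label}\t{table[idx]:.17g}\n")


def read_penetrance_table(path) -> np.ndarray:
    with open(path) as fh:
        L = int(fh.readline().strip())
        table = np.full((3,) * L, np.nan)
        for line in fh:
            line = line.strip()
            if not line:
                continue
            label, prob = line.split("\t")
            idx = []
            for l, tok in enumerate(label.split(",")):
                u = chr(ord("A") + l)
                idx.append({u + u: 0, u + u.lower(): 1,
                            u.lower() + u.lower(): 2}[tok])
            table[tuple(idx)] = float(prob)
    if np.isnan(table).any():
        raise ValueError(f"{path}: penetrance table incomplete")
    if ((table < 0) | (table > 1)).any():
        raise ValueError(f"{path}: penetrance values outside [0, 1]")
    return table


# ------------------------------------------------------------------ scenarios

@dataclass
class SimScenario:
    """One simulation design: sample sizes, regions, LD, disease model.

    ``layout`` controls where the two genes' variants come from:
    ``independent`` (two unlinked regions), ``adjacent`` (first/next
    ``variants_per_gene`` sites of a single region — strong between-gene
    LD when the region has LD) or ``distal`` (first/last sites of one
    region — weak between-gene LD).
    """

    n_cases: int = 1000
    n_controls: int = 1000
    variants_per_gene: int = 50
    region_sites: int = 600
    n_haplotypes: int = 10_000
    ld_profile: str | float = "none"
    layout: str = "independent"
    stratification: tuple | None = None  # population proportions
    model: str = "null"  # null | coded | table
    coding: str | tuple = "additive"
    n_causal_pairs: int = 0
    causal_class: str = "lf"  # lf | common | mixed | any
    beta: float | None = None  # None -> MAF rule (LF) / log(1.25) (common)
    main_effect_beta: float | None = None  # add main effects on causal variants
    mixed_signs: bool = False
    prevalence: float = 0.05
    rare_fraction: float = 0.8
    penetrance_table: np.ndarray | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "SimScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        if "stratification" in raw and raw["stratification"] is not None:
            raw["stratification"] = tuple(raw["stratification"])
        if "coding" in raw and isinstance(raw["coding"], list):
            raw["coding"] = tuple(raw["coding"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {}
        for name in self.__dataclass_fields__:
            val = getattr(self, name)
            if isinstance(val, np.ndarray):
                continue
            if isinstance(val, tuple):
                val = list(val)
            data[name] = val
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class ScenarioSampler:
    """Materialises replicate datasets for a :class:`SimScenario`.

    Haplotype pools are generated once per sampler (they play the role of
    the fixed source population); each replicate draws its own variant
    subsets, causal pairs and case-control panel from seeds derived by
    counter from the scenario seed.
    """

    GENE1, GENE2 = "G1", "G2"

    def __init__(self, scenario: SimScenario):
        self.sc = scenario
        spectrum = MafSpectrum(rare_fraction=scenario.rare_fraction)
        base = np.random.SeedSequence((int(scenario.seed), 0x9001))
        children = base.spawn(4)
        seeds = children[:2]
        if scenario.layout == "independent":
            self.pools = [
                generate_haplotype_pool(scenario.region_sites,
                                        scenario.n_haplotypes, spectrum,
                                        scenario.ld_profile, seeds[0],
                                        region="region1"),
                generate_haplotype_pool(scenario.region_sites,
                                        scenario.n_haplotypes, spectrum,
                                        scenario.ld_profile, seeds[1],
                                        region="region2"),
            ]
        else:
            self.pools = [
                generate_haplotype_pool(scenario.region_sites,
                                        scenario.n_haplotypes, spectrum,
                                        scenario.ld_profile, seeds[0],
                                        region="region1"),
            ]
        self.strat_pools = None
        if scenario.stratification is not None:
            if scenario.layout != "independent":
                raise ValueError("stratification requires independent layout")
            div = children[2].spawn(2)
            self.strat_pools = [
                generate_haplotype_pool(scenario.region_sites,
                                        scenario.n_haplotypes, spectrum,
                                        scenario.ld_profile, div[0],
                                        region="region1"),
                generate_haplotype_pool(scenario.region_sites,
                                        scenario.n_haplotypes, spectrum,
                                        scenario.ld_profile, div[1],
                                        region="region2"),
            ]

    def _needs_causal(self) -> bool:
        return self.sc.model in ("coded", "table")

    def _pick_causal_sites(self, rng):
        """Causal site indices per region, honouring the class rule.

        Causal candidates are restricted to MAF >= 1% (effects on variants
        observable in the sample; the LF/common split is then governed by
        the expected doubly-homozygous-minor count rule).
        """
        sc = self.sc
        if sc.layout != "independent":
            raise ValueError("causal models require the independent layout")
        maf1, maf2 = self.pools[0].mafs, self.pools[1].mafs
        n_group = min(sc.n_cases, sc.n_controls)
        n_causal = sc.n_causal_pairs
        if sc.model == "table":
            L = (sc.penetrance_table.ndim
                 if sc.penetrance_table is not None else 2)
            n_causal = max(n_causal, 1)
        want_list = []
        for t in range(n_causal):
            if sc.causal_class == "mixed":
                want_list.append("LF" if t % 2 == 0 else "common")
            elif sc.causal_class == "any":
                want_list.append("any")  # no class constraint
            else:
                want_list.append({"lf": "LF", "common": "common"}[sc.causal_class])
        cand1 = np.nonzero(maf1 >= 0.01)[0]
        cand2 = np.nonzero(maf2 >= 0.01)[0]
        chosen1, chosen2 = [], []
        for want in want_list:
            found = None
            for _ in range(20_000):
                i = int(cand1[rng.integers(cand1.size)])
                j = int(cand2[rng.integers(cand2.size)])
                if i in chosen1 or j in chosen2:
                    continue
                if want == "any" or \
                        power_pair_class(maf1[i], maf2[j], n_group) == want:
                    found = (i, j)
                    break
            if found is None:
                raise ValueError(
                    f"pool offers no {want} causal pair at this sample size")
            chosen1.append(found[0])
            chosen2.append(found[1])
        return chosen1, chosen2

    def _gene_sites(self, rng, include1=(), include2=()):
        """Variant site draws per gene; causal sites are always included."""
        v = self.sc.variants_per_gene
        if self.sc.layout == "independent":
            def draw(include, n_sites):
                include = list(include)
                if len(include) > v:
                    raise ValueError("more causal sites than variants per gene")
                rest = np.setdiff1d(np.arange(n_sites), include)
                extra = rng.choice(rest, size=v - len(include), replace=False)
                return np.concatenate([include, extra]).astype(np.int64)

            return (draw(include1, self.sc.region_sites),
                    draw(include2, self.sc.region_sites))
        if self.sc.layout == "adjacent":
            if 2 * v > self.sc.region_sites:
                raise ValueError("region too small for adjacent layout")
            return np.arange(v), np.arange(v, 2 * v)
        if self.sc.layout == "distal":
            return np.arange(v), np.arange(self.sc.region_sites - v,
                                           self.sc.region_sites)
        raise ValueError(f"unknown layout {self.sc.layout!r}")

    def _build_model(self, causal1, causal2, rng) -> PenetranceModel:
        """Penetrance model with causal variants at the first gene columns."""
        sc = self.sc
        v = sc.variants_per_gene
        if sc.model == "null":
            return PenetranceModel(alpha0=float(logit(sc.prevalence)))
        if sc.model == "table":
            if sc.penetrance_table is None:
                raise ValueError("table model requires penetrance_table")
            L = sc.penetrance_table.ndim
            half = L - L // 2
            loci = list(range(half)) + list(range(v, v + (L - half)))
            return PenetranceModel(table=sc.penetrance_table,
                                   table_variants=loci[:L])
        if sc.model != "coded":
            raise ValueError(f"unknown model {sc.model!r}")
        maf1 = self.pools[0].mafs
        maf2 = self.pools[1].mafs
        n_group = min(sc.n_cases, sc.n_controls)
        codings = ((sc.coding,) if isinstance(sc.coding, str)
                   else tuple(sc.coding))
        effects = []
        for t, (si, sj) in enumerate(zip(causal1, causal2)):
            if sc.beta is not None:
                beta = float(sc.beta)
            elif power_pair_class(maf1[si], maf2[sj], n_group) == "LF":
                beta = lf_effect_size(float(maf1[si]), float(maf2[sj]))
            else:
                beta = math.log(1.25)
            if sc.mixed_signs and t % 2 == 1:
                beta = -beta
            effects.append((t, v + t, beta, codings[t % len(codings)]))
        mains = []
        if sc.main_effect_beta is not None:
            for i, j, beta, _ in effects:
                sign = 1.0 if beta >= 0 else -1.0
                mains.append((i, sign * sc.main_effect_beta))
                mains.append((j, sign * sc.main_effect_beta))
        return PenetranceModel(main_effects=mains,
                               interaction_effects=effects)

    def replicate(self, rep: int):
        """Dataset for replicate ``rep``: (GenotypeMatrix, Phenotype,
        gene-variant dict, [(gene1, gene2)])."""
        sc = self.sc
        rng = np.random.default_rng(
            np.random.SeedSequence((int(sc.seed), 0xA11CE, int(rep))))
        causal1 = causal2 = ()
        if self._needs_causal():
            causal1, causal2 = self._pick_causal_sites(rng)
        s1, s2 = self._gene_sites(rng, causal1, causal2)
        if sc.layout == "independent":
            sub = [self.pools[0].subset(s1), self.pools[1].subset(s2)]
            joint = HaplotypePool(
                haplotypes=np.concatenate(
                    [sub[0].haplotypes, sub[1].haplotypes], axis=1),
                mafs=np.concatenate([sub[0].mafs, sub[1].mafs]),
                region="joint")
        else:
            sites = np.concatenate([s1, s2])
            joint = self.pools[0].subset(sites)
        model = self._build_model(causal1, causal2, rng)
        model = calibrate_alpha0(joint, model, sc.prevalence, rng)
        if self.strat_pools is not None:
            joint2 = HaplotypePool(
                haplotypes=np.concatenate(
                    [self.strat_pools[0].subset(s1).haplotypes,
                     self.strat_pools[1].subset(s2).haplotypes], axis=1),
                mafs=None, region="joint_pop2")
            joint2.mafs = joint2.haplotypes.mean(axis=0)
            cases, controls = stratified_sample(
                [joint, joint2], sc.stratification, model,
                sc.n_cases, sc.n_controls, rng)
        else:
            cases, controls = sample_case_control(
                joint, model, sc.n_cases, sc.n_controls, rng)
        counts = np.concatenate([cases, controls])
        status = np.zeros(counts.shape[0], dtype=bool)
        status[: cases.shape[0]] = True
        v = sc.variants_per_gene
        variants = [f"g1v{i:04d}" for i in range(v)] \
            + [f"g2v{j:04d}" for j in range(v)]
        samples = [f"s{i:05d}" for i in range(counts.shape[0])]
        geno = GenotypeMatrix(samples=samples, variants=variants, counts=counts)
        phen = Phenotype(samples=samples, status=status)
        gene_map = {self.GENE1: variants[:v], self.GENE2: variants[v:]}
        return geno, phen, gene_map, [(self.GENE1, self.GENE2)]
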