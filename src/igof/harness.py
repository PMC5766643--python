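"""Experiment runners: gene-pair scans, type I error and power studies.

The type1/power runners reproduce the simulation-study workflow: simulate
replicate case-control datasets under a scenario, run the three IGOF
tests on each, and report empirical rejection rates with binomial
confidence intervals, plus the mean fraction of variant pairs passing
the two selection thresholds (the "Prop" diagnostics).
"""

from __future__ import annotations

import json
import logging
import math
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, replace

import numpy as np

from .genotypes import (GeneMap, GenePairList, GenotypeMatrix, Phenotype,
                        write_gene_map, write_pair_list, write_phenotype,
                        write_vcf)
from .igof import IgofConfig, IgofResult, test_gene_pair
from .pvalue_engine import estimate_br
from .simulate import ScenarioSampler, SimScenario

logger = logging.getLogger("igof")

__all__ = [
    "ExperimentReport",
    "nominal_ci",
    "rate_ci",
    "run_type1",
    "run_power",
    "scan",
    "simulate_dataset",
    "sample_null_c2",
]

TESTS = ("igof_common", "igof_lf", "igof_combined")


def nominal_ci(alpha: float, n: int) -> tuple:
    """95% binomial CI around the nominal level at ``n`` replicates."""
    half = 1.96 * math.sqrt(alpha * (1.0 - alpha) / n)
    return (alpha - half, alpha + half)


def rate_ci(rate: float, n: int) -> tuple:
    """95% normal-approximation CI around an empirical rate."""
    half = 1.96 * math.sqrt(max(rate * (1.0 - rate), 0.0) / n)
    return (max(rate - half, 0.0), min(rate + half, 1.0))


@dataclass
class ExperimentReport:
    """Empirical rejection rates of the three tests for one scenario."""

    scenario: str
    kind: str  # "type1" | "power"
    replicates: int
    alpha: float
    rates: dict  # test name -> empirical rate
    ci: dict  # test name -> (lo, hi) around the empirical rate
    nominal_ci: tuple
    mean_omega_prop: float  # mean |Omega| / n_common (replicates with common pairs)
    mean_psi_prop: float  # mean |Psi| / n_lf
    total_permutations: int
    wall_time: float

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "kind": self.kind,
            "replicates": self.replicates,
            "alpha": self.alpha,
            "rates": self.rates,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "nominal_ci": list(self.nominal_ci),
            "mean_omega_prop": self.mean_omega_prop,
            "mean_psi_prop": self.mean_psi_prop,
            "total_permutations": self.total_permutations,
            "wall_time": self.wall_time,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def _default_config(alpha: float, overrides: IgofConfig | None,
                    seed: int) -> IgofConfig:
    if overrides is not None:
        return replace(overrides, alpha=alpha, seed=seed)
    b, r = estimate_br(alpha)
    return IgofConfig(alpha=alpha, b=b, r=r, seed=seed)


def _rep_seed(master: int, rep: int) -> int:
    ss = np.random.SeedSequence((int(master), 0xBEEF, int(rep)))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def _run_experiment(scenario: SimScenario, replicates: int, alpha: float,
                    cfg: IgofConfig | None, kind: str,
                    collect_pvalues: bool = False):
    sampler = ScenarioSampler(scenario)
    t0 = time.time()
    pvals = {t: np.empty(replicates) for t in TESTS}
    omega_props, psi_props = [], []
    total_perms = 0
    results = []
    for rep in range(replicates):
        geno, phen, gene_map, pairs = sampler.replicate(rep)
        rep_cfg = _default_config(alpha, cfg, _rep_seed(scenario.seed, rep))
        res = test_gene_pair(geno, phen, gene_map, pairs[0][0], pairs[0][1],
                             rep_cfg)
        pvals["igof_common"][rep] = res.p_common
        pvals["igof_lf"][rep] = res.p_lf
        pvals["igof_combined"][rep] = res.p_combined
        if res.n_common > 0:
            omega_props.append(res.k / res.n_common)
        if res.n_lf > 0:
            psi_props.append(res.l / res.n_lf)
        total_perms += res.perms_common + res.perms_lf
        if collect_pvalues:
            results.append(res)
        if rep % 200 == 199:
            logger.info("%s: replicate %d/%d (%.1fs elapsed)",
                        kind, rep + 1, replicates, time.time() - t0)
    rates = {t: float((pvals[t] <= alpha).mean()) for t in TESTS}
    report = ExperimentReport(
        scenario=f"{scenario.layout}/{scenario.model}"
                 f"/v{scenario.variants_per_gene}"
                 f"/n{scenario.n_cases}+{scenario.n_controls}",
        kind=kind,
        replicates=replicates,
        alpha=alpha,
        rates=rates,
        ci={t: rate_ci(rates[t], replicates) for t in TESTS},
        nominal_ci=nominal_ci(alpha, replicates),
        mean_omega_prop=float(np.mean(omega_props)) if omega_props else float("nan"),
        mean_psi_prop=float(np.mean(psi_props)) if psi_props else float("nan"),
        total_permutations=total_perms,
        wall_time=time.time() - t0,
    )
    if collect_pvalues:
        return report, results
    return report


def run_type1(scenario: SimScenario, replicates: int = 2000,
              alpha: float = 0.01, cfg: IgofConfig | None = None,
              collect_pvalues: bool = False):
    """Empirical type I error of the three tests under a null scenario."""
    if scenario.model != "null" or scenario.n_causal_pairs:
        raise ValueError("type I error runs require a null scenario")
    return _run_experiment(scenario, replicates, alpha, cfg, "type1",
                           collect_pvalues)


def run_power(scenario: SimScenario, replicates: int = 1000,
              alpha: float = 0.01, cfg: IgofConfig | None = None,
              collect_pvalues: bool = False):
    """Empirical power of the three tests under an alternative scenario."""
    return _run_experiment(scenario, replicates, alpha, cfg, "power",
                           collect_pvalues)


def sample_null_c2(n_datasets: int, maf: float = 0.3, n_cases: int = 500,
                   n_controls: int = 500, seed: int = 0) -> np.ndarray:
    """Null draws of the pairwise goodness-of-fit statistic.

    Each draw simulates two independent Hardy-Weinberg variants at the
    given MAF for ``n_cases + n_controls`` individuals with labels
    independent of genotype, and evaluates the full-table C^2.  Used to
    check the asymptotic chi-square(8) null (mean = 8).
    """
    from .gof_pair import build_pair_table, gof_statistic

    n = n_cases + n_controls
    status = np.zeros(n, dtype=bool)
    status[:n_cases] = True
    phen = Phenotype(samples=[f"s{i}" for i in range(n)], status=status)
    rng = np.random.default_rng(seed)
    out = np.empty(n_datasets)
    for i in range(n_datasets):
        g1 = rng.binomial(2, maf, size=n)
        g2 = rng.binomial(2, maf, size=n)
        out[i] = gof_statistic(build_pair_table(g1, g2, phen)).c2
    return out


# ------------------------------------------------------------------- scanning

def _scan_one(args):
    geno, phen, gene_map, g1, g2, cfg = args
    return test_gene_pair(geno, phen, gene_map, g1, g2, cfg)


def scan(geno: GenotypeMatrix, phen: Phenotype, gene_map: GeneMap,
         pairs: GenePairList, cfg: IgofConfig, out_path,
         resume: bool = True, threads: int = 1) -> list:
    """Test every listed gene pair and write one TSV row per pair.

    The output file doubles as the progress journal: rows already present
    are not recomputed on a resumed run.  Per-pair random streams are
    derived from (seed, gene1, gene2), so parallel and resumed runs
    produce the same rows as a fresh serial run.
    """
    if hasattr(gene_map, "validate"):
        gene_map.validate(geno)
    if hasattr(pairs, "validate"):
        pairs.validate(gene_map)
    if sorted(phen.samples) != sorted(geno.samples):
        raise ValueError("phenotype and genotype sample sets differ")

    done = set()
    header_needed = True
    out_path = str(out_path)
    if resume:
        try:
            with open(out_path) as fh:
                for line in fh:
                    if line.startswith("#") or line.startswith("gene1\t"):
                        header_needed = False
                        continue
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) >= 2:
                        done.add((parts[0], parts[1]))
        except FileNotFoundError:
            pass

    todo = [(g1, g2) for g1, g2 in pairs if (g1, g2) not in done]
    n_pairs = len(pairs)
    results = []
    mode = "a" if done or not header_needed else "w"
    with open(out_path, mode) as fh:
        if header_needed:
            fh.write(f"# igof scan: {n_pairs} gene pairs, alpha={cfg.alpha}, "
                     f"bonferroni_threshold={cfg.alpha / max(n_pairs, 1):.6g}, "
                     f"tau={cfg.tau}, m={cfg.m}, b={cfg.b}, r={cfg.r}, "
                     f"seed={cfg.seed}\n")
            fh.write("\t".join(IgofResult.TSV_COLUMNS) + "\n")
        if threads > 1 and len(todo) > 1:
            jobs = [(geno, phen, gene_map, g1, g2, cfg) for g1, g2 in todo]
            with ProcessPoolExecutor(max_workers=threads) as ex:
                for res in ex.map(_scan_one, jobs):
                    results.append(res)
                    fh.write("\t".join(res.to_row()) + "\n")
                    fh.flush()
                    _log_result(res)
        else:
            for g1, g2 in todo:
                res = test_gene_pair(geno, phen, gene_map, g1, g2, cfg)
                results.append(res)
                fh.write("\t".join(res.to_row()) + "\n")
                fh.flush()
                _log_result(res)
    return results


def _log_result(res: IgofResult) -> None:
    logger.info(
        "pair (%s,%s): n_common=%d n_lf=%d |Omega|=%d |Psi|=%d "
        "screen(p_N=%.3g p_D=%.3g p_SW=%.3g) perms=(%d,%d) p_combined=%.3g",
        res.gene1, res.gene2, res.n_common, res.n_lf, res.k, res.l,
        res.p_n, res.p_d, res.p_sw, res.perms_common, res.perms_lf,
        res.p_combined,
    )


def simulate_dataset(scenario: SimScenario, out_dir, rep: int = 0) -> dict:
    """Write one simulated dataset (VCF, phenotype, gene map, pair list)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    sampler = ScenarioSampler(scenario)
    geno, phen, gene_map, pairs = sampler.replicate(rep)
    tag = f"seed{scenario.seed}_rep{rep}"
    paths = {
        "vcf": os.path.join(out_dir, f"sim_{tag}.vcf"),
        "phenotype": os.path.join(out_dir, f"sim_{tag}.phen.tsv"),
        "gene_map": os.path.join(out_dir, f"sim_{tag}.genes.tsv"),
        "pairs": os.path.join(out_dir, f"sim_{tag}.pairs.tsv"),
        "scenario": os.path.join(out_dir, f"sim_{tag}.scenario.yaml"),
    }
    write_vcf(geno, paths["vcf"])
    write_phenotype(phen, paths["phenotype"])
    write_gene_map(GeneMap(genes=gene_map), paths["gene_map"])
    write_pair_list(GenePairList(pairs=pairs), paths["pairs"])
    scenario.to_yaml(paths["scenario"])
    return paths
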