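"""Genotype matrices, phenotypes, gene maps and gene-pair lists.

In-memory model: a sample-by-variant matrix of minor-allele counts
(0/1/2, ``-1`` = missing), a binary case/control phenotype aligned to the
sample order, a gene -> variants map, and an unordered list of gene pairs
to test.  File dialects are deliberately plain: VCF (via cyvcf2) or a
tab-separated count matrix for genotypes, and two-column TSV for
everything else.

Minor-allele orientation for VCF input is a pure function of the pooled
(case + control) ALT frequency: sites where ALT exceeds 0.5 are flipped
(0 <-> 2) so that counts always refer to the minor allele; an exact tie
keeps ALT as the minor allele.  The TSV dialect is defined as already
minor-oriented and is read back verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "Phenotype",
    "GeneMap",
    "GenePairList",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_vcf",
    "read_phenotype",
    "write_phenotype",
    "read_gene_map",
    "write_gene_map",
    "read_pair_list",
    "write_pair_list",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line/record."""


@dataclass
class GenotypeMatrix:
    """Sample x variant matrix of minor-allele counts."""

    samples: list
    variants: list
    counts: np.ndarray  # int8, shape (n_samples, n_variants), MISSING = -1
    chrom: list | None = None
    pos: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int8)
        ns, nv = self.counts.shape
        if len(self.samples) != ns or len(self.variants) != nv:
            raise ValueError("counts shape does not match sample/variant labels")
        if len(set(self.samples)) != ns:
            raise ValueError("sample identifiers must be unique")
        if len(set(self.variants)) != nv:
            raise ValueError("variant identifiers must be unique")
        bad = (self.counts > 2) | ((self.counts < 0) & (self.counts != MISSING))
        if bad.any():
            raise ValueError("genotype entries must be 0/1/2 or the missing marker")
        self._index = {v: i for i, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def column(self, variant: str) -> np.ndarray:
        try:
            return self.counts[:, self._index[variant]]
        except KeyError:
            raise KeyError(f"unknown variant {variant!r}") from None

    def columns(self, variants) -> np.ndarray:
        idx = [self._index[v] for v in variants]
        return self.counts[:, idx]

    def pooled_maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency over non-missing samples."""
        valid = self.counts != MISSING
        alleles = np.where(valid, self.counts, 0).sum(axis=0)
        denom = 2 * valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.where(denom > 0, alleles / np.maximum(denom, 1), 0.0)
        return np.minimum(freq, 1.0 - freq)


@dataclass
class Phenotype:
    """Binary affection status aligned to a sample order."""

    samples: list
    status: np.ndarray  # bool, True = case

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=bool)
        if len(self.samples) != self.status.size:
            raise ValueError("phenotype labels do not match sample list")
        if self.N < 1 or self.M < 1:
            raise ValueError(
                f"need at least one case and one control (N={self.N}, M={self.M})"
            )

    @property
    def N(self) -> int:
        return int(self.status.sum())

    @property
    def M(self) -> int:
        return int(self.status.size - self.status.sum())


@dataclass
class GeneMap:
    """Gene id -> ordered list of variant identifiers."""

    genes: dict

    def __post_init__(self):
        for g, vs in self.genes.items():
            if not vs:
                raise ValueError(f"gene {g!r} maps to no variants")

    def __getitem__(self, gene):
        return self.genes[gene]

    def __contains__(self, gene):
        return gene in self.genes

    def __iter__(self):
        return iter(self.genes)

    def validate(self, geno: GenotypeMatrix) -> None:
        known = set(geno.variants)
        for g, vs in self.genes.items():
            missing = [v for v in vs if v not in known]
            if missing:
                raise ValueError(
                    f"gene {g!r} references variants absent from the genotype "
                    f"matrix: {missing[:5]}"
                )


@dataclass
class GenePairList:
    """Ordered list of unordered gene pairs; no duplicate pairs."""

    pairs: list

    def __post_init__(self):
        seen = set()
        for g1, g2 in self.pairs:
            key = frozenset((g1, g2))
            if key in seen:
                raise ValueError(f"duplicate unordered gene pair ({g1}, {g2})")
            seen.add(key)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)

    def validate(self, gene_map: GeneMap) -> None:
        for g1, g2 in self.pairs:
            for g in (g1, g2):
                if g not in gene_map:
                    raise ValueError(f"gene pair references unknown gene {g!r}")


# ----------------------------------------------------------------- genotypes

_TSV_MISSING_TOKENS = {"NA", "na", ".", "-1", ""}


def read_genotypes(path, format: str = "auto") -> GenotypeMatrix:
    """Read genotypes from VCF (optionally gzipped) or a TSV count matrix."""
    path = str(path)
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    variants, chrom, pos, cols = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(
                f"non-biallelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={rec.ALT}); split multiallelic sites upstream"
            )
        g = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a = gt[:-1]  # trailing element is phasing
            g[i] = MISSING if any(x < 0 for x in a) else sum(1 for x in a if x == 1)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(vid)
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        cols.append(g)
    if not variants:
        raise ParseError(f"no variant records parsed from {path}")
    counts = np.stack(cols, axis=1)
    # orient to the minor allele from the pooled sample (ties keep ALT)
    valid = counts != MISSING
    alt = np.where(valid, counts, 0).sum(axis=0)
    denom = 2 * valid.sum(axis=0)
    flip = alt * 2 > denom
    counts[:, flip] = np.where(
        counts[:, flip] == MISSING, MISSING, 2 - counts[:, flip]
    ).astype(np.int8)
    return GenotypeMatrix(
        samples=samples, variants=variants, counts=counts,
        chrom=chrom, pos=np.asarray(pos),
    )


def _read_tsv(path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: expected a header with variant columns")
        variants = header[1:]
        samples, rows = [], []
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(
                    f"{path}:{ln}: expected {len(header)} columns, got {len(parts)}"
                )
            samples.append(parts[0])
            row = np.empty(len(variants), dtype=np.int8)
            for j, tok in enumerate(parts[1:]):
                if tok in _TSV_MISSING_TOKENS:
                    row[j] = MISSING
                else:
                    try:
                        val = int(tok)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{ln}: bad genotype value {tok!r}"
                        ) from None
                    if val not in (0, 1, 2):
                        raise ParseError(f"{path}:{ln}: genotype {val} not in 0/1/2")
                    row[j] = val
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no sample rows")
    return GenotypeMatrix(samples=samples, variants=variants, counts=np.stack(rows))


def write_genotypes_tsv(geno: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(geno.variants) + "\n")
        for i, s in enumerate(geno.samples):
            toks = ["NA" if v == MISSING else str(int(v)) for v in geno.counts[i]]
            fh.write(s + "\t" + "\t".join(toks) + "\n")


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal uncompressed VCF; ALT carries the minor allele."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted(set(geno.chrom)) if geno.chrom is not None else ["1"]
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        for j, vid in enumerate(geno.variants):
            chrom = geno.chrom[j] if geno.chrom is not None else "1"
            pos = int(geno.pos[j]) if geno.pos is not None else j + 1
            gts = "\t".join(gt_map[int(v)] for v in geno.counts[:, j])
            fh.write(f"{chrom}\t{pos}\t{vid}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


# ----------------------------------------------------------------- phenotype

_CASE_TOKENS = {"case", "1", "2"}  # 2 = plink-style affected
_CONTROL_TOKENS = {"control", "0"}


def read_phenotype(path, samples=None) -> Phenotype:
    """Read a two-column sample/status TSV; align to ``samples`` if given.

    Accepted status labels: case/control, 1/0 (and plink-style 2 = case).
    Every genotype sample must be present, and a phenotype sample absent
    from the genotypes is an alignment error.
    """
    status_by_sample = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected two columns")
            sample, tok = parts
            tok_l = tok.lower()
            if tok_l in _CASE_TOKENS:
                st = True
            elif tok_l in _CONTROL_TOKENS:
                st = False
            else:
                raise ValueError(f"{path}:{ln}: unrecognized status {tok!r}")
            if sample in status_by_sample:
                raise ParseError(f"{path}:{ln}: duplicate sample {sample!r}")
            status_by_sample[sample] = st
    if samples is None:
        samples = list(status_by_sample)
    else:
        extra = set(status_by_sample) - set(samples)
        if extra:
            raise ValueError(
                f"phenotype samples absent from genotypes: {sorted(extra)[:5]}"
            )
        missing = [s for s in samples if s not in status_by_sample]
        if missing:
            raise ValueError(f"samples lacking phenotype: {missing[:5]}")
    status = np.array([status_by_sample[s] for s in samples], dtype=bool)
    return Phenotype(samples=list(samples), status=status)


def write_phenotype(phen: Phenotype, path) -> None:
    with open(path, "w") as fh:
        for s, st in zip(phen.samples, phen.status):
            fh.write(f"{s}\t{'case' if st else 'control'}\n")


# ------------------------------------------------------- gene map / pair list

def read_gene_map(path, geno: GenotypeMatrix | None = None) -> GeneMap:
    """Two-column gene/variant TSV; a comma list in column 2 is accepted."""
    genes: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected two columns")
            gene, vs = parts
            for v in vs.split(","):
                v = v.strip()
                if v:
                    genes.setdefault(gene, []).append(v)
    gm = GeneMap(genes=genes)
    if geno is not None:
        gm.validate(geno)
    return gm


def write_gene_map(gene_map: GeneMap, path) -> None:
    with open(path, "w") as fh:
        for g, vs in gene_map.genes.items():
            for v in vs:
                fh.write(f"{g}\t{v}\n")


def read_pair_list(path, gene_map: GeneMap | None = None) -> GenePairList:
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{ln}: expected two columns")
            pairs.append((parts[0], parts[1]))
    pl = GenePairList(pairs=pairs)
    if gene_map is not None:
        pl.validate(gene_map)
    return pl


def write_pair_list(pairs: GenePairList, path) -> None:
    with open(path, "w") as fh:
        for g1, g2 in pairs:
            fh.write(f"{g1}\t{g2}\n")
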