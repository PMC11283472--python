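"""Synthetic data generators with known ground truth.

Each generator emulates the statistical structure one downstream stage
assumes:

* :func:`simulate_coverage` — Poisson read counts over genomic windows
  with sex-dependent X copy number (1 in males, 2 in females of an XO
  system), the substrate for coverage-based X identification.
* :func:`simulate_counts` — negative-binomial RNA-seq counts with
  planted female-/male-biased genes of graded log2 effect sizes and an
  X dosage-compensation switch.
* :func:`simulate_orthology` — reciprocal-best-hit score tables that
  realize a planned cross-species congruence pattern.
* :func:`simulate_genotypes` — neutral-frequency-spectrum genotype
  matrices with group-specific per-bp diversity theta.

All generators are deterministic under a fixed seed and return a
:class:`GroundTruth` alongside the data so recovery can be tested.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popgen import GenotypeMatrix

__all__ = [
    "ContigSpec",
    "CoverageSimConfig",
    "ExpressionSimConfig",
    "PopGenSimConfig",
    "GroundTruth",
    "simulate_coverage",
    "simulate_counts",
    "simulate_orthology",
    "simulate_genotypes",
]

SEXES = ("female", "male")
BLAST6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class GroundTruth:
    """Planted truth accompanying each simulated dataset."""

    x_contigs: list[str] | None = None
    genes: pd.DataFrame | None = None  # gene_id, chromosome, status, log2_effect, ...
    ortholog_pairs: pd.DataFrame | None = None  # gene_a, gene_b, planned_class
    theta: dict[str, float] | None = None
    regions: pd.DataFrame | None = None  # contig, group, length


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContigSpec:
    name: str
    length: int
    kind: str = "A"  # "A" autosome (2 copies both sexes) or "X" (1 in males)


@dataclass
class CoverageSimConfig:
    """Sex-specific copy-number coverage simulation.

    ``depth`` is the expected read count per full window in a diploid
    (two-copy) sample; male windows on X contigs are drawn at half that
    expectation. Window counts are Poisson.
    """

    contigs: Sequence[ContigSpec]
    depth: float = 100.0
    window_size: int = 10000
    samples_per_sex: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window size must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.samples_per_sex < 1:
            raise ValueError("need at least one sample per sex")
        kinds = {c.kind for c in self.contigs}
        if not kinds <= {"A", "X"}:
            raise ValueError(f"unknown contig kind in {kinds}")
        if "A" not in kinds:
            raise ValueError("need at least one autosomal contig")
        names = [c.name for c in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names")


def simulate_coverage(cfg: CoverageSimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-window raw read counts for each sample.

    Returns a long table with columns ``contig, start, end, sample,
    sex, count, truncated`` (0-based half-open windows; the terminal
    window of a contig is truncated to the contig end and flagged).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    samples = [
        (f"{sex}_{i + 1}", sex)
        for sex in SEXES
        for i in range(cfg.samples_per_sex)
    ]
    ws = cfg.window_size
    recs = []
    for contig in cfg.contigs:
        n_win = max(1, math.ceil(contig.length / ws))
        for k in range(n_win):
            start = k * ws
            end = min(start + ws, contig.length)
            frac = (end - start) / ws
            for name, sex in samples:
                copies = 1 if (contig.kind == "X" and sex == "male") else 2
                lam = cfg.depth * frac * copies / 2.0
                recs.append(
                    (contig.name, start, end, name, sex,
                     int(rng.poisson(lam)), end - start < ws)
                )
    cov = pd.DataFrame(
        recs, columns=["contig", "start", "end", "sample", "sex", "count", "truncated"]
    )
    truth = GroundTruth(x_contigs=[c.name for c in cfg.contigs if c.kind == "X"])
    return cov, truth


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def _default_chrom_probs() -> dict[str, float]:
    return {"X": 0.10, "chr1": 0.25, "chr2": 0.25, "chr3": 0.20, "chr4": 0.20}


@dataclass
class ExpressionSimConfig:
    """Negative-binomial count simulation with planted sex effects.

    Gene baseline means are log-normal (``2 ** Normal(log2_mean,
    log2_sd)``). ``planted_bias`` is an ordered sequence of
    ``(sex, fraction)`` pairs; a biased gene's mean in the favored sex
    is ``2 ** effect`` times its mean in the other sex, with |effect|
    drawn uniformly from ``effect_size_range``. Because direction
    assignment follows the *position* of each entry, swapping the sex
    names in place while keeping the fractions reverses every planted
    direction exactly under the same seed. With ``x_compensation =
    "full"`` X-linked genes have equal expected expression in both
    sexes; with ``"none"`` the male expectation on the X is halved
    (single copy, no compensating upregulation).
    """

    n_genes: int = 2000
    chrom_probs: Mapping[str, float] = field(default_factory=_default_chrom_probs)
    replicates: int = 5
    tissues: Sequence[str] = ("head",)
    species: str = "spA"
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    dispersion: float = 0.1
    planted_bias: Sequence[tuple[str, float]] = (("female", 0.05), ("male", 0.05))
    effect_size_range: tuple[float, float] = (2.5, 6.0)
    x_compensation: str = "full"
    libsize_range: tuple[float, float] = (0.75, 1.25)
    seed: int = 0

    def validate(self) -> None:
        fracs = [f for _, f in self.planted_bias]
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("bias fractions must lie in [0,1] and sum to <= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per (sex, tissue)")
        if self.x_compensation not in ("full", "none"):
            raise ValueError("x_compensation must be 'full' or 'none'")
        if min(self.libsize_range) <= 0:
            raise ValueError("library-size factors must be positive")
        sexes = [s for s, _ in self.planted_bias]
        if len(set(sexes)) != len(sexes) or not set(sexes) <= set(SEXES):
            raise ValueError("planted_bias sexes must be distinct members of "
                             f"{SEXES}")


def simulate_counts(
    cfg: ExpressionSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Gene x sample count matrix, sample metadata and planted truth.

    The truth table records each gene's chromosome, bias status
    ('female-biased' / 'male-biased' / 'unbiased'), signed log2 effect
    (positive = higher in females) and expected mean per sex before
    library-size scaling.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = [f"{cfg.species}.g{i:05d}" for i in range(1, n + 1)]

    chroms = list(cfg.chrom_probs)
    probs = np.array([cfg.chrom_probs[c] for c in chroms], dtype=float)
    probs = probs / probs.sum()
    gene_chrom = rng.choice(chroms, size=n, p=probs)

    base = 2.0 ** rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)

    # positional direction assignment (see class docstring)
    u = rng.random(n)
    status = np.full(n, "unbiased", dtype=object)
    cum = 0.0
    for sex, frac in cfg.planted_bias:
        status[(u >= cum) & (u < cum + frac)] = f"{sex}-biased"
        cum += frac
    lo, hi = cfg.effect_size_range
    magnitude = rng.uniform(lo, hi, n)
    effect = np.zeros(n)
    effect[status == "female-biased"] = magnitude[status == "female-biased"]
    effect[status == "male-biased"] = -magnitude[status == "male-biased"]

    # effect split symmetrically about the baseline so the favored sex is
    # 2**|effect| above the other while library mass stays balanced
    mean_f = base * 2.0 ** (effect / 2.0)
    mean_m = base * 2.0 ** (-effect / 2.0)
    if cfg.x_compensation == "none":
        on_x = gene_chrom == "X"
        mean_m = np.where(on_x, mean_m * 0.5, mean_m)

    meta_rows = []
    cols = {}
    r = 1.0 / cfg.dispersion  # NB size parameter: var = mu + disp * mu^2
    for tissue in cfg.tissues:
        for sex in SEXES:
            mu_sex = mean_f if sex == "female" else mean_m
            for rep in range(1, cfg.replicates + 1):
                lib = rng.uniform(*cfg.libsize_range)
                sid = f"{cfg.species}_{tissue}_{sex}_{rep}"
                mu = mu_sex * lib
                p = r / (r + mu)
                cols[sid] = rng.negative_binomial(r, p)
                meta_rows.append((sid, cfg.species, sex, tissue, rep))
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "species", "sex", "tissue", "replicate"]
    )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chromosome": gene_chrom,
                "status": status,
                "log2_effect": effect,
                "mean_female": mean_f,
                "mean_male": mean_m,
            }
        )
    )
    return counts, meta, truth


# ---------------------------------------------------------------------------
# orthology
# ---------------------------------------------------------------------------

_PLAN_CLASSES = ("congruent", "incongruent", "transition", "both-unbiased", "absent")


def simulate_orthology(
    truth_a: GroundTruth,
    truth_b: GroundTruth,
    plan: Mapping[str, int],
    seed: int = 0,
    base_score: float = 500.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Directed similarity-score tables realizing a congruence plan.

    ``plan`` maps each class (congruent, incongruent, transition,
    both-unbiased, absent) to the number of gene pairs (or, for
    'absent', single species-A genes) to emit. True pairs receive
    mutually best scores plus occasional strictly lower decoy hits;
    'absent' genes get either no hit or a non-reciprocal one, so the
    reciprocal-best-hit step excludes them. Output tables are 12-column
    BLAST outfmt-6-like frames.
    """
    bad = set(plan) - set(_PLAN_CLASSES)
    if bad:
        raise ValueError(f"unknown plan classes: {sorted(bad)}")
    genes_a, genes_b = truth_a.genes, truth_b.genes
    if genes_a is None or genes_b is None:
        raise ValueError("both truths need gene tables")
    overlap = set(genes_a["gene_id"]) & set(genes_b["gene_id"])
    if overlap:
        raise ValueError(f"duplicate gene ids across species: {sorted(overlap)[:5]}")

    rng = np.random.default_rng(seed)

    def pools(genes: pd.DataFrame) -> dict[str, deque]:
        out = {}
        for st, grp in genes.groupby("status"):
            ids = grp["gene_id"].to_list()
            rng.shuffle(ids)
            out[st] = deque(ids)
        return out

    pool_a, pool_b = pools(genes_a), pools(genes_b)

    def take(pool: dict[str, deque], statuses: Sequence[str]) -> str:
        for st in statuses:
            if pool.get(st):
                return pool[st].popleft()
        raise ValueError(f"not enough genes with status in {list(statuses)}")

    biased = ("female-biased", "male-biased")
    pairs = []
    for cls in _PLAN_CLASSES:
        for i in range(plan.get(cls, 0)):
            if cls == "congruent":
                d = biased[i % 2] if pool_a.get(biased[i % 2]) and pool_b.get(biased[i % 2]) else biased[(i + 1) % 2]
                pairs.append((take(pool_a, [d]), take(pool_b, [d]), cls))
            elif cls == "incongruent":
                d = biased[i % 2]
                other = biased[(i + 1) % 2]
                if not (pool_a.get(d) and pool_b.get(other)):
                    d, other = other, d
                pairs.append((take(pool_a, [d]), take(pool_b, [other]), cls))
            elif cls == "transition":
                if i % 2 == 0:
                    pairs.append(
                        (take(pool_a, [biased[(i // 2) % 2], biased[(i // 2 + 1) % 2]]),
                         take(pool_b, ["unbiased"]), cls)
                    )
                else:
                    pairs.append(
                        (take(pool_a, ["unbiased"]),
                         take(pool_b, [biased[(i // 2) % 2], biased[(i // 2 + 1) % 2]]), cls)
                    )
            elif cls == "both-unbiased":
                pairs.append((take(pool_a, ["unbiased"]), take(pool_b, ["unbiased"]), cls))
            elif cls == "absent":
                any_status = ["unbiased", *biased]
                pairs.append((take(pool_a, any_status), None, cls))

    rows_ab, rows_ba = [], []

    def blast_row(q: str, s: str, score: float) -> tuple:
        return (q, s, 90.0 + rng.uniform(0, 9), 500, int(rng.integers(0, 40)),
                0, 1, 500, 1, 500, 1e-120, round(score, 1))

    paired_b = [b for _, b, c in pairs if b is not None]
    for idx, (a, b, cls) in enumerate(pairs):
        if b is not None:
            s_ab = base_score + rng.uniform(10, 60)
            s_ba = base_score + rng.uniform(10, 60)
            rows_ab.append(blast_row(a, b, s_ab))
            rows_ba.append(blast_row(b, a, s_ba))
            if rng.random() < 0.5 and len(paired_b) > 1:
                decoy = paired_b[int(rng.integers(len(paired_b)))]
                if decoy != b:
                    rows_ab.append(blast_row(a, decoy, s_ab - rng.uniform(5, 50)))
            if rng.random() < 0.5:
                rows_ba.append(blast_row(b, a + "_decoy", s_ba - rng.uniform(5, 50)))
        else:
            # absent: alternate between no hit at all and a one-way hit
            if idx % 2 == 0 and paired_b:
                target = paired_b[int(rng.integers(len(paired_b)))]
                rows_ab.append(blast_row(a, target, base_score - rng.uniform(50, 100)))

    scores_ab = pd.DataFrame(rows_ab, columns=BLAST6_COLUMNS)
    scores_ba = pd.DataFrame(rows_ba, columns=BLAST6_COLUMNS)
    truth = GroundTruth(
        ortholog_pairs=pd.DataFrame(pairs, columns=["gene_a", "gene_b", "planned_class"])
    )
    return scores_ab, scores_ba, truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class PopGenSimConfig:
    """Neutral-spectrum genotype simulation with per-group theta.

    For each region the segregating-site count is Poisson with mean
    ``theta * L * a1`` (a1 = sum_{i<n} 1/i), and derived-allele counts
    follow the neutral site-frequency spectrum P(count = i) ~ 1/i —
    sufficient for pi and Tajima's D to take their coalescent expected
    values without simulating genealogies.
    """

    n_haplotypes: int = 20
    region_length: int = 10000
    theta: Mapping[str, float] = field(
        default_factory=lambda: {"unbiased": 0.001, "sex-biased": 0.002}
    )
    n_regions_per_group: int = 1
    missingness: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_haplotypes < 4:
            raise ValueError("need at least 4 haplotypes")
        if self.n_haplotypes % 2:
            raise ValueError("haplotype count must be even (diploid samples)")
        if any(t < 0 for t in self.theta.values()):
            raise ValueError("theta must be non-negative")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must lie in [0, 1)")
        if self.region_length <= 0 or self.n_regions_per_group <= 0:
            raise ValueError("region length and count must be positive")


def simulate_genotypes(cfg: PopGenSimConfig) -> tuple[GenotypeMatrix, GroundTruth]:
    """Genotype matrix over one contig per simulated region."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_haplotypes
    L = cfg.region_length
    a1 = sum(1.0 / i for i in range(1, n))
    sfs = 1.0 / np.arange(1, n)
    sfs = sfs / sfs.sum()

    site_frames, gt_blocks, region_rows = [], [], []
    contig_lengths = {}
    for group, theta in cfg.theta.items():
        for ri in range(cfg.n_regions_per_group):
            contig = f"{group}.r{ri:03d}"
            contig_lengths[contig] = L
            region_rows.append((contig, group, L))
            S = int(rng.poisson(theta * L * a1)) if theta > 0 else 0
            S = min(S, L)
            if S == 0:
                continue
            pos = np.sort(rng.choice(L, size=S, replace=False)) + 1
            counts = rng.choice(np.arange(1, n), size=S, p=sfs)
            gt = np.zeros((S, n), dtype=np.int8)
            for k, j in enumerate(counts):
                carriers = rng.choice(n, size=j, replace=False)
                gt[k, carriers] = 1
            if cfg.missingness > 0:
                miss = rng.random((S, n // 2)) < cfg.missingness
                gt[np.repeat(miss, 2, axis=1)] = -1
            site_frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "pos": pos,
                        "ref": "A",
                        "alt": "T",
                        "qual": 60.0,
                    }
                )
            )
            gt_blocks.append(gt)

    samples = [f"ind{i + 1:02d}" for i in range(n // 2)]
    if site_frames:
        sites = pd.concat(site_frames, ignore_index=True)
        genotypes = np.vstack(gt_blocks)
    else:
        sites = pd.DataFrame(
            {"contig": pd.Series(dtype=str), "pos": pd.Series(dtype=int),
             "ref": pd.Series(dtype=str), "alt": pd.Series(dtype=str),
             "qual": pd.Series(dtype=float)}
        )
        genotypes = np.zeros((0, n), dtype=np.int8)
    g = GenotypeMatrix(sites, genotypes, samples, contig_lengths)
    truth = GroundTruth(
        theta=dict(cfg.theta),
        regions=pd.DataFrame(region_rows, columns=["contig", "group", "length"]),
    )
    return g, truth
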