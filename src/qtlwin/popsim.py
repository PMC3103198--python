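"""Synthetic pedigreed-population generator.

Builds QTLMAS2010-style studies end to end: a multi-generation pedigree from a
small founder set, founder haplotypes drawn either in linkage equilibrium or
with historical LD from a forward-in-time bottleneck simulation, gene-dropped
SNP genotypes under Haldane recombination (1 Mbp = 1 cM), additive / epistatic
/ paternally imprinted QTL with an exactly calibrated additive variance, and
phenotypes with a sex fixed effect. The same machinery provides the
null-genotype simulations used to derive genome-scan thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._kernels import recombine

MALE, FEMALE = 0, 1
_SEX_CODE = {"M": MALE, "F": FEMALE}
_SEX_CHAR = {MALE: "M", FEMALE: "F"}

#: base pairs per Morgan under the fixed 1 Mbp = 1 cM rule
BP_PER_MORGAN = 100_000_000


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Ordered SNP map; positions strictly increasing within chromosomes."""

    chrom: np.ndarray          # int, per SNP
    snp_id: np.ndarray         # str, per SNP
    position_bp: np.ndarray    # int, per SNP

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        if np.any(self.position_bp < 0):
            raise ValueError("position_bp must be >= 0")
        for c in np.unique(self.chrom):
            pos = self.position_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return self.chrom.size

    @property
    def position_morgan(self) -> np.ndarray:
        return self.position_bp / BP_PER_MORGAN

    def chrom_slices(self) -> list[tuple[int, slice]]:
        """(chromosome id, slice into the SNP axis) in map order."""
        out = []
        for c in pd.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            out.append((int(c), slice(int(idx[0]), int(idx[-1]) + 1)))
        return out

    def chrom_length_morgan(self, chrom: int, chrom_length_bp: int | None = None) -> float:
        if chrom_length_bp is not None:
            return chrom_length_bp / BP_PER_MORGAN
        pos = self.position_bp[self.chrom == chrom]
        return float(pos[-1]) / BP_PER_MORGAN


def evenly_spaced_map(n_snps: int, n_chrom: int = 5,
                      chrom_length_bp: int = BP_PER_MORGAN) -> GeneticMap:
    """Evenly spaced SNPs over equal-length chromosomes (QTLMAS layout)."""
    base, extra = divmod(n_snps, n_chrom)
    chroms, ids, pos = [], [], []
    for c in range(1, n_chrom + 1):
        m_c = base + (1 if c <= extra else 0)
        step = chrom_length_bp // (m_c + 1)
        p = (np.arange(1, m_c + 1) * step).astype(np.int64)
        chroms.append(np.full(m_c, c))
        pos.append(p)
        ids.extend(f"snp{c}_{k + 1}" for k in range(m_c))
    return GeneticMap(np.concatenate(chroms), np.array(ids, dtype=object),
                      np.concatenate(pos))


@dataclass
class Pedigree:
    """Individuals in parents-before-offspring order; parent index -1 = unknown."""

    sire: np.ndarray        # int index into pedigree, -1 unknown
    dam: np.ndarray
    sex: np.ndarray         # 0 male, 1 female
    generation: np.ndarray  # int >= 0

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=np.int64)
        self.generation = np.asarray(self.generation, dtype=np.int64)
        n = self.sire.size
        idx = np.arange(n)
        if np.any(self.sire >= idx) or np.any(self.dam >= idx):
            raise ValueError("parents must precede offspring")
        known_s = self.sire >= 0
        known_d = self.dam >= 0
        if np.any(self.sex[self.sire[known_s]] != MALE):
            raise ValueError("sire must be male")
        if np.any(self.sex[self.dam[known_d]] != FEMALE):
            raise ValueError("dam must be female")

    @property
    def n(self) -> int:
        return self.sire.size

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    @property
    def n_founders(self) -> int:
        return int(self.is_founder.sum())


@dataclass
class PedigreeConfig:
    """Discrete-generation mating design.

    Each generation, ``n_sires`` males and ``n_dams`` females are drawn from
    the previous generation (all available if fewer); each dam is mated to a
    random selected sire and produces ``offspring_per_dam`` offspring of
    random sex.
    """

    n_founders: int = 20
    n_founder_males: int = 5
    n_generations: int = 5
    n_sires: int = 5
    n_dams: int = 150
    offspring_per_dam: int = 7


def build_pedigree(config: PedigreeConfig = PedigreeConfig(), seed=0) -> Pedigree:
    rng = _rng(seed)
    c = config
    if c.n_founders < 2 or not (0 < c.n_founder_males < c.n_founders):
        raise ValueError("founder set must contain at least one male and one female")
    if c.n_generations < 1:
        raise ValueError("need at least the founder generation")
    sex = [MALE] * c.n_founder_males + [FEMALE] * (c.n_founders - c.n_founder_males)
    sire = [-1] * c.n_founders
    dam = [-1] * c.n_founders
    gen = [0] * c.n_founders
    prev = np.arange(c.n_founders)
    for g in range(1, c.n_generations):
        males = prev[np.array([sex[i] for i in prev]) == MALE]
        females = prev[np.array([sex[i] for i in prev]) == FEMALE]
        if males.size == 0 or females.size == 0:
            raise ValueError(f"generation {g - 1} lacks one sex; cannot continue mating")
        sires = rng.choice(males, size=min(c.n_sires, males.size), replace=False)
        dams = rng.choice(females, size=min(c.n_dams, females.size), replace=False)
        new = []
        for d in dams:
            s = int(rng.choice(sires))
            for _ in range(c.offspring_per_dam):
                sire.append(s)
                dam.append(int(d))
                sex.append(int(rng.integers(2)))
                gen.append(g)
                new.append(len(sire) - 1)
        prev = np.array(new)
    return Pedigree(np.array(sire), np.array(dam), np.array(sex), np.array(gen))


@dataclass
class HaplotypePool:
    """Phased haplotypes; consecutive row pairs (2i, 2i+1) form individual i.

    ``position_bp`` records realized locus positions when the pool comes from
    a historical simulation whose surviving loci were snapped to a target map.
    """

    haplotypes: np.ndarray  # (2n, m) int8 in {0, 1}
    position_bp: np.ndarray | None = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise ValueError("haplotypes must be a (2n, m) matrix")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class NeSchedule:
    """Piecewise-constant effective-size history, oldest epoch first."""

    epochs: list[tuple[int, int]] = field(
        default_factory=lambda: [(500, 1000), (100, 1)])
    #: linear growth from the last epoch's size to this over ``growth_generations``
    final_size: int = 1500
    growth_generations: int = 10

    def sizes(self) -> list[int]:
        out: list[int] = []
        for ne, g in self.epochs:
            if ne <= 1:
                raise ValueError("effective size must exceed 1")
            out.extend([ne] * g)
        if self.growth_generations > 0:
            start = self.epochs[-1][0] if self.epochs else self.final_size
            out.extend(np.linspace(start, self.final_size,
                                   self.growth_generations + 1)[1:]
                       .round().astype(int).tolist())
        return out


def simulate_founders_le(n_individuals: int, gmap: GeneticMap,
                         allele_freq=0.5, seed=0) -> HaplotypePool:
    """Founder haplotypes with every locus drawn independently (LE).

    ``allele_freq`` may be a scalar, an array of per-SNP frequencies, or a
    callable ``f(m, rng) -> freqs``.
    """
    rng = _rng(seed)
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    m = gmap.n_snps
    if callable(allele_freq):
        p = np.asarray(allele_freq(m, rng), dtype=float)
    else:
        p = np.broadcast_to(np.asarray(allele_freq, dtype=float), (m,))
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    haps = (rng.random((2 * n_individuals, m)) < p).astype(np.int8)
    return HaplotypePool(haps)


def _chrom_geometry(gmap: GeneticMap, chrom_length_bp: int | None):
    """Per-chromosome (slice, morgan positions, map length in Morgan)."""
    out = []
    for c, sl in gmap.chrom_slices():
        pos = gmap.position_bp[sl] / BP_PER_MORGAN
        if chrom_length_bp is not None:
            length = chrom_length_bp / BP_PER_MORGAN
        else:
            length = float(pos[-1])
        out.append((sl, pos.astype(np.float64), length))
    return out


def _make_gamete(haps: np.ndarray, parent: int, geometry, rng) -> np.ndarray:
    """One meiosis: Poisson crossovers, uniform positions, no interference."""
    m = haps.shape[1]
    gam = np.empty(m, dtype=np.int8)
    h0 = haps[2 * parent]
    h1 = haps[2 * parent + 1]
    for sl, pos, length in geometry:
        n_x = rng.poisson(length) if length > 0 else 0
        xpos = np.sort(rng.random(n_x) * length) if n_x else np.empty(0)
        start = int(rng.integers(2))
        gam[sl] = recombine(h0[sl], h1[sl], pos, xpos, start)
    return gam


def _drop_generation(parent_haps: np.ndarray, sires: np.ndarray,
                     dams: np.ndarray, geometry, rng) -> np.ndarray:
    """Gametes for one offspring cohort; rows (2i, 2i+1) = (paternal, maternal)."""
    n = sires.size
    child = np.empty((2 * n, parent_haps.shape[1]), dtype=np.int8)
    for i in range(n):
        child[2 * i] = _make_gamete(parent_haps, int(sires[i]), geometry, rng)
        child[2 * i + 1] = _make_gamete(parent_haps, int(dams[i]), geometry, rng)
    return child


def simulate_founders_ld(schedule: NeSchedule, gmap: GeneticMap,
                         n_candidate_loci: int | None = None,
                         maf_floor: float = 0.05, seed=0,
                         chrom_length_bp: int | None = None) -> HaplotypePool:
    """Founder haplotypes carrying historical LD.

    Runs a discrete-generation Wright-Fisher population (random union of
    gametes, no mutation) over the ``schedule``, starting from surplus
    candidate loci at Uniform(0.1, 0.9) frequencies; after the final
    generation, loci that went monomorphic or fell below ``maf_floor`` are
    dropped and survivors nearest each target map position are kept.
    """
    rng = _rng(seed)
    m = gmap.n_snps
    if n_candidate_loci is None:
        n_candidate_loci = 3 * m
    if n_candidate_loci < m:
        raise ValueError("need at least as many candidate loci as target SNPs")
    sizes = schedule.sizes()

    # candidate map: evenly spaced within each target chromosome, pro rata
    cand_chrom, cand_pos = [], []
    per_chrom = []
    slices = gmap.chrom_slices()
    total = gmap.n_snps
    for c, sl in slices:
        share = max(1, round(n_candidate_loci * (sl.stop - sl.start) / total))
        per_chrom.append((c, sl, share))
    for c, sl, share in per_chrom:
        if chrom_length_bp is not None:
            length = chrom_length_bp
        else:
            length = int(gmap.position_bp[sl][-1]) + 1
        step = length // (share + 1)
        cand_chrom.append(np.full(share, c))
        cand_pos.append((np.arange(1, share + 1) * max(step, 1)).astype(np.int64))
    cand_map = GeneticMap(np.concatenate(cand_chrom),
                          np.array([f"c{i}" for i in range(sum(s for _, _, s in per_chrom))],
                                   dtype=object),
                          np.concatenate(cand_pos))
    geometry = _chrom_geometry(cand_map, chrom_length_bp)

    if not sizes:
        # no history: equivalent to LE founders at the initial frequencies
        pool = simulate_founders_le(
            max(schedule.final_size, gmap.n_snps and 1),
            cand_map, lambda mm, r: r.uniform(0.1, 0.9, mm), rng)
        haps = pool.haplotypes
    else:
        p0 = rng.uniform(0.1, 0.9, cand_map.n_snps)
        haps = (rng.random((2 * sizes[0], cand_map.n_snps)) < p0).astype(np.int8)
        for n_next in sizes[1:] + [sizes[-1]]:
            n_par = haps.shape[0] // 2
            sires = rng.integers(n_par, size=n_next)
            dams = rng.integers(n_par, size=n_next)
            haps = _drop_generation(haps, sires, dams, geometry, rng)

    freq = haps.mean(axis=0)
    alive = (freq >= maf_floor) & (freq <= 1 - maf_floor)
    # match each target SNP to the nearest surviving candidate on its chromosome
    keep = np.empty(m, dtype=np.int64)
    for (c, sl) in slices:
        cand_idx = np.flatnonzero((cand_map.chrom == c) & alive)
        want = sl.stop - sl.start
        if cand_idx.size < want:
            raise ValueError(
                f"chromosome {c}: only {cand_idx.size} polymorphic candidate loci "
                f"survived, {want} required")
        cpos = cand_map.position_bp[cand_idx]
        used = np.zeros(cand_idx.size, dtype=bool)
        for k, tp in enumerate(gmap.position_bp[sl]):
            order = np.argsort(np.abs(cpos - tp), kind="stable")
            for o in order:
                if not used[o]:
                    used[o] = True
                    keep[sl.start + k] = cand_idx[o]
                    break
    return HaplotypePool(haps[:, keep], cand_map.position_bp[keep])


def sample_founder_pool(pool: HaplotypePool, n_founders: int, seed=0) -> HaplotypePool:
    """Draw ``n_founders`` diploid genomes without replacement from a cohort."""
    rng = _rng(seed)
    if pool.n_individuals < n_founders:
        raise ValueError(f"pool holds {pool.n_individuals} individuals, "
                         f"{n_founders} founders requested")
    pick = rng.choice(pool.n_individuals, size=n_founders, replace=False)
    rows = np.empty(2 * n_founders, dtype=np.int64)
    rows[0::2] = 2 * pick
    rows[1::2] = 2 * pick + 1
    return HaplotypePool(pool.haplotypes[rows])


def gene_drop(pedigree: Pedigree, founder_pool: HaplotypePool, gmap: GeneticMap,
              seed=0, chrom_length_bp: int | None = BP_PER_MORGAN):
    """Drop founder haplotypes down the pedigree.

    Each non-founder gamete recombines the parent's two haplotypes with a
    Poisson crossover count in the chromosome map length and uniform crossover
    positions (Haldane, no interference).

    Returns ``(X, gametes)`` — the 0/1/2 genotype matrix and the phased
    gamete array of shape (n, 2, m) with axis 1 = (paternal, maternal).
    """
    rng = _rng(seed)
    founders = np.flatnonzero(pedigree.is_founder)
    if founder_pool.n_individuals < founders.size:
        raise ValueError(f"founder pool supplies {founder_pool.n_individuals} "
                         f"genomes for {founders.size} founders")
    geometry = _chrom_geometry(gmap, chrom_length_bp)
    m = gmap.n_snps
    n = pedigree.n
    gam = np.empty((n, 2, m), dtype=np.int8)
    haps = np.empty((2 * n, m), dtype=np.int8)  # row pairs per individual
    fmap = {int(ind): k for k, ind in enumerate(founders)}
    for i in range(n):
        s, d = int(pedigree.sire[i]), int(pedigree.dam[i])
        if s < 0 and d < 0:
            k = fmap[i]
            gam[i, 0] = founder_pool.haplotypes[2 * k]
            gam[i, 1] = founder_pool.haplotypes[2 * k + 1]
        else:
            gam[i, 0] = _make_gamete(haps, s, geometry, rng)
            gam[i, 1] = _make_gamete(haps, d, geometry, rng)
        haps[2 * i] = gam[i, 0]
        haps[2 * i + 1] = gam[i, 1]
    X = gam.sum(axis=1).astype(np.int8)
    return X, gam


# ---------------------------------------------------------------------------
# QTL model and true values
# ---------------------------------------------------------------------------


@dataclass
class QTLCounts:
    n_additive: int = 30
    n_epistatic_pairs: int = 2
    n_imprinted: int = 3


@dataclass
class QTLModel:
    """Simulated trait architecture on mapped SNP positions.

    Epistatic pairs are two tightly linked loci whose 1-1 haplotype carries
    the full effect (other haplotypes zero), so the pair segregates like one
    multi-allelic additive locus. Imprinted loci express the maternally
    inherited allele only (paternal-allele silencing).
    """

    additive_index: np.ndarray
    additive_effect: np.ndarray
    additive_freq: np.ndarray
    epistatic: list[tuple[int, int, float]] = field(default_factory=list)
    imprinted_index: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    imprinted_effect: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    target_vg: float = 0.0

    def additive_variance(self) -> float:
        p = self.additive_freq
        return float(np.sum(2 * p * (1 - p) * self.additive_effect ** 2))


@dataclass
class TrueValues:
    tbv: np.ndarray
    genotypic_value: np.ndarray


def assign_qtl(gmap: GeneticMap, founder_pool: HaplotypePool,
               counts: QTLCounts = QTLCounts(), target_vg: float = 51.76,
               seed=0, effect_shape: float = 0.42) -> QTLModel:
    """Place QTL on mapped SNPs and calibrate the additive variance.

    Raw additive effects are gamma-distributed in magnitude (heavy tail: a few
    large QTL, many small) with random sign, then rescaled so that
    sum_k 2 p_k (1 - p_k) a_k^2 equals ``target_vg`` exactly at founder
    frequencies. Epistatic-pair and imprinted effects default to the largest
    additive effect magnitude.
    """
    rng = _rng(seed)
    if target_vg < 0:
        raise ValueError("target_vg must be >= 0")
    p_all = founder_pool.allele_freq
    poly = np.flatnonzero((p_all > 0) & (p_all < 1))
    if target_vg > 0 and poly.size == 0:
        raise ValueError("no polymorphic loci available for QTL placement")
    n_needed = counts.n_additive + 2 * counts.n_epistatic_pairs + counts.n_imprinted
    if poly.size < n_needed:
        raise ValueError(f"{poly.size} polymorphic loci < {n_needed} required")

    add_idx = np.sort(rng.choice(poly, size=counts.n_additive, replace=False))
    p = p_all[add_idx]
    raw = rng.gamma(effect_shape, 1.0, counts.n_additive) * \
        rng.choice([-1.0, 1.0], counts.n_additive)
    denom = np.sum(2 * p * (1 - p) * raw ** 2)
    if target_vg == 0 or denom == 0:
        a = np.zeros_like(raw)
    else:
        a = raw * np.sqrt(target_vg / denom)
    big = float(np.max(np.abs(a))) if a.size else 0.0

    taken = set(add_idx.tolist())
    free = np.array([i for i in poly if i not in taken])

    epistatic: list[tuple[int, int, float]] = []
    for _ in range(counts.n_epistatic_pairs):
        # adjacent mapped loci on the same chromosome, < 1 cM apart if possible
        for _ in range(200):
            i = int(rng.choice(free))
            j = i + 1
            if j < gmap.n_snps and gmap.chrom[j] == gmap.chrom[i] \
                    and j in set(free.tolist()):
                break
        else:
            raise ValueError("could not place an epistatic pair on free adjacent loci")
        epistatic.append((i, j, big))
        taken.update((i, j))
        free = np.array([k for k in free if k not in (i, j)])

    imp_idx = np.sort(rng.choice(free, size=counts.n_imprinted, replace=False)) \
        if counts.n_imprinted else np.empty(0, np.int64)
    imp_eff = np.full(counts.n_imprinted, big)

    return QTLModel(add_idx, a, p, epistatic, imp_idx.astype(np.int64),
                    imp_eff, float(target_vg))


def compute_true_values(gametes: np.ndarray, qtl: QTLModel,
                        sex: np.ndarray) -> TrueValues:
    """Genotypic value g (expressed in own phenotype) and TBV.

    TBV is twice the expected deviation of a progeny's genotypic value given
    the individual's transmitted gametes: additive and epistatic terms carry
    over unchanged; an imprinted locus contributes through a dam's transmitted
    alleles but not through a sire's (the paternal copy is silenced in the
    progeny), while g uses only the individual's own maternal allele.
    """
    if gametes.ndim != 3 or gametes.shape[1] != 2:
        raise ValueError("gametes must have shape (n, 2, m) with known phase")
    pat = gametes[:, 0, :].astype(float)
    mat = gametes[:, 1, :].astype(float)
    x = pat + mat
    n = x.shape[0]
    g = np.zeros(n)
    tbv = np.zeros(n)

    if qtl.additive_index.size:
        part = x[:, qtl.additive_index] @ qtl.additive_effect
        g += part
        tbv += part
    for i, j, eff in qtl.epistatic:
        hits = ((gametes[:, :, i] == 1) & (gametes[:, :, j] == 1)).sum(axis=1)
        g += eff * hits
        tbv += eff * hits
    for k, idx in enumerate(qtl.imprinted_index):
        eff = qtl.imprinted_effect[k]
        g += eff * mat[:, idx]
        tbv += np.where(np.asarray(sex) == FEMALE, eff * x[:, idx], 0.0)
    return TrueValues(tbv, g)


def simulate_phenotypes(true_values: TrueValues, pedigree: Pedigree,
                        mu: float, sex_effects, ve: float,
                        phenotyped_generations, seed=0) -> np.ndarray:
    """y_i = mu + s_sex(i) + g_i + e_i with e ~ N(0, Ve); NaN outside the
    phenotyped generations."""
    rng = _rng(seed)
    if ve < 0:
        raise ValueError("Ve must be >= 0")
    s = np.asarray(sex_effects, dtype=float)
    y = mu + s[pedigree.sex] + true_values.genotypic_value \
        + rng.normal(0.0, np.sqrt(ve), pedigree.n)
    mask = np.isin(pedigree.generation, np.asarray(list(phenotyped_generations)))
    y[~mask] = np.nan
    return y


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Defaults mirror the QTLMAS2010-style design: 5 generations from 20
    founders, 5 x 100 Mbp chromosomes, evenly spaced SNPs, h^2 = 0.5, sex
    fixed effect, phenotypes on all generations but the last."""

    pedigree: PedigreeConfig = field(default_factory=PedigreeConfig)
    n_snps: int = 10031
    n_chrom: int = 5
    chrom_length_bp: int = BP_PER_MORGAN
    founder_mode: str = "le"            # "le" | "ld"
    ne_schedule: NeSchedule = field(default_factory=NeSchedule)
    qtl_counts: QTLCounts = field(default_factory=QTLCounts)
    vg: float = 51.76
    ve: float = 51.76
    mu: float = 0.0
    sex_effects: tuple[float, float] = (0.0, 5.0)
    #: generations carrying phenotypes; None = every generation but the last
    phenotyped: tuple[int, ...] | None = None

    @property
    def phenotyped_generations(self):
        if self.phenotyped is not None:
            return tuple(self.phenotyped)
        return tuple(range(self.pedigree.n_generations - 1))


@dataclass
class SimulatedStudy:
    pedigree: Pedigree
    gmap: GeneticMap
    X: np.ndarray                  # (n, m) 0/1/2
    y: np.ndarray                  # NaN = unphenotyped
    mu: float
    sex_effects: np.ndarray
    ve: float
    true_values: TrueValues
    qtl: QTLModel
    seed: int
    phenotyped_generations: tuple[int, ...] = ()

    @property
    def training_mask(self) -> np.ndarray:
        return ~np.isnan(self.y)


def simulate_study(config: StudyConfig = StudyConfig(), seed: int = 0) -> SimulatedStudy:
    rng = _rng(seed)
    gmap = evenly_spaced_map(config.n_snps, config.n_chrom, config.chrom_length_bp)
    ped = build_pedigree(config.pedigree, rng)
    if config.founder_mode == "ld":
        cohort = simulate_founders_ld(config.ne_schedule, gmap, seed=rng,
                                      chrom_length_bp=config.chrom_length_bp)
        pool = sample_founder_pool(cohort, ped.n_founders, rng)
    else:
        pool = simulate_founders_le(ped.n_founders, gmap,
                                    lambda m, r: r.uniform(0.1, 0.9, m), rng)
    X, gametes = gene_drop(ped, pool, gmap, rng,
                           chrom_length_bp=config.chrom_length_bp)
    founder_haps = gametes[ped.is_founder].reshape(-1, gmap.n_snps)
    qtl = assign_qtl(gmap, HaplotypePool(founder_haps), config.qtl_counts,
                     config.vg, rng)
    tv = compute_true_values(gametes, qtl, ped.sex)
    y = simulate_phenotypes(tv, ped, config.mu, config.sex_effects, config.ve,
                            config.phenotyped_generations, rng)
    return SimulatedStudy(ped, gmap, X, y, config.mu,
                          np.asarray(config.sex_effects, float), config.ve,
                          tv, qtl, int(seed) if np.isscalar(seed) else -1,
                          tuple(config.phenotyped_generations))


# ---------------------------------------------------------------------------
# study IO (plain TSV + YAML metadata)
# ---------------------------------------------------------------------------


def write_study(study: SimulatedStudy, directory) -> None:
    from pathlib import Path
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ped = study.pedigree
    ids = np.arange(1, ped.n + 1)
    pd.DataFrame({
        "id": ids, "sire": np.where(ped.sire < 0, 0, ped.sire + 1),
        "dam": np.where(ped.dam < 0, 0, ped.dam + 1),
        "sex": [_SEX_CHAR[s] for s in ped.sex], "generation": ped.generation,
    }).to_csv(d / "pedigree.tsv", sep="\t", index=False)
    pd.DataFrame({"chrom": study.gmap.chrom, "snp_id": study.gmap.snp_id,
                  "position_bp": study.gmap.position_bp}
                 ).to_csv(d / "map.tsv", sep="\t", index=False)
    geno = pd.DataFrame(study.X, columns=study.gmap.snp_id)
    geno.insert(0, "id", ids)
    geno.to_csv(d / "genotypes.tsv", sep="\t", index=False)
    pd.DataFrame({"id": ids, "sex": [_SEX_CHAR[s] for s in ped.sex],
                  "trait": study.y}
                 ).to_csv(d / "phenotypes.tsv", sep="\t", index=False,
                          na_rep="NA", float_format="%.17g")
    q = study.qtl
    rows = [{"chrom": study.gmap.chrom[i], "snp_id": study.gmap.snp_id[i],
             "position_bp": study.gmap.position_bp[i], "type": "additive",
             "effect": q.additive_effect[k], "founder_freq": q.additive_freq[k],
             "partner": ""}
            for k, i in enumerate(q.additive_index)]
    for i, j, eff in q.epistatic:
        rows.append({"chrom": study.gmap.chrom[i], "snp_id": study.gmap.snp_id[i],
                     "position_bp": study.gmap.position_bp[i], "type": "epistatic",
                     "effect": eff, "founder_freq": np.nan,
                     "partner": study.gmap.snp_id[j]})
    for k, i in enumerate(q.imprinted_index):
        rows.append({"chrom": study.gmap.chrom[i], "snp_id": study.gmap.snp_id[i],
                     "position_bp": study.gmap.position_bp[i], "type": "imprinted",
                     "effect": q.imprinted_effect[k], "founder_freq": np.nan,
                     "partner": ""})
    pd.DataFrame(rows).to_csv(d / "qtl.tsv", sep="\t", index=False,
                              na_rep="NA", float_format="%.17g")
    pd.DataFrame({"id": ids, "tbv": study.true_values.tbv,
                  "genotypic_value": study.true_values.genotypic_value}
                 ).to_csv(d / "truth.tsv", sep="\t", index=False,
                          float_format="%.17g")
    meta = {"mu": float(study.mu),
            "sex_effects": [float(v) for v in study.sex_effects],
            "ve": float(study.ve), "seed": int(study.seed),
            "target_vg": float(study.qtl.target_vg),
            "phenotyped_generations": [int(g) for g in study.phenotyped_generations]}
    (d / "study.yaml").write_text(yaml.safe_dump(meta))


def read_study(directory) -> SimulatedStudy:
    from pathlib import Path
    d = Path(directory)

    def _load(name, **kw):
        try:
            return pd.read_csv(d / name, sep="\t", **kw)
        except Exception as exc:  # pragma: no cover - message formatting
            raise ValueError(f"malformed study file {d / name}: {exc}") from exc

    ped_df = _load("pedigree.tsv")
    ped = Pedigree(ped_df["sire"].to_numpy() - 1, ped_df["dam"].to_numpy() - 1,
                   np.array([_SEX_CODE[s] for s in ped_df["sex"]]),
                   ped_df["generation"].to_numpy())
    map_df = _load("map.tsv")
    gmap = GeneticMap(map_df["chrom"].to_numpy(), map_df["snp_id"].to_numpy(),
                      map_df["position_bp"].to_numpy())
    geno = _load("genotypes.tsv")
    X = geno.drop(columns="id").to_numpy(dtype=np.int8)
    phen = _load("phenotypes.tsv", na_values="NA")
    y = phen["trait"].to_numpy(dtype=float)
    meta = yaml.safe_load((d / "study.yaml").read_text())

    qdf = _load("qtl.tsv", na_values="NA", keep_default_na=False)
    sid_index = {s: i for i, s in enumerate(gmap.snp_id)}
    add = qdf[qdf["type"] == "additive"]
    epi = qdf[qdf["type"] == "epistatic"]
    imp = qdf[qdf["type"] == "imprinted"]
    qtl = QTLModel(
        np.array([sid_index[s] for s in add["snp_id"]], dtype=np.int64),
        add["effect"].to_numpy(dtype=float),
        add["founder_freq"].to_numpy(dtype=float),
        [(sid_index[r.snp_id], sid_index[r.partner], float(r.effect))
         for r in epi.itertuples()],
        np.array([sid_index[s] for s in imp["snp_id"]], dtype=np.int64),
        imp["effect"].to_numpy(dtype=float),
        float(meta["target_vg"]))
    truth = _load("truth.tsv")
    tv = TrueValues(truth["tbv"].to_numpy(float),
                    truth["genotypic_value"].to_numpy(float))
    return SimulatedStudy(ped, gmap, X, y, float(meta["mu"]),
                          np.asarray(meta["sex_effects"], float),
                          float(meta["ve"]), tv, qtl, int(meta["seed"]),
                          tuple(meta["phenotyped_generations"]))


def adjacent_r2(pool: HaplotypePool) -> np.ndarray:
    """Squared correlation between adjacent loci across haplotypes (LD check)."""
    h = pool.haplotypes.astype(float)
    h = h - h.mean(axis=0)
    sd = h.std(axis=0)
    out = np.full(h.shape[1] - 1, np.nan)
    for j in range(h.shape[1] - 1):
        if sd[j] > 0 and sd[j + 1] > 0:
            out[j] = (np.mean(h[:, j] * h[:, j + 1]) / (sd[j] * sd[j + 1])) ** 2
    return out
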