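"""Synthetic populations with the structure of a partial factorial carp cross.

The generator emulates a juvenile growth study design in common carp
(*Cyprinus carpio*): four factorial mating blocks of 5 dams x 10 sires
(60 founders), ~1,425 offspring in overdispersed full-sib families, a
50-linkage-group genome carrying ~12,311 RAD-derived SNP markers, and
bivariate weight/length phenotypes with moderate heritability and a very
high genetic correlation.  By default the 60 broodstock descend from a
closed random-mating ancestral pool of limited effective size, so founders
are related and carry linkage disequilibrium, as hatchery-strain broodstock
do; an unrelated/linkage-equilibrium founder model is also available.

Genetic values are strictly additive sums of QTL allele effects; QTL sit at
map positions distinct from the marker panel so that markers tag QTL only
through linkage, mimicking anonymous RAD tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree

# Consensus linkage map of the study population: (length in cM, SNP count)
# for each of the 50 carp linkage groups; totals 3,944 cM and 12,311 SNPs.
CARP_LINKAGE_MAP: tuple[tuple[int, int], ...] = (
    (102, 350), (91, 350), (76, 325), (77, 322), (90, 319),
    (77, 315), (77, 311), (77, 292), (75, 290), (84, 287),
    (83, 283), (71, 277), (81, 272), (70, 263), (69, 260),
    (78, 259), (105, 257), (78, 256), (92, 249), (75, 249),
    (106, 246), (75, 245), (84, 241), (70, 241), (76, 240),
    (77, 239), (71, 238), (84, 237), (93, 237), (81, 236),
    (71, 229), (77, 229), (78, 227), (70, 227), (87, 226),
    (77, 225), (88, 222), (77, 221), (73, 215), (71, 213),
    (74, 212), (72, 212), (72, 208), (79, 203), (80, 199),
    (67, 193), (73, 175), (71, 169), (75, 163), (69, 157),
)

N_LINKAGE_GROUPS = len(CARP_LINKAGE_MAP)
TOTAL_MAP_CM = sum(length for length, _ in CARP_LINKAGE_MAP)
TOTAL_MAP_SNPS = sum(count for _, count in CARP_LINKAGE_MAP)


@dataclass
class GenomeTemplate:
    """Fixed genome layout used by the gene-drop simulator.

    ``marker_lg``/``marker_pos`` and ``qtl_lg``/``qtl_pos`` are parallel
    arrays (linkage group 1..50, position in cM), each sorted by (lg, pos).
    """

    lengths_cm: np.ndarray
    marker_lg: np.ndarray
    marker_pos: np.ndarray
    qtl_lg: np.ndarray
    qtl_pos: np.ndarray

    @property
    def n_markers(self) -> int:
        return self.marker_pos.size

    @property
    def n_qtl(self) -> int:
        return self.qtl_pos.size

    def marker_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [f"LG{g}_{i + 1}" for i, g in enumerate(self.marker_lg)],
                "lg": self.marker_lg.astype(int),
                "pos_cm": self.marker_pos.astype(float),
            }
        )

    def combined_loci(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All loci (markers + QTL) merged and sorted by (lg, pos).

        Returns (lg, pos, is_qtl) arrays.  Transmission operates on this
        combined layout so markers and QTL segregate on the same gametes.
        """
        lg = np.concatenate([self.marker_lg, self.qtl_lg])
        pos = np.concatenate([self.marker_pos, self.qtl_pos])
        is_qtl = np.zeros(lg.size, dtype=bool)
        is_qtl[self.n_markers:] = True
        order = np.lexsort((pos, lg))
        return lg[order], pos[order], is_qtl[order]


def _proportional_allocation(total: int, weights: np.ndarray, minimum: int = 1) -> np.ndarray:
    """Integer allocation proportional to ``weights`` (largest remainder),
    forcing at least ``minimum`` per cell and an exact grand total."""
    k = weights.size
    if total < minimum * k:
        raise ValueError(f"cannot place {total} items with minimum {minimum} in {k} cells")
    ideal = weights / weights.sum() * (total - minimum * k)
    alloc = np.floor(ideal).astype(int)
    remainder = total - minimum * k - alloc.sum()
    if remainder > 0:
        frac_order = np.argsort(-(ideal - np.floor(ideal)), kind="stable")
        alloc[frac_order[:remainder]] += 1
    return alloc + minimum


def build_genome_template(n_markers: int = TOTAL_MAP_SNPS, n_qtl: int = 2000,
                          seed: int = 0) -> GenomeTemplate:
    """Lay out markers and QTL on the 50-group carp linkage map.

    Markers are allocated across groups proportionally to the published
    per-group SNP counts (at least one per group) and placed uniformly at
    random within each group; QTL likewise, proportionally to map length.
    QTL positions are redrawn on the (measure-zero) event of coinciding
    exactly with a marker.
    """
    if n_markers < N_LINKAGE_GROUPS:
        raise ValueError("need at least one marker per linkage group")
    if n_qtl < 0:
        raise ValueError("n_qtl must be non-negative")
    rng = np.random.default_rng(seed)
    lengths = np.array([length for length, _ in CARP_LINKAGE_MAP], dtype=float)
    snp_weights = np.array([count for _, count in CARP_LINKAGE_MAP], dtype=float)

    m_counts = _proportional_allocation(n_markers, snp_weights, minimum=1)
    q_counts = _proportional_allocation(n_qtl, lengths, minimum=0) if n_qtl else np.zeros(50, int)

    marker_lg, marker_pos, qtl_lg, qtl_pos = [], [], [], []
    for g in range(N_LINKAGE_GROUPS):
        mp = np.sort(rng.uniform(0.0, lengths[g], size=m_counts[g]))
        marker_lg.append(np.full(m_counts[g], g + 1))
        marker_pos.append(mp)
        if q_counts[g]:
            qp = rng.uniform(0.0, lengths[g], size=q_counts[g])
            while np.isin(qp, mp).any():  # pragma: no cover - measure zero
                qp[np.isin(qp, mp)] = rng.uniform(0.0, lengths[g], size=int(np.isin(qp, mp).sum()))
            qtl_lg.append(np.full(q_counts[g], g + 1))
            qtl_pos.append(np.sort(qp))
    return GenomeTemplate(
        lengths_cm=lengths,
        marker_lg=np.concatenate(marker_lg),
        marker_pos=np.concatenate(marker_pos),
        qtl_lg=np.concatenate(qtl_lg) if qtl_lg else np.empty(0, dtype=int),
        qtl_pos=np.concatenate(qtl_pos) if qtl_pos else np.empty(0, dtype=float),
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study design: 4 factorial blocks of 5 dams x 10
    sires, 1,425 offspring, weight 16.3 g (SD 4.6) / standard length 77 mm
    (SD 7.1) with h2 0.26 / 0.33, genetic correlation 0.94 and phenotypic
    correlation 0.93.  ``block_effect_sd_frac`` scales the common cross
    (block) effect as a fraction of the phenotypic SD.
    """

    n_blocks: int = 4
    dams_per_block: int = 5
    sires_per_block: int = 10
    n_offspring: int = 1425
    maf_low: float = 0.01
    maf_high: float = 0.5
    founder_model: str = "ancestral_pool"  # or "unrelated"
    pool_size: int = 18
    pool_generations: int = 15
    n_qtl: int = 2000
    h2_weight: float = 0.26
    h2_length: float = 0.33
    rg: float = 0.94
    rp_target: float = 0.93
    sd_weight: float = 4.6
    sd_length: float = 7.1
    mean_weight: float = 16.3
    mean_length: float = 77.0
    block_effect_sd_frac: float = 0.25
    genotyping_error_rate: float = 0.01
    missing_rate: float = 0.05
    family_concentration: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("h2_weight", "h2_length"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if abs(self.rg) > 1:
            raise ValueError("|rg| must be <= 1")
        for name in ("genotyping_error_rate", "missing_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("founder MAF law must satisfy 0 < low <= high <= 0.5")


def residual_correlation(cfg: SimConfig) -> float:
    """Residual correlation implied by the target phenotypic correlation.

    Solves rp*sPw*sPl = rg*sgw*sgl + re*sew*sel for re, where sg = h*sP and
    se = sqrt(1-h2)*sP per trait.  Raises if the triple (rp, rg, h2s) is
    internally inconsistent (|re| > 1).
    """
    sgw = math.sqrt(cfg.h2_weight) * cfg.sd_weight
    sgl = math.sqrt(cfg.h2_length) * cfg.sd_length
    sew = math.sqrt(1 - cfg.h2_weight) * cfg.sd_weight
    sel = math.sqrt(1 - cfg.h2_length) * cfg.sd_length
    re = (cfg.rp_target * cfg.sd_weight * cfg.sd_length - cfg.rg * sgw * sgl) / (sew * sel)
    if abs(re) > 1:
        raise ValueError(
            "inconsistent correlation structure: rp_target="
            f"{cfg.rp_target}, rg={cfg.rg}, h2=({cfg.h2_weight}, {cfg.h2_length}) "
            f"imply residual correlation {re:.3f} outside [-1, 1]"
        )
    return re


def _le_haplotypes(n_individuals: int, n_loci: int, cfg: SimConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Unrelated haplotype pairs in linkage equilibrium; frequencies of the
    counted allele drawn per locus from Uniform(maf_low, maf_high)."""
    freqs = rng.uniform(cfg.maf_low, cfg.maf_high, size=n_loci)
    return (rng.random((n_individuals, 2, n_loci)) < freqs).astype(np.int8)


def simulate_founders(cfg: SimConfig, genome: GenomeTemplate,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Haplotypes of the 60 broodstock founders.

    Two founder models:

    ``"unrelated"``
        Founders are unrelated and loci are in linkage equilibrium
        (independent Bernoulli alleles at frequencies from the MAF law).

    ``"ancestral_pool"`` (default)
        Founders descend from a closed random-mating ancestral pool of
        ``pool_size`` individuals run for ``pool_generations`` generations
        (pool generation 0 is unrelated/LE as above).  Each founder is the
        offspring of a random distinct pair from the final pool generation.
        This emulates a hatchery strain of limited effective size: founders
        are related, carry some inbreeding, and share long haplotype
        segments, which is what gives marker data predictive power across
        families in real broodstock.

    Returns ``(n_founders, 2, n_loci)`` int8 over the combined
    (marker + QTL) locus layout.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_founders = cfg.n_blocks * (cfg.dams_per_block + cfg.sires_per_block)
    n_loci = genome.n_markers + genome.n_qtl
    if cfg.founder_model == "unrelated":
        return _le_haplotypes(n_founders, n_loci, cfg, rng)
    if cfg.founder_model != "ancestral_pool":
        raise ValueError(f"unknown founder model {cfg.founder_model!r}")

    n_pool = cfg.pool_size
    base = _le_haplotypes(n_pool, n_loci, cfg, rng)
    rows = [(f"A0_{i}", UNKNOWN, UNKNOWN, 0) for i in range(n_pool)]
    prev = [f"A0_{i}" for i in range(n_pool)]
    for gen in range(1, cfg.pool_generations + 1):
        cur = [f"A{gen}_{i}" for i in range(n_pool)]
        for ind in cur:
            s, d = rng.choice(len(prev), size=2, replace=False)
            rows.append((ind, prev[s], prev[d], 0))
        prev = cur
    founder_names = [f"F_{i}" for i in range(n_founders)]
    for ind in founder_names:
        s, d = rng.choice(len(prev), size=2, replace=False)
        rows.append((ind, prev[s], prev[d], 0))
    pool_ped = Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "block"]))
    drop_seed = int(rng.integers(2 ** 31))
    haps = _drop_haplotypes(pool_ped, base, genome, seed=drop_seed)
    return np.stack([haps[f] for f in founder_names])


def mate_partial_factorial(cfg: SimConfig, seed: int | None = None) -> Pedigree:
    """Build the partial factorial pedigree.

    Within each block every dam is crossed with every sire (dams_per_block x
    sires_per_block possible full-sib families).  Family sizes follow a
    Dirichlet-multinomial with per-pair concentration
    ``family_concentration``, which overdisperses sizes relative to a plain
    multinomial; some pairs may receive no offspring.  Blocks are redrawn
    until every parent contributes at least one offspring.
    """
    if cfg.n_offspring < cfg.n_blocks:
        raise ValueError("need at least one offspring per block")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sires = [f"S{i + 1:02d}" for i in range(cfg.n_blocks * cfg.sires_per_block)]
    dams = [f"D{i + 1:02d}" for i in range(cfg.n_blocks * cfg.dams_per_block)]

    rows = []
    for b in range(cfg.n_blocks):
        bs = sires[b * cfg.sires_per_block:(b + 1) * cfg.sires_per_block]
        bd = dams[b * cfg.dams_per_block:(b + 1) * cfg.dams_per_block]
        for s in bs:
            rows.append((s, UNKNOWN, UNKNOWN, b + 1))
        for d in bd:
            rows.append((d, UNKNOWN, UNKNOWN, b + 1))

    base = cfg.n_offspring // cfg.n_blocks
    block_n = [base + (1 if b < cfg.n_offspring % cfg.n_blocks else 0) for b in range(cfg.n_blocks)]

    child = 0
    for b in range(cfg.n_blocks):
        bs = sires[b * cfg.sires_per_block:(b + 1) * cfg.sires_per_block]
        bd = dams[b * cfg.dams_per_block:(b + 1) * cfg.dams_per_block]
        pairs = [(s, d) for s in bs for d in bd]
        for _ in range(1000):
            if math.isinf(cfg.family_concentration):
                probs = np.full(len(pairs), 1.0 / len(pairs))
            else:
                probs = rng.dirichlet(np.full(len(pairs), cfg.family_concentration))
            sizes = rng.multinomial(block_n[b], probs)
            used_s = {pairs[i][0] for i in np.flatnonzero(sizes)}
            used_d = {pairs[i][1] for i in np.flatnonzero(sizes)}
            if len(used_s) == len(bs) and len(used_d) == len(bd):
                break
        else:  # pragma: no cover - essentially impossible at defaults
            raise RuntimeError("could not place offspring with all parents used")
        for (s, d), k in zip(pairs, sizes):
            for _ in range(k):
                child += 1
                rows.append((f"O{child:04d}", s, d, b + 1))

    return Pedigree(pd.DataFrame(rows, columns=["id", "sire", "dam", "block"]))


def _meiosis(hap_pair: np.ndarray, genome: GenomeTemplate, loci_global: np.ndarray,
             loci_lg0: np.ndarray, offsets: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a (2, n_loci) haplotype pair.

    Crossovers per linkage group are Poisson(length/100) with positions
    uniform along the group (Haldane: no interference); the starting
    haplotype of each group is an independent fair coin.
    """
    lengths = genome.lengths_cm
    n_x = rng.poisson(lengths / 100.0)
    total = int(n_x.sum())
    if total:
        groups = np.repeat(np.arange(lengths.size), n_x)
        xpos = offsets[groups] + rng.random(total) * lengths[groups]
        xpos.sort()
        before = np.searchsorted(xpos, loci_global)
    else:
        before = np.zeros(loci_global.size, dtype=int)
    starts = rng.integers(0, 2, size=lengths.size)
    parity = (before + starts[loci_lg0]) & 1
    return np.where(parity == 0, hap_pair[0], hap_pair[1]).astype(np.int8)


def _drop_haplotypes(pedigree: Pedigree, founder_haps: np.ndarray,
                     genome: GenomeTemplate, seed: int = 0) -> dict[str, np.ndarray]:
    """Transmit haplotypes through a pedigree; returns id -> (2, n_loci)."""
    ped = pedigree.table
    order = pedigree.topological_order()
    founder_ids = list(pedigree.founders())
    if founder_haps.shape[0] != len(founder_ids):
        raise ValueError(
            f"founder haplotypes for {founder_haps.shape[0]} individuals but "
            f"pedigree has {len(founder_ids)} founders"
        )
    lg, pos, _ = genome.combined_loci()
    if founder_haps.shape[2] != lg.size:
        raise ValueError("founder haplotype locus dimension does not match genome")
    offsets = np.concatenate([[0.0], np.cumsum(genome.lengths_cm)])[:-1]
    loci_global = offsets[lg - 1] + pos
    loci_lg0 = lg - 1

    rng = np.random.default_rng(seed)
    haps: dict[str, np.ndarray] = {}
    founder_row = {fid: i for i, fid in enumerate(founder_ids)}
    for idx in order:
        ind = ped["id"].iloc[idx]
        sire, dam = ped["sire"].iloc[idx], ped["dam"].iloc[idx]
        if sire == UNKNOWN and dam == UNKNOWN:
            haps[ind] = founder_haps[founder_row[ind]]
        elif sire == UNKNOWN or dam == UNKNOWN:
            raise ValueError(f"{ind!r} has exactly one known parent; gene drop needs both or neither")
        else:
            for parent in (sire, dam):
                if parent not in haps:
                    raise ValueError(f"missing haplotypes for parent {parent!r}")
            g1 = _meiosis(haps[sire], genome, loci_global, loci_lg0, offsets, rng)
            g2 = _meiosis(haps[dam], genome, loci_global, loci_lg0, offsets, rng)
            haps[ind] = np.stack([g1, g2])
    return haps


def gene_drop(pedigree: Pedigree, founder_haps: np.ndarray, genome: GenomeTemplate,
              seed: int = 0) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop founder haplotypes through the pedigree by recombination.

    Founders (in pedigree-table order) take ``founder_haps`` rows; every
    non-founder receives one recombinant gamete from each parent, with
    crossovers Poisson along each linkage group (Haldane, no interference).
    Returns the marker ``GenotypeMatrix`` over all pedigree individuals plus
    an ``(n_individuals, n_qtl)`` QTL dosage array in the same row order.
    """
    haps = _drop_haplotypes(pedigree, founder_haps, genome, seed=seed)
    _, _, is_qtl = genome.combined_loci()
    n_loci = is_qtl.size
    ids = pedigree.ids
    dosage = np.empty((len(ids), n_loci), dtype=np.int8)
    for i, ind in enumerate(ids):
        dosage[i] = haps[ind].sum(axis=0)
    marker_dosage = dosage[:, ~is_qtl]
    qtl_dosage = dosage[:, is_qtl]
    return GenotypeMatrix(marker_dosage, ids, genome.marker_table()), qtl_dosage


def simulate_bivariate_phenotypes(pedigree: Pedigree, qtl_dosage: np.ndarray,
                                  cfg: SimConfig, seed: int = 0
                                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Weight/length phenotypes and true breeding values.

    QTL effects are bivariate normal across traits with correlation ``rg``;
    per-trait genetic values are rescaled so their realized variance among
    offspring equals h2 * sigmaP^2 exactly.  Residuals are bivariate normal
    with the correlation implied by ``rp_target`` (see
    :func:`residual_correlation`); a common block (cross) effect with SD
    ``block_effect_sd_frac * sigmaP`` and across-trait correlation
    ``rp_target`` is added.  Only offspring are phenotyped; breeding values
    are returned for every individual.
    """
    rng = np.random.default_rng(seed)
    re = residual_correlation(cfg)
    ped = pedigree.table
    is_off = (ped["sire"] != UNKNOWN).to_numpy() & (ped["dam"] != UNKNOWN).to_numpy()
    n_all = len(ped)
    h2 = np.array([cfg.h2_weight, cfg.h2_length])
    sd_p = np.array([cfg.sd_weight, cfg.sd_length])
    means = np.array([cfg.mean_weight, cfg.mean_length])

    if cfg.n_qtl == 0 or qtl_dosage.shape[1] == 0:
        if h2.max() > 0:
            raise ValueError("cannot realize h2 > 0 with zero QTL")
        u = np.zeros((n_all, 2))
    else:
        cg = np.array([[1.0, cfg.rg], [cfg.rg, 1.0]])
        effects = rng.multivariate_normal(np.zeros(2), cg, size=qtl_dosage.shape[1])
        u = qtl_dosage.astype(float) @ effects
        for t in range(2):
            target_sd = math.sqrt(h2[t]) * sd_p[t]
            realized = u[is_off, t].std()
            u[:, t] = (u[:, t] - u[is_off, t].mean()) * (target_sd / realized if realized > 0 else 0.0)

    sd_e = np.sqrt(1 - h2) * sd_p
    ce = np.array([[sd_e[0] ** 2, re * sd_e[0] * sd_e[1]],
                   [re * sd_e[0] * sd_e[1], sd_e[1] ** 2]])
    e = rng.multivariate_normal(np.zeros(2), ce, size=int(is_off.sum()))

    sd_b = cfg.block_effect_sd_frac * sd_p
    cb = np.array([[sd_b[0] ** 2, cfg.rp_target * sd_b[0] * sd_b[1]],
                   [cfg.rp_target * sd_b[0] * sd_b[1], sd_b[1] ** 2]])
    blocks = sorted(ped["block"].unique())
    block_eff = {b: v for b, v in zip(blocks, rng.multivariate_normal(np.zeros(2), cb, size=len(blocks)))}

    off = ped.loc[is_off]
    beff = np.stack([block_eff[b] for b in off["block"]])
    y = means + beff + u[is_off] + e
    phenotypes = pd.DataFrame(
        {"id": off["id"].to_numpy(), "weight_g": y[:, 0], "length_mm": y[:, 1],
         "cross": off["block"].to_numpy()}
    )
    tbv = pd.DataFrame({"id": ped["id"].to_numpy(), "weight_g": u[:, 0], "length_mm": u[:, 1]})
    return phenotypes, tbv


def apply_genotyping_noise(g: GenotypeMatrix, error_rate: float, missing_rate: float,
                           seed: int = 0) -> GenotypeMatrix:
    """Overlay genotyping error and missingness on a clean matrix.

    Each call is independently set missing with ``missing_rate``; surviving
    calls are replaced, with probability ``error_rate``, by one of the two
    other dosages chosen uniformly (symmetric error).  The input is left
    untouched.
    """
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    d = g.dosages.copy()
    present = d != MISSING
    if missing_rate > 0:
        drop = present & (rng.random(d.shape) < missing_rate)
        d[drop] = MISSING
        present &= ~drop
    if error_rate > 0:
        err = present & (rng.random(d.shape) < error_rate)
        shift = rng.integers(1, 3, size=int(err.sum()), dtype=np.int8)
        d[err] = (d[err] + shift) % 3
    return GenotypeMatrix(d, g.samples.copy(), g.markers.copy())


@dataclass
class TruePopulation:
    """A fully simulated study population with known ground truth."""

    config: SimConfig
    genome: GenomeTemplate
    pedigree: Pedigree
    genotypes_clean: GenotypeMatrix
    genotypes_observed: GenotypeMatrix
    qtl_dosage: np.ndarray
    phenotypes: pd.DataFrame
    true_breeding_values: pd.DataFrame

    @property
    def parent_ids(self) -> np.ndarray:
        return self.pedigree.founders()

    @property
    def offspring_ids(self) -> np.ndarray:
        return self.pedigree.offspring()


def simulate_population(cfg: SimConfig, genome: GenomeTemplate | None = None,
                        n_markers: int = TOTAL_MAP_SNPS) -> TruePopulation:
    """Run the full generator: genome, pedigree, gene drop, phenotypes, noise.

    All randomness derives from ``cfg.seed`` through independent spawned
    streams, so identical configs give byte-identical populations.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_genome, s_found, s_mate, s_drop, s_pheno, s_noise = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(6)
    ]
    if genome is None:
        genome = build_genome_template(n_markers=n_markers, n_qtl=cfg.n_qtl, seed=s_genome)
    pedigree = mate_partial_factorial(cfg, seed=s_mate)
    founders = simulate_founders(cfg, genome, rng=np.random.default_rng(s_found))
    geno_clean, qtl_dosage = gene_drop(pedigree, founders, genome, seed=s_drop)
    phenotypes, tbv = simulate_bivariate_phenotypes(pedigree, qtl_dosage, cfg, seed=s_pheno)
    geno_obs = apply_genotyping_noise(
        geno_clean, cfg.genotyping_error_rate, cfg.missing_rate, seed=s_noise
    )
    return TruePopulation(
        config=cfg, genome=genome, pedigree=pedigree,
        genotypes_clean=geno_clean, genotypes_observed=geno_obs,
        qtl_dosage=qtl_dosage, phenotypes=phenotypes, true_breeding_values=tbv,
    )
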