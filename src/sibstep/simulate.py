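"""Synthetic breeding-design generator.

Emulates a multi-generation aquaculture breeding program with semi-nested
matings (one sire to one or two dams), separate family rearing (which
induces a family-shared environmental effect), gene dropping over a SNP
panel, and a tagging-weight phenotype

    y = generation + batch + age-slope * (age - age_center)
        + breeding value + family effect + residual

so that downstream pedigree/genomic evaluations can be tested against a
known truth.  Family sizes follow a truncated negative binomial; ages and
spawning batches are assigned per family (a family is spawned and tagged
together).  All randomness flows from the configured seed through fixed
per-stage streams, so each operation is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genomic import MISSING, GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "TrueValues",
    "SimulatedData",
    "full_scale_config",
    "reduced_config",
    "simulate_pedigree",
    "drop_genes",
    "simulate_phenotypes",
    "mask_genotypes",
    "simulate_dataset",
]

# fixed sub-stream keys so each stage is independently reproducible
_STREAM_PEDIGREE, _STREAM_GENES, _STREAM_PHENO, _STREAM_MASK = 11, 13, 17, 19


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are set by the preset helpers."""

    seed: int
    families_per_generation: tuple[int, ...] = (179, 167, 93)
    parent_generation: tuple[int | None, ...] = (None, 0, 0)
    offspring_mean: float = 27.1
    offspring_min: int = 10
    offspring_max: int = 87
    offspring_dispersion: float = 3.0  # negative-binomial size parameter r
    mating_ratio: int = 2  # one sire serves 1..mating_ratio dams
    batches_per_generation: tuple[int, ...] = (9, 4, 7)
    age_ranges: tuple[tuple[int, int], ...] = ((149, 208), (132, 180), (132, 222))
    age_center: float = 172.2
    age_slope: float = 0.05  # g per day
    n_snp: int = 14_154
    n_qtl: int = 500
    founder_maf: tuple[float, float] = (0.05, 0.5)
    sigma_g: float = 22.5  # g^2; with sigma_c, sigma_e gives h2=.15, c2=.71
    sigma_c: float = 106.5
    sigma_e: float = 21.0
    mean_weight: float = 22.7  # g, population target
    generation_means: tuple[float, ...] | None = None  # derived when None
    generation_targets: tuple[float, ...] | None = (23.9, 20.8, 25.0)
    batch_sd: float = 1.5  # g
    genotyped_generation: int = 1
    genotyped_families: int = 40
    genotyped_individuals: int = 560
    missing_rate: float = 0.10
    # second trait (survival time after challenge, d) for bivariate mode
    genetic_correlation: float = 0.3
    survival_mean: float = 21.0
    survival_sigma_g: float = 20.0
    survival_sigma_c: float = 15.0
    survival_sigma_e: float = 65.0
    hide_qtl: bool = False

    def __post_init__(self):
        if min(self.families_per_generation) <= 0 or self.n_snp <= 0:
            raise ValueError("counts must be positive")
        if self.n_qtl > self.n_snp:
            raise ValueError("n_qtl cannot exceed n_snp")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate {self.missing_rate} outside [0, 1]")
        if min(self.sigma_g, self.sigma_c, self.sigma_e) < 0:
            raise ValueError("variance components must be non-negative")
        if not self.offspring_min <= self.offspring_mean <= self.offspring_max:
            raise ValueError("offspring mean outside [min, max]")
        if len(self.parent_generation) != len(self.families_per_generation):
            raise ValueError("parent_generation must match families_per_generation")


@dataclass
class TrueValues:
    """Simulation truth for parameter-recovery tests."""

    animal_ids: np.ndarray
    tbv: np.ndarray  # g, aligned with animal_ids
    qtl_ids: np.ndarray
    qtl_effects: np.ndarray  # g per allele copy
    family_effect: dict[str, float] = field(default_factory=dict)
    tbv2: np.ndarray | None = None  # second-trait breeding values


@dataclass
class SimulatedData:
    config: SimConfig
    pedigree: Pedigree
    families: pd.DataFrame
    genotypes_all: GenotypeMatrix
    truth: TrueValues
    phenotypes: pd.DataFrame
    panel: GenotypeMatrix  # observed (masked) genotyped subset


def full_scale_config(seed: int, **overrides) -> SimConfig:
    """Full-scale calibration: 439 families in three cohorts, ~11.9k records,
    14,154 SNPs on 560 genotyped fish from 40 families, 10% missingness."""
    return replace(SimConfig(seed=seed), **overrides) if overrides else SimConfig(seed=seed)


def reduced_config(seed: int, **overrides) -> SimConfig:
    """Desk-scale variant preserving the study's statistical structure:
    150 families of ~25 offspring, 2,000 SNPs, 500 genotyped fish."""
    cfg = SimConfig(
        seed=seed,
        families_per_generation=(61, 57, 32),
        offspring_mean=25.0,
        n_snp=2_000,
        n_qtl=200,
        genotyped_families=40,
        genotyped_individuals=500,
    )
    return replace(cfg, **overrides) if overrides else cfg


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


def _truncated_nbinom(mean: float, lo: int, hi: int, r: float):
    """Negative binomial conditioned on [lo, hi], untruncated mean solved so
    the truncated mean hits the target."""
    if lo == hi:
        return None  # degenerate: constant family size

    support = np.arange(lo, hi + 1)

    def trunc_mean(m):
        p = r / (r + m)
        w = stats.nbinom.pmf(support, r, p)
        return float(np.sum(support * w) / np.sum(w))

    lo_m, hi_m = 0.2, 4.0 * hi
    if mean <= trunc_mean(lo_m):
        m = lo_m  # target at the truncation floor: most mass on lo
    elif mean >= trunc_mean(hi_m):
        m = hi_m
    else:
        m = optimize.brentq(lambda x: trunc_mean(x) - mean, lo_m, hi_m, xtol=1e-6)
    p = r / (r + m)
    w = stats.nbinom.pmf(support, r, p)
    return support, w / w.sum()


def _draw_family_sizes(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    law = _truncated_nbinom(
        config.offspring_mean, config.offspring_min, config.offspring_max,
        config.offspring_dispersion,
    )
    if law is None:
        return np.full(n, config.offspring_min, dtype=np.int64)
    support, w = law
    return rng.choice(support, size=n, p=w)


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Generate the multi-cohort pedigree.

    Cohort 0 parents are fresh founders; later cohorts draw their parents
    from the offspring of the configured parent cohort.  The returned
    Pedigree carries a ``families`` DataFrame (family_id, sire/dam,
    generation, batch, age_d, size) describing the rearing design.
    """
    rng = _rng(config, _STREAM_PEDIGREE)
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    gen: list[str] = []
    fam: list[str] = []
    cohort_members: dict[int, list[int]] = {}  # 1-based codes of offspring
    fam_rows = []

    def new_animal(s: int, d: int, g: str, f: str) -> int:
        ids.append(str(len(ids) + 1))
        sire.append(s)
        dam.append(d)
        gen.append(g)
        fam.append(f)
        return len(ids)

    batch_offset = 0
    for c, n_fam in enumerate(config.families_per_generation):
        sizes = _draw_family_sizes(config, n_fam, rng)
        parent_cohort = config.parent_generation[c]
        if parent_cohort is None:
            pool = None
        else:
            pool = np.asarray(cohort_members.get(parent_cohort, []), dtype=np.int64)
        # semi-nested matings: draw sires, each serving 1..mating_ratio dams
        n_dams = n_fam
        shares = []
        while sum(shares) < n_dams:
            shares.append(int(rng.integers(1, config.mating_ratio + 1)))
        shares[-1] -= sum(shares) - n_dams
        n_sires = len(shares)
        if pool is None:
            sire_codes = [new_animal(0, 0, f"G{c}", "") for _ in range(n_sires)]
            dam_codes = [new_animal(0, 0, f"G{c}", "") for _ in range(n_dams)]
        else:
            if len(pool) < n_sires + n_dams:
                raise ValueError(
                    f"cohort {c}: {n_fam} families need {n_sires + n_dams} parents "
                    f"but cohort {parent_cohort} has only {len(pool)} candidates"
                )
            picked = rng.choice(pool, size=n_sires + n_dams, replace=False)
            sire_codes = list(picked[:n_sires])
            dam_codes = list(picked[n_sires:])

        n_batches = config.batches_per_generation[min(c, len(config.batches_per_generation) - 1)]
        age_lo, age_hi = config.age_ranges[min(c, len(config.age_ranges) - 1)]
        fam_idx = 0
        members: list[int] = []
        for si, k in zip(sire_codes, shares):
            for _ in range(k):
                di = dam_codes[fam_idx]
                fid = f"F{c}_{fam_idx + 1}"
                batch = f"B{batch_offset + int(rng.integers(0, n_batches)) + 1}"
                age = int(rng.integers(age_lo, age_hi + 1))
                size = int(sizes[fam_idx])
                for _ in range(size):
                    members.append(new_animal(int(si), int(di), f"G{c}", fid))
                fam_rows.append(
                    dict(family_id=fid, sire=int(si), dam=int(di), generation=f"G{c}",
                         batch=batch, age_d=age, size=size)
                )
                fam_idx += 1
        cohort_members[c] = members
        batch_offset += n_batches

    ped = Pedigree(
        np.asarray(ids, dtype=object),
        np.asarray(sire, dtype=np.int32),
        np.asarray(dam, dtype=np.int32),
        np.asarray(gen, dtype=object),
        np.asarray(fam, dtype=object),
    )
    ped.families = pd.DataFrame(fam_rows)  # design metadata rides along
    return ped


def drop_genes(ped: Pedigree, config: SimConfig) -> tuple[GenotypeMatrix, TrueValues]:
    """Gene-drop the SNP panel through the pedigree and derive true
    breeding values from a random QTL subset.

    Founders are Hardy-Weinberg draws at frequencies from the configured
    MAF law; every offspring inherits one allele per parent per locus
    independently.  QTL effects are normal and rescaled so the founder TBV
    variance matches sigma_g.
    """
    rng = _rng(config, _STREAM_GENES)
    n, m = ped.n_animals, config.n_snp
    q = rng.uniform(*config.founder_maf, size=m)
    geno = np.empty((n, m), dtype=np.int8)

    founder = ped.is_founder
    n_found = int(founder.sum())
    geno[founder] = rng.binomial(2, q, size=(n_found, m)).astype(np.int8)

    # Mendelian transmission level by level (an animal's parents always sit
    # in an earlier level, so their rows are complete before being read)
    level = np.zeros(n, dtype=np.int64)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        lp = 0
        if s:
            lp = level[s - 1] + 1
        if d:
            lp = max(lp, level[d - 1] + 1)
        level[i] = lp
    for lev in range(1, int(level.max()) + 1):
        todo = np.flatnonzero(level == lev)
        sire0 = ped.sire[todo] - 1
        dam0 = ped.dam[todo] - 1
        for start in range(0, len(todo), 2048):
            sl = slice(start, start + 2048)
            gs = geno[sire0[sl]].astype(np.float32) / 2.0
            gd = geno[dam0[sl]].astype(np.float32) / 2.0
            u = rng.random(gs.shape, dtype=np.float32)
            v = rng.random(gs.shape, dtype=np.float32)
            geno[todo[sl]] = (u < gs).astype(np.int8) + (v < gd).astype(np.int8)

    qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    alpha = rng.standard_normal(config.n_qtl)
    zf = geno[founder][:, qtl_idx].astype(float)
    zf -= zf.mean(axis=0)
    tbv_f = zf @ alpha
    sd = tbv_f.std()
    if sd > 0 and config.sigma_g > 0:
        alpha *= np.sqrt(config.sigma_g) / sd
    elif config.sigma_g == 0:
        alpha[:] = 0.0
    zc = geno[:, qtl_idx].astype(float)
    zc -= zc[founder].mean(axis=0)
    tbv = zc @ alpha

    snp_ids = np.asarray([f"SNP{j + 1}" for j in range(m)], dtype=object)
    gm = GenotypeMatrix(ped.ids.copy(), snp_ids, geno)
    truth = TrueValues(ped.ids.copy(), tbv, snp_ids[qtl_idx], alpha)
    return gm, truth


def _polygenic_standard(ped: Pedigree, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance pedigree-structured polygenic deviate (infinitesimal
    gene flow: parent average plus Mendelian sampling)."""
    n = ped.n_animals
    w = np.zeros(n + 1)
    mend = rng.standard_normal(n)
    F = np.concatenate(([-1.0], ped.inbreeding))
    for i in range(1, n + 1):
        s, d = ped.sire[i - 1], ped.dam[i - 1]
        var_m = 0.5 - 0.25 * (F[s] + F[d])
        w[i] = 0.5 * (w[s] + w[d]) + np.sqrt(var_m) * mend[i - 1]
    return w[1:]


def default_generation_means(config: SimConfig) -> tuple[float, ...]:
    """Cohort means calibrated so the expected population mean equals the
    target, honouring the per-cohort spread of the study data and
    compensating the age-covariate offsets."""
    k = len(config.families_per_generation)
    w = np.asarray(config.families_per_generation, float)
    w /= w.sum()
    if config.generation_targets is not None and len(config.generation_targets) == k:
        tgt = np.asarray(config.generation_targets, float)
    else:
        tgt = np.full(k, config.mean_weight)
    tgt = tgt + (config.mean_weight - float(w @ tgt))
    age_mid = np.asarray([(a + b) / 2.0 for (a, b) in config.age_ranges[:k]], float)
    return tuple(tgt - config.age_slope * (age_mid - config.age_center))


def simulate_phenotypes(
    ped: Pedigree, truth: TrueValues, config: SimConfig
) -> pd.DataFrame:
    """Tagging-weight (and survival-time) records for all non-founder animals.

    Family environmental effects are drawn once per full-sib family with
    variance sigma_c; residuals are iid normal.  The second trait shares
    the pedigree structure with genetic correlation ``genetic_correlation``.
    """
    if min(config.sigma_g, config.sigma_c, config.sigma_e) < 0:
        raise ValueError("negative variance components")
    rng = _rng(config, _STREAM_PHENO)
    fam_df: pd.DataFrame = ped.families
    gen_means = (
        config.generation_means
        if config.generation_means is not None
        else default_generation_means(config)
    )
    gen_lab = sorted(set(fam_df["generation"]))
    gmean = {g: gen_means[i] for i, g in enumerate(gen_lab)}
    batches = sorted(set(fam_df["batch"]))
    beffect = dict(zip(batches, rng.normal(0.0, config.batch_sd, size=len(batches))))
    feffect = dict(
        zip(fam_df["family_id"], rng.normal(0.0, np.sqrt(config.sigma_c), size=len(fam_df)))
    )
    truth.family_effect = dict(feffect)

    rec = ~ped.is_founder
    idx = np.flatnonzero(rec)
    fam_info = fam_df.set_index("family_id")
    fams = ped.family[idx]
    age = fam_info["age_d"].reindex(fams).to_numpy(float)
    batch = fam_info["batch"].reindex(fams).to_numpy(object)
    genl = ped.generation[idx]
    mu = np.asarray([gmean[g] for g in genl])
    be = np.asarray([beffect[b] for b in batch])
    fe = np.asarray([feffect[f] for f in fams])
    e = rng.normal(0.0, np.sqrt(config.sigma_e), size=len(idx))
    y = mu + be + config.age_slope * (age - config.age_center) + truth.tbv[idx] + fe + e

    # second trait on the same families (challenge-test survival time)
    w2 = _polygenic_standard(ped, rng)
    tbv_std = truth.tbv / np.sqrt(config.sigma_g) if config.sigma_g > 0 else w2 * 0.0
    rg = config.genetic_correlation
    tbv2 = np.sqrt(config.survival_sigma_g) * (rg * tbv_std + np.sqrt(max(0.0, 1 - rg**2)) * w2)
    truth.tbv2 = tbv2
    fe2 = dict(
        zip(fam_df["family_id"], rng.normal(0.0, np.sqrt(config.survival_sigma_c), size=len(fam_df)))
    )
    e2 = rng.normal(0.0, np.sqrt(config.survival_sigma_e), size=len(idx))
    y2 = (
        config.survival_mean
        + tbv2[idx]
        + np.asarray([fe2[f] for f in fams])
        + e2
    )

    return pd.DataFrame(
        {
            "animal_id": ped.ids[idx],
            "tag_weight_g": y,
            "age_d": age,
            "generation": genl,
            "batch": batch,
            "family_id": fams,
            "survival_time_d": y2,
        }
    )


def select_genotyped(
    ped: Pedigree, config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sample the genotyped subset: ``genotyped_individuals`` fish drawn from
    ``genotyped_families`` random families of the configured cohort."""
    if rng is None:
        rng = _rng(config, _STREAM_MASK)
    fam_df: pd.DataFrame = ped.families
    lab = f"G{config.genotyped_generation}"
    pool_fams = fam_df.loc[fam_df["generation"] == lab, "family_id"].to_numpy()
    if len(pool_fams) < config.genotyped_families:
        raise ValueError(
            f"cohort {lab} has {len(pool_fams)} families < {config.genotyped_families}"
        )
    fams = rng.choice(pool_fams, size=config.genotyped_families, replace=False)
    members = np.flatnonzero(np.isin(ped.family, fams))
    if len(members) < config.genotyped_individuals:
        raise ValueError(
            f"selected families hold {len(members)} fish < {config.genotyped_individuals}"
        )
    chosen = rng.choice(members, size=config.genotyped_individuals, replace=False)
    return np.sort(chosen)


def mask_genotypes(
    genotypes: GenotypeMatrix, config: SimConfig, ped: Pedigree | None = None
) -> GenotypeMatrix:
    """Export the observed panel: genotyped subset with exactly
    round(missing_rate x cells) entries set to the missing code.

    When ``ped`` is given the subset is sampled per the config; otherwise
    ``genotypes`` is taken to be the panel already.
    """
    if not 0.0 <= config.missing_rate <= 1.0:
        raise ValueError(f"missing_rate {config.missing_rate} outside [0, 1]")
    rng = _rng(config, _STREAM_MASK)
    if ped is not None:
        rows = select_genotyped(ped, config, rng=rng)
        vals = genotypes.values[rows].copy()
        samples = genotypes.sample_ids[rows]
    else:
        vals = genotypes.values.copy()
        samples = genotypes.sample_ids.copy()
    n_cells = vals.size
    n_miss = int(round(config.missing_rate * n_cells))
    if n_miss:
        flat = rng.choice(n_cells, size=n_miss, replace=False)
        vals.ravel()[flat] = MISSING
    return GenotypeMatrix(samples, genotypes.snp_ids.copy(), vals)


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """One full draw of the breeding design: pedigree, genotypes, truth,
    phenotypes and the observed (masked) genotype panel."""
    ped = simulate_pedigree(config)
    geno, truth = drop_genes(ped, config)
    pheno = simulate_phenotypes(ped, truth, config)
    panel = mask_genotypes(geno, config, ped=ped)
    if config.hide_qtl:
        keep = ~np.isin(panel.snp_ids, truth.qtl_ids)
        panel = GenotypeMatrix(panel.sample_ids, panel.snp_ids[keep], panel.values[:, keep])
    return SimulatedData(config, ped, ped.families, geno, truth, pheno, panel)
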