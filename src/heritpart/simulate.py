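"""Synthetic wild-pedigree studies: pedigree, genotypes, traits.

The generator emulates the statistical structure of a long-term study of a
promiscuous wild ungulate population: a multigenerational pedigree in which
both sexes mate with several partners (so half-sib pairs vastly outnumber
full-sib pairs), unlinked biallelic SNPs gene-dropped from Hardy-Weinberg
founders, quantitative traits composed of additive, family-associated,
maternal, cohort and permanent-environment variance, with repeated records
for adults, and single-locus categorical traits with dominant or codominant
(optionally sex-dependent) architectures.

Every draw flows from one :class:`numpy.random.Generator` seeded in the
:class:`SimulationConfig`, so identical configurations reproduce identical
studies byte for byte.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TraitArchitecture",
    "MonogenicLocus",
    "SimulatedStudy",
    "simulate_pedigree",
    "drop_genotypes",
    "simulate_polygenic_trait",
    "simulate_monogenic_trait",
    "simulate_study",
    "encode_monogenic",
]


@dataclasses.dataclass
class TraitArchitecture:
    """Variance composition of one simulated quantitative trait.

    Fractions are of the total phenotypic variance (normalised to 1) and
    must sum to at most 1; the remainder is the residual.  ``family_mode``:

    * ``"genetic"`` — family-associated genetic effect drawn MVN with
      covariance ``c * (M_t + lambda I)`` where ``M_t`` is the
      relatedness-thresholded GRM, ``lambda`` the smallest spectrum lift
      making it positive semidefinite and ``c = family_fraction``; the
      white ``c * lambda`` part is charged to the residual budget, so the
      coefficient on ``M_t`` — the two-GRM model's kinship variance — is
      exactly ``family_fraction``;
    * ``"common_env"`` — a deviate shared by all offspring of one mother;
    * ``"dominance"`` — per-causal-SNP dominance deviations (heterozygote
      effects), a within-family genetic source.
    """

    name: str = "trait"
    h2_additive: float = 0.3
    family_fraction: float = 0.0
    family_mode: str = "genetic"
    family_threshold: float = 0.1
    maternal_fraction: float = 0.0
    year_fraction: float = 0.0
    perm_env_fraction: float = 0.0
    n_causal: int = 200
    records_per_individual: int = 1
    sex_effect: float = 0.5
    age_slope: float = 0.1

    def __post_init__(self) -> None:
        fracs = (self.h2_additive, self.family_fraction, self.maternal_fraction,
                 self.year_fraction, self.perm_env_fraction)
        if any(f < 0 for f in fracs):
            raise ValueError("variance fractions must be >= 0")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError(f"variance fractions sum to {sum(fracs)} > 1")
        if self.family_mode not in ("genetic", "common_env", "dominance"):
            raise ValueError(f"unknown family_mode {self.family_mode!r}")
        if self.records_per_individual < 1:
            raise ValueError("records_per_individual must be >= 1")

    @property
    def residual_fraction(self) -> float:
        return 1.0 - (self.h2_additive + self.family_fraction
                      + self.maternal_fraction + self.year_fraction
                      + self.perm_env_fraction)


@dataclasses.dataclass
class MonogenicLocus:
    """Single-locus categorical architecture.

    ``pattern`` maps genotype dosage to phenotype class: "dominant" gives
    two classes ({0} vs {1,2} copies of the counted allele) and
    "codominant" three.  ``sex_patterns`` optionally overrides the pattern
    per sex (e.g. dominant in males, codominant in females, as for horn
    type).  ``misclassification_rate`` relabels that fraction of records
    uniformly at random among the observed classes.
    """

    snp_id: str
    pattern: str = "dominant"
    sex_patterns: Optional[dict[str, str]] = None
    misclassification_rate: float = 0.0

    def __post_init__(self) -> None:
        pats = [self.pattern] + list((self.sex_patterns or {}).values())
        for p in pats:
            if p not in ("dominant", "codominant"):
                raise ValueError(f"unknown dominance pattern {p!r}")


@dataclasses.dataclass
class SimulationConfig:
    """Study-level generator settings.

    Defaults give a desk-scale analogue of a multigenerational wild sheep
    study: overlapping generations, promiscuous mating (mean mate count per
    breeding female well above 1 across years), litter size mostly 1-2, and
    a few thousand unlinked SNPs with founder frequencies drawn
    Uniform(0.05, 0.5) on the counted allele.
    """

    seed: int
    n_founders: int = 100
    n_generations: int = 5
    offspring_per_generation: int = 120
    litter_size_mean: float = 1.08
    parent_overlap_prob: float = 0.25
    n_snps: int = 2000
    founder_freq_low: float = 0.05
    founder_freq_high: float = 0.5
    traits: list[TraitArchitecture] = dataclasses.field(default_factory=list)
    monogenic: list[MonogenicLocus] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_founders < 2 or self.n_generations < 1:
            raise ValueError("need n_founders >= 2 and n_generations >= 1")
        if not (0.0 < self.founder_freq_low <= self.founder_freq_high < 1.0):
            raise ValueError("founder frequency bounds must satisfy 0 < low <= high < 1")


@dataclasses.dataclass
class SimulatedStudy:
    """A generated study with its ground truth."""

    config: SimulationConfig
    pedigree: pd.DataFrame
    sex: pd.Series
    birth_year: pd.Series
    genotypes: GenotypeMatrix
    phenotypes: dict[str, pd.DataFrame]
    truth: dict


def simulate_pedigree(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Overlapping-generation pedigree under promiscuous mating.

    Founders (generation 0) have unknown parents.  Each later generation is
    built by drawing mothers (in litters of ``1 + Poisson(litter_size_mean
    - 1)``) and, independently for each litter, a sire — so maternal sibs
    from different litters and paternal sibs across mothers are both half
    sibs, and full sibs arise only within a litter or by chance re-pairing.
    With probability ``parent_overlap_prob`` a parent is drawn from two
    generations back instead of the previous one.

    Returns ``(pedigree, sex, birth_year)``; sexes are Bernoulli(1/2).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ids: list[str] = []
    sires: list[Optional[str]] = []
    dams: list[Optional[str]] = []
    sex: list[str] = []
    year: list[int] = []

    def add(ind_sire, ind_dam, gen):
        i = f"ind{len(ids):05d}"
        ids.append(i)
        sires.append(ind_sire)
        dams.append(ind_dam)
        sex.append("M" if rng.random() < 0.5 else "F")
        year.append(gen)
        return i

    for _ in range(cfg.n_founders):
        add(None, None, 0)

    by_gen: dict[int, list[int]] = {0: list(range(cfg.n_founders))}
    for gen in range(1, cfg.n_generations):
        pools = [by_gen.get(gen - 1, []), by_gen.get(gen - 2, [])]
        members: list[int] = []
        while len(members) < cfg.offspring_per_generation:
            use_older = rng.random() < cfg.parent_overlap_prob and pools[1]
            pool_d = pools[1] if use_older else pools[0]
            use_older_s = rng.random() < cfg.parent_overlap_prob and pools[1]
            pool_s = pools[1] if use_older_s else pools[0]
            mothers = [i for i in pool_d if sex[i] == "F"]
            fathers = [i for i in pool_s if sex[i] == "M"]
            if not mothers or not fathers:
                mothers = mothers or [i for p in pools for i in p if sex[i] == "F"]
                fathers = fathers or [i for p in pools for i in p if sex[i] == "M"]
            if not mothers or not fathers:
                raise ValueError(
                    f"no available mates in generation {gen}: "
                    f"{len(mothers)} mothers, {len(fathers)} fathers"
                )
            dam = ids[rng.choice(mothers)]
            sire = ids[rng.choice(fathers)]
            litter = 1 + rng.poisson(max(cfg.litter_size_mean - 1.0, 0.0))
            for _ in range(litter):
                if len(members) >= cfg.offspring_per_generation:
                    break
                add(sire, dam, gen)
                members.append(len(ids) - 1)
        by_gen[gen] = members

    ped = pd.DataFrame({"id": ids, "sire": sires, "dam": dams}, dtype="string")
    return (
        ped,
        pd.Series(sex, index=ids, name="sex"),
        pd.Series(year, index=ids, name="birth_year"),
    )


def drop_genotypes(
    ped: pd.DataFrame, cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """Gene-drop unlinked SNPs down the pedigree.

    Founders are Hardy-Weinberg draws at per-SNP frequencies; each
    non-founder receives one Mendelian allele per parent per SNP
    (Bernoulli(parent dosage / 2)), loci independent.  The realised GRM of
    the output converges to the pedigree A matrix in expectation as the SNP
    count grows.
    """
    from .pedigree import _topological_order, _normalise

    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    p = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, size=cfg.n_snps)
    norm = _normalise(ped)
    order = _topological_order(norm)
    ped = norm.set_index("id").loc[order].reset_index()
    ids = ped["id"].tolist()
    pos = {s: i for i, s in enumerate(ids)}
    dos = np.zeros((len(ids), cfg.n_snps), dtype=np.int8)
    for row in ped.itertuples():
        i = pos[row.id]
        if pd.isna(row.sire) and pd.isna(row.dam):
            dos[i] = rng.binomial(2, p)
        else:
            for parent in (row.sire, row.dam):
                if pd.isna(parent):
                    dos[i] += rng.binomial(1, p)  # unknown parent: population draw
                else:
                    dos[i] += rng.binomial(1, dos[pos[parent]] / 2.0)
    n_chrom = 26
    chrom = rng.integers(1, n_chrom + 1, size=cfg.n_snps)
    position = rng.integers(1, 100_000_000, size=cfg.n_snps)
    snp_order = np.lexsort((position, chrom))
    snps = pd.DataFrame({
        "snp_id": [f"snp{j:05d}" for j in range(cfg.n_snps)],
        "chromosome": chrom[snp_order].astype(str),
        "position_bp": position[snp_order],
        "counted_allele": "A",
        "other_allele": "B",
    })
    return GenotypeMatrix(dos[:, snp_order].astype(float), ids, snps)


def _thresholded_family_covariance(genotypes, threshold):
    from .grm import build_grm, threshold_grm

    # fixation can occur during gene dropping; use the polymorphic panel
    p = np.nanmean(genotypes.dosages, axis=0) / 2.0
    poly = [s for s, v in zip(genotypes.snps["snp_id"], p) if 0.0 < v < 1.0]
    grm = build_grm(genotypes, snp_subset=poly)
    return threshold_grm(grm, threshold).values


def simulate_polygenic_trait(
    study_or_genotypes,
    arch: TraitArchitecture,
    ped: Optional[pd.DataFrame] = None,
    sex: Optional[pd.Series] = None,
    birth_year: Optional[pd.Series] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate records of a quantitative trait on the genotyped pedigree.

    The phenotype is built as a sum of independent parts, each rescaled so
    its realised variance matches the target fraction (total variance 1):
    additive breeding values from ``n_causal`` random panel SNPs, a
    family-associated effect (see :class:`TraitArchitecture`), maternal and
    birth-year deviates, a permanent-environment deviate, fixed sex and age
    effects, and a fresh residual per record.  Adults carry
    ``records_per_individual`` records sharing all individual-level parts.

    Returns ``(records, truth)`` where truth holds breeding values, each
    variance part and the realised fractions.
    """
    if isinstance(study_or_genotypes, SimulatedStudy):
        st = study_or_genotypes
        genotypes, ped = st.genotypes, st.pedigree
        sex, birth_year = st.sex, st.birth_year
    else:
        genotypes = study_or_genotypes
        if ped is None or sex is None or birth_year is None:
            raise ValueError("ped, sex and birth_year are required")
    rng = rng if rng is not None else np.random.default_rng(0)

    n = genotypes.n_individuals
    ids = genotypes.sample_ids

    def scaled(values: np.ndarray, target: float) -> np.ndarray:
        sd = values.std()
        if target <= 0 or sd == 0:
            return np.zeros_like(values)
        return values * np.sqrt(target) / sd

    causal = rng.choice(genotypes.n_snps, size=min(arch.n_causal, genotypes.n_snps),
                        replace=False)
    dc = genotypes.dosages[:, causal]
    dc = dc - dc.mean(axis=0)
    bv = scaled(dc @ rng.normal(size=len(causal)), arch.h2_additive)

    dams = ped.set_index("id")["dam"].reindex(ids)
    family_white = 0.0
    if arch.family_fraction > 0:
        if arch.family_mode == "common_env":
            fam_labels = dams.fillna(pd.Series(ids, index=ids))  # orphans: own family
            uniq = fam_labels.unique()
            dev = pd.Series(rng.normal(size=len(uniq)), index=uniq)
            fam = scaled(fam_labels.map(dev).to_numpy(float), arch.family_fraction)
        elif arch.family_mode == "dominance":
            het = (genotypes.dosages[:, causal] == 1).astype(float)
            het = het - het.mean(axis=0)
            fam = scaled(het @ rng.normal(size=len(causal)), arch.family_fraction)
        else:  # "genetic": MVN with covariance c * (M_t + lambda I)
            # The thresholded GRM M_t is indefinite, so c*M_t alone is not a
            # covariance.  Lifting the spectrum by lambda = |min eigenvalue|
            # gives cov = c*M_t + c*lambda*I; the white part is charged to
            # the residual budget below, so the coefficient on M_t — the
            # quantity the two-GRM model estimates — is exactly
            # family_fraction.
            cov = _thresholded_family_covariance(genotypes, arch.family_threshold)
            w, U = np.linalg.eigh(cov)
            lam = max(0.0, -float(w.min())) + 1e-10
            c = arch.family_fraction
            family_white = c * lam
            if family_white > arch.residual_fraction:
                raise ValueError(
                    "residual fraction too small to absorb the spectrum lift "
                    f"of the family covariance ({family_white:.3f} needed)"
                )
            fam = U @ (np.sqrt(c * (w + lam)) * rng.normal(size=n))
    else:
        fam = np.zeros(n)

    if arch.maternal_fraction > 0:
        uniq = dams.dropna().unique()
        dev = pd.Series(rng.normal(size=len(uniq)), index=uniq)
        mat = scaled(dams.map(dev).fillna(0.0).to_numpy(float),
                     arch.maternal_fraction)
    else:
        mat = np.zeros(n)

    yr = birth_year.reindex(ids)
    if arch.year_fraction > 0:
        uniq = yr.unique()
        dev = pd.Series(rng.normal(size=len(uniq)), index=uniq)
        year_eff = scaled(yr.map(dev).to_numpy(float), arch.year_fraction)
    else:
        year_eff = np.zeros(n)

    pe = (scaled(rng.normal(size=n), arch.perm_env_fraction)
          if arch.perm_env_fraction > 0 else np.zeros(n))

    indiv_part = bv + fam + mat + year_eff + pe
    sex_vec = sex.reindex(ids).to_numpy()

    rows = []
    resid_fraction = arch.residual_fraction - family_white
    for rep in range(arch.records_per_individual):
        age = 2.0 + rep
        resid = scaled(rng.normal(size=n), resid_fraction)
        yvals = (indiv_part
                 + arch.sex_effect * (sex_vec == "M").astype(float)
                 + arch.age_slope * age
                 + resid)
        rows.append(pd.DataFrame({
            "id": ids,
            arch.name: yvals,
            "sex": sex_vec,
            "birth_year": yr.to_numpy(),
            "mother_id": dams.fillna("unknown").to_numpy(),
            "age": age,
        }))
    records = pd.concat(rows, ignore_index=True)

    truth = {
        "architecture": arch,
        "breeding_values": pd.Series(bv, index=ids),
        "family_effect": pd.Series(fam, index=ids),
        "maternal_effect": pd.Series(mat, index=ids),
        "year_effect": pd.Series(year_eff, index=ids),
        "permanent_environment": pd.Series(pe, index=ids),
        "realized_fractions": {
            "additive": float(np.var(bv)),
            "family": (arch.family_fraction
                       if arch.family_mode == "genetic" and arch.family_fraction > 0
                       else float(np.var(fam))),
            "maternal": float(np.var(mat)),
            "year": float(np.var(year_eff)),
            "perm_env": float(np.var(pe)),
            "residual": resid_fraction,
        },
    }
    return records, truth


_PATTERN_CLASSES = {
    "dominant": {0: "a", 1: "A", 2: "A"},
    "codominant": {0: "aa", 1: "Aa", 2: "AA"},
}


def simulate_monogenic_trait(
    genotypes: GenotypeMatrix,
    locus: MonogenicLocus,
    sex: pd.Series,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict]:
    """Categorical phenotype from the genotype at one causal SNP."""
    rng = rng if rng is not None else np.random.default_rng(0)
    snp_ids = genotypes.snps["snp_id"].tolist()
    if locus.snp_id not in snp_ids:
        raise KeyError(f"causal SNP {locus.snp_id!r} not in panel")
    j = snp_ids.index(locus.snp_id)
    dos = genotypes.dosages[:, j]
    ids = genotypes.sample_ids
    sex_vec = sex.reindex(ids)

    classes = []
    for i, s in enumerate(ids):
        pattern = locus.pattern
        if locus.sex_patterns:
            pattern = locus.sex_patterns.get(str(sex_vec.loc[s]), pattern)
        d = dos[i]
        classes.append(None if np.isnan(d) else _PATTERN_CLASSES[pattern][int(d)])
    classes = pd.Series(classes, index=ids, dtype="object")

    if locus.misclassification_rate > 0:
        observed = classes.dropna().unique().tolist()
        flip = rng.random(len(ids)) < locus.misclassification_rate
        for i, s in enumerate(ids):
            if flip[i] and classes.loc[s] is not None:
                classes.loc[s] = observed[rng.integers(len(observed))]

    records = pd.DataFrame({
        "id": ids,
        locus.snp_id: classes.to_numpy(),
        "sex": sex_vec.to_numpy(),
    })
    truth = {"locus": locus, "causal_dosage": pd.Series(dos, index=ids)}
    return records, truth


def encode_monogenic(records: pd.DataFrame, column: str) -> pd.DataFrame:
    """Numeric coding for categorical monogenic phenotypes.

    Two observed classes map to 0/1 and three to 0/1/2 in sorted class
    order, so the same linear machinery fits them on the observed scale.
    """
    out = records.copy()
    levels = sorted(out[column].dropna().unique())
    lut = {lev: float(k) for k, lev in enumerate(levels)}
    out[column] = out[column].map(lut)
    return out


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate a full study: pedigree, genotypes, all configured traits."""
    rng = np.random.default_rng(cfg.seed)
    ped, sex, birth_year = simulate_pedigree(cfg, rng)
    genotypes = drop_genotypes(ped, cfg, rng)
    study = SimulatedStudy(
        config=cfg, pedigree=ped, sex=sex, birth_year=birth_year,
        genotypes=genotypes, phenotypes={}, truth={},
    )
    for arch in cfg.traits:
        records, truth = simulate_polygenic_trait(study, arch, rng=rng)
        study.phenotypes[arch.name] = records
        study.truth[arch.name] = truth
    for locus in cfg.monogenic:
        records, truth = simulate_monogenic_trait(genotypes, locus, sex, rng=rng)
        study.phenotypes[locus.snp_id] = records
        study.truth[locus.snp_id] = truth
    return study
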