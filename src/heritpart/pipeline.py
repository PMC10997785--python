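"""Per-trait model suite: heritability partitions and model comparisons.

For each trait the suite fits, on one fixed set of individuals and records:

* Model 1 — full IBS GRM only (h2_GRM);
* Model 2 — full GRM plus relatedness-thresholded GRM, once per threshold t
  (default t in {0.05, 0.1}), giving h2_pop, h2_kin and their sum h2_pk;
* Model 3 — full GRM plus a GRM built from low-MAF SNPs, once per MAF
  threshold (default {0.1, 0.05, 0.01, 0.005, 0.001});
* Model 4 — pedigree numerator relationship matrix (h2_ped).

Monogenic traits additionally rerun Models 1 and 3 with both GRMs restricted
to the causal chromosome and to the causal gene +/- 1 Mb; a scope with fewer
than 10 SNPs is recorded as skipped, and non-convergence is recorded, never
fatal.  Log-likelihood ratio tests compare Models 2 and 3 against Model 1.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from .exceptions import AlignmentError, RegionTooSparseError
from .grm import GRM, allele_frequencies, build_grm, maf_subset, region_subset, threshold_grm
from .io import GenotypeMatrix
from .mixed_model import (
    RESIDUAL,
    FixedEffect,
    ModelSpec,
    VarianceComponentFit,
    build_design,
    h2_from_fit,
    reml_fit_design,
)
from .pedigree import build_A, extend_pedigree

__all__ = [
    "TraitConfig",
    "HeritabilityPartition",
    "LRTResult",
    "likelihood_ratio_test",
    "partition_heritability",
    "compare_partitions",
    "run_model_suite",
    "load_trait_configs",
]

DEFAULT_RELATEDNESS_THRESHOLDS = (0.05, 0.1)
DEFAULT_MAF_THRESHOLDS = (0.1, 0.05, 0.01, 0.005, 0.001)
REGION_FLANK_BP = 1_000_000
MIN_REGION_SNPS = 10


@dataclasses.dataclass
class TraitConfig:
    """One trait/age-class analysis configuration.

    ``fixed_effects`` entries are (name, kind, degree) tuples or
    :class:`FixedEffect`; ``trait_type`` is "polygenic" or "monogenic", the
    latter requiring the causal chromosome and gene span for the
    chromosome/region scopes.
    """

    name: str
    phenotype_col: str
    age_class: str = "all"
    fixed_effects: list = dataclasses.field(default_factory=list)
    random_effects: list[str] = dataclasses.field(default_factory=list)
    trait_type: str = "polygenic"
    causal_chromosome: Optional[str] = None
    causal_start_bp: Optional[int] = None
    causal_end_bp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("polygenic", "monogenic"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "monogenic" and self.causal_chromosome is None:
            raise ValueError("monogenic traits must name a causal chromosome")
        if self.trait_type == "polygenic" and self.causal_chromosome is not None:
            raise ValueError("polygenic traits carry no causal locus")
        self.fixed_effects = [
            fe if isinstance(fe, FixedEffect) else FixedEffect(*fe)
            for fe in self.fixed_effects
        ]

    @classmethod
    def from_dict(cls, d: dict) -> "TraitConfig":
        d = dict(d)
        d["fixed_effects"] = [
            FixedEffect(fe["name"], fe.get("kind", "continuous"), fe.get("degree", 1))
            if isinstance(fe, dict) else fe
            for fe in d.get("fixed_effects", [])
        ]
        return cls(**d)


def load_trait_configs(path) -> list[TraitConfig]:
    """Load per-trait analysis blocks from a YAML (or JSON) file.

    The file holds a ``traits:`` list; each entry mirrors the
    :class:`TraitConfig` fields, fixed effects as
    ``{name, kind, degree}`` mappings.
    """
    doc = yaml.safe_load(Path(path).read_text())
    blocks = doc["traits"] if isinstance(doc, dict) else doc
    return [TraitConfig.from_dict(b) for b in blocks]


@dataclasses.dataclass
class HeritabilityPartition:
    """Population/kinship split of heritability from a two-GRM model."""

    h2_pop: float
    se_pop: float
    h2_kin: float
    se_kin: float
    h2_pk: float
    se_pk: float
    scope: str = "whole-genome"
    kin_label: str = "kin"


@dataclasses.dataclass
class LRTResult:
    """Log-likelihood ratio test of a nested variance-component pair."""

    statistic: float
    df: int
    p_value: float
    null_mode: str
    full_label: str = "full"
    reduced_label: str = "reduced"


def likelihood_ratio_test(
    fit_full: VarianceComponentFit,
    fit_reduced: VarianceComponentFit,
    null_mode: str = "chi2_df1",
    full_label: str = "full",
    reduced_label: str = "reduced",
) -> LRTResult:
    """LRT for one extra variance component.

    ``Lambda = max(0, 2 (ll_full - ll_reduced))``.  ``null_mode`` is
    ``"chi2_df1"`` (central chi-square, 1 df — conservative at the boundary)
    or ``"mixture_50_50"`` (equal mixture of a point mass at zero and
    chi-square 1 df, the boundary-correct null).
    """
    if fit_full.n_records != fit_reduced.n_records:
        raise ValueError(
            f"fits use different record counts: {fit_full.n_records} vs "
            f"{fit_reduced.n_records}"
        )
    lam = max(0.0, 2.0 * (fit_full.loglik_restricted - fit_reduced.loglik_restricted))
    if null_mode == "chi2_df1":
        p = float(scipy.stats.chi2.sf(lam, df=1))
    elif null_mode == "mixture_50_50":
        p = 1.0 if lam <= 0 else float(0.5 * scipy.stats.chi2.sf(lam, df=1))
    else:
        raise ValueError(f"unknown null_mode {null_mode!r}")
    return LRTResult(statistic=lam, df=1, p_value=min(p, 1.0), null_mode=null_mode,
                     full_label=full_label, reduced_label=reduced_label)


def partition_heritability(
    fit: VarianceComponentFit,
    pop_label: str = "pop",
    kin_label: str = "kin",
    scope: str = "whole-genome",
) -> HeritabilityPartition:
    """h2_pop, h2_kin and h2_pk = h2_pop + h2_kin from a two-GRM fit.

    ``kin_label`` may name either the relatedness-thresholded component or a
    MAF-GRM component.  The sum identity holds by construction: the pk ratio
    is the joint ratio of both components to the same total.
    """
    for lab in (pop_label, kin_label):
        if lab not in fit.sigma2:
            raise KeyError(f"fit has no component {lab!r}; has {fit.labels}")
    h2_pop, se_pop = h2_from_fit(fit, [pop_label])
    h2_kin, se_kin = h2_from_fit(fit, [kin_label])
    h2_pk, se_pk = h2_from_fit(fit, [pop_label, kin_label])
    return HeritabilityPartition(
        h2_pop=h2_pop, se_pop=se_pop, h2_kin=h2_kin, se_kin=se_kin,
        h2_pk=h2_pk, se_pk=se_pk, scope=scope, kin_label=kin_label,
    )


def compare_partitions(
    partition: HeritabilityPartition,
    h2_ped: float,
    se_ped: float,
    h2_grm: float,
    se_grm: float,
) -> dict:
    """Flag the two standard-error comparisons used to judge the partition.

    ``pk_within_se_of_ped``: h2_pk falls inside h2_ped +/- 1 SE.
    ``pop_grm_se_overlap``: the +/- 1 SE intervals of h2_pop and h2_GRM
    overlap.
    """
    pk_within = abs(partition.h2_pk - h2_ped) <= se_ped
    lo_pop, hi_pop = partition.h2_pop - partition.se_pop, partition.h2_pop + partition.se_pop
    lo_grm, hi_grm = h2_grm - se_grm, h2_grm + se_grm
    overlap = (lo_pop <= hi_grm) and (lo_grm <= hi_pop)
    return {
        "pk_within_se_of_ped": bool(pk_within),
        "pop_grm_se_overlap": bool(overlap),
        "h2_pk": partition.h2_pk,
        "h2_ped": h2_ped,
        "se_ped": se_ped,
    }


# ---------------------------------------------------------------------------
# Suite orchestration
# ---------------------------------------------------------------------------


def _fit_row(cfg, model, variant, scope, fit, extra=None):
    row = {
        "trait": cfg.name,
        "model": model,
        "variant": variant,
        "scope": scope,
        "status": "ok" if fit is None or fit.converged else "failed_to_converge",
        "loglik": fit.loglik_restricted if fit else np.nan,
        "n_records": fit.n_records if fit else 0,
    }
    if fit is not None:
        for lab, v in fit.sigma2.items():
            row[f"sigma2_{lab}"] = v
    if extra:
        row.update(extra)
    return row


def _spec_for(cfg: TraitConfig, genetic) -> ModelSpec:
    return ModelSpec(
        trait=cfg.phenotype_col,
        fixed_effects=list(cfg.fixed_effects),
        random_effects=list(cfg.random_effects),
        genetic_components=genetic,
    )


@dataclasses.dataclass
class SuiteResult:
    """Rectangular fit table plus the raw fits and partitions of one trait."""

    table: pd.DataFrame
    fits: dict
    partitions: dict
    lrts: dict
    individuals: list[str]


def run_model_suite(
    cfg: TraitConfig,
    genotypes: GenotypeMatrix,
    pedigree: pd.DataFrame,
    phenotypes: pd.DataFrame,
    relatedness_thresholds: Sequence[float] = DEFAULT_RELATEDNESS_THRESHOLDS,
    maf_thresholds: Sequence[float] = DEFAULT_MAF_THRESHOLDS,
    null_mode: str = "chi2_df1",
    reml_kwargs: Optional[dict] = None,
) -> SuiteResult:
    """Run the full model suite for one trait.

    The same individuals (phenotyped AND genotyped) are used across every
    model; allele frequencies are computed from the analysed individuals.
    Returns a rectangular table with one row per model variant, including
    rows for skipped (<10 SNP) scopes and non-converged fits.
    """
    reml_kwargs = dict(reml_kwargs or {})
    phen_ids = [str(s) for s in phenotypes["id"].astype(str).unique()]
    genotyped = set(genotypes.sample_ids)
    individuals = [s for s in phen_ids if s in genotyped]
    if not individuals:
        raise AlignmentError("no phenotyped individual is genotyped")
    phenos = phenotypes[phenotypes["id"].astype(str).isin(individuals)]

    g = genotypes.subset(individuals=individuals)
    freqs = allele_frequencies(g)
    poly = ~((freqs.p <= 0.0) | (freqs.p >= 1.0))
    panel = [s for s, keep in zip(freqs.snp_ids, poly) if keep]
    g = g.subset(snp_ids=panel)
    freqs = allele_frequencies(g)

    grm_full = build_grm(g, freqs=freqs)
    ped_ext = extend_pedigree(pedigree, individuals)
    a_matrix = build_A(ped_ext, ids=individuals)

    scopes: list[tuple[str, Optional[list[str]]]] = [("whole-genome", None)]
    if cfg.trait_type == "monogenic":
        for scope_name, kwargs in (
            ("chromosome", dict(min_snps=MIN_REGION_SNPS)),
            ("region", dict(center_start_bp=cfg.causal_start_bp,
                            center_end_bp=cfg.causal_end_bp,
                            flank_bp=REGION_FLANK_BP, min_snps=MIN_REGION_SNPS)),
        ):
            try:
                ids = region_subset(g.snps, cfg.causal_chromosome, **kwargs)
                scopes.append((scope_name, ids))
            except RegionTooSparseError as exc:
                scopes.append((scope_name, exc))  # recorded as skipped below

    rows = []
    fits: dict = {}
    partitions: dict = {}
    lrts: dict = {}

    def fit_model(key, model, variant, scope, genetic, start=None):
        spec = _spec_for(cfg, genetic)
        design = build_design(spec, phenos, individuals)
        kw = dict(reml_kwargs)
        if start is not None:
            kw["start"] = start
        fit = reml_fit_design(spec, design, **kw)
        fits[key] = fit
        return fit

    for scope_name, scope_obj in scopes:
        suffix = "" if scope_name == "whole-genome" else f"_{scope_name}"
        if isinstance(scope_obj, Exception):
            for model, variant in [("model1", "full")] + [
                ("model3", f"maf<{m:g}") for m in maf_thresholds
            ]:
                rows.append({
                    "trait": cfg.name, "model": model, "variant": variant,
                    "scope": scope_name, "status": f"skipped: {scope_obj}",
                    "loglik": np.nan, "n_records": 0,
                })
            continue

        if scope_name == "whole-genome":
            grm_scope = grm_full
            scope_snps = None
        else:
            scope_snps = scope_obj
            grm_scope = build_grm(g, snp_subset=scope_snps,
                                  provenance=f"{scope_name}({cfg.causal_chromosome})")

        # Model 1: full GRM of this scope
        fit1 = fit_model(f"model1{suffix}", "model1", "full", scope_name,
                         [("pop", grm_scope)])
        rows.append(_fit_row(cfg, "model1", "full", scope_name, fit1))
        h2_grm, se_grm = h2_from_fit(fit1, ["pop"])
        rows[-1].update({"h2_GRM": h2_grm, "se_GRM": se_grm})

        start2 = None
        if fit1 is not None:
            base = [fit1.sigma2[lab] for lab in fit1.labels[:-1]]
            start2 = base[:1] + [0.05 * fit1.total_variance] + base[1:] + [
                fit1.sigma2[RESIDUAL] * 0.95
            ]

        # Model 2: relatedness-thresholded kinship GRM (whole-genome scope only)
        if scope_name == "whole-genome":
            for t in relatedness_thresholds:
                kin = threshold_grm(grm_scope, t)
                key = f"model2_t{t:g}"
                fit2 = fit_model(key, "model2", f"t={t:g}", scope_name,
                                 [("pop", grm_scope), ("kin", kin)], start=start2)
                part = partition_heritability(fit2, scope=scope_name)
                partitions[key] = part
                lrt = likelihood_ratio_test(fit2, fit1, null_mode=null_mode,
                                            full_label=key,
                                            reduced_label=f"model1{suffix}")
                lrts[key] = lrt
                rows.append(_fit_row(cfg, "model2", f"t={t:g}", scope_name, fit2, {
                    "h2_pop": part.h2_pop, "se_pop": part.se_pop,
                    "h2_kin": part.h2_kin, "se_kin": part.se_kin,
                    "h2_pk": part.h2_pk, "se_pk": part.se_pk,
                    "lrt_stat": lrt.statistic, "lrt_p": lrt.p_value,
                }))

        # Model 3: MAF-restricted second GRM within this scope
        scope_snp_table = (g.snps if scope_snps is None
                           else g.snps[g.snps["snp_id"].isin(scope_snps)])
        scope_freq_mask = g.snps["snp_id"].isin(scope_snp_table["snp_id"]).to_numpy()
        for m in maf_thresholds:
            variant = f"maf<{m:g}"
            key = f"model3_maf{m:g}{suffix}"
            try:
                from .grm import AlleleFrequencies
                scoped_freqs = AlleleFrequencies(
                    p=freqs.p[scope_freq_mask],
                    n_obs=freqs.n_obs[scope_freq_mask],
                    snp_ids=list(np.array(freqs.snp_ids)[scope_freq_mask]),
                )
                maf_ids = maf_subset(scoped_freqs, scope_snp_table, m)
                if scope_name != "whole-genome" and len(maf_ids) < MIN_REGION_SNPS:
                    raise RegionTooSparseError(
                        f"{len(maf_ids)} SNPs below MAF {m:g} in {scope_name}; "
                        f"refusing to build a GRM from fewer than {MIN_REGION_SNPS} SNPs"
                    )
            except (ValueError, RegionTooSparseError) as exc:
                rows.append({
                    "trait": cfg.name, "model": "model3", "variant": variant,
                    "scope": scope_name, "status": f"skipped: {exc}",
                    "loglik": np.nan, "n_records": 0,
                })
                continue
            grm_maf = build_grm(g, snp_subset=maf_ids,
                                provenance=f"maf(<{m:g}){suffix}")
            fit3 = fit_model(key, "model3", variant, scope_name,
                             [("pop", grm_scope), ("maf", grm_maf)], start=start2)
            part = partition_heritability(fit3, kin_label="maf", scope=scope_name)
            partitions[key] = part
            lrt = likelihood_ratio_test(fit3, fit1, null_mode=null_mode,
                                        full_label=key,
                                        reduced_label=f"model1{suffix}")
            lrts[key] = lrt
            rows.append(_fit_row(cfg, "model3", variant, scope_name, fit3, {
                "h2_pop": part.h2_pop, "se_pop": part.se_pop,
                "h2_kin": part.h2_kin, "se_kin": part.se_kin,
                "h2_pk": part.h2_pk, "se_pk": part.se_pk,
                "lrt_stat": lrt.statistic, "lrt_p": lrt.p_value,
            }))

    # Model 4: pedigree A matrix (whole-genome rows only)
    fit4 = None
    spec4 = _spec_for(cfg, [("ped", a_matrix)])
    design4 = build_design(spec4, phenos, individuals)
    fit4 = reml_fit_design(spec4, design4, **reml_kwargs)
    fits["model4"] = fit4
    h2_ped, se_ped = h2_from_fit(fit4, ["ped"])
    rows.append(_fit_row(cfg, "model4", "pedigree", "whole-genome", fit4,
                         {"h2_ped": h2_ped, "se_ped": se_ped}))

    table = pd.DataFrame(rows)
    return SuiteResult(table=table, fits=fits, partitions=partitions,
                       lrts=lrts, individuals=individuals)
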