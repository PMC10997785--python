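"""Partition heritability into population-level and family-associated parts.

Fits three animal models to one simulated trait (truth: h2_pop = 0.30,
family-associated fraction = 0.15): the single-GRM model, the two-GRM model
adding a relatedness-thresholded kinship GRM at t = 0.1, and the pedigree
model, then reports h2_GRM, the (h2_pop, h2_kin, h2_pk) partition, h2_ped,
and the likelihood-ratio test for the kinship component.
"""

import heritpart as hp
from heritpart.mixed_model import FixedEffect, ModelSpec, build_design, reml_fit_design

cfg = hp.SimulationConfig(
    seed=3, n_founders=100, n_generations=6, offspring_per_generation=150,
    n_snps=2500,
    traits=[hp.TraitArchitecture(name="size", h2_additive=0.30,
                                 family_fraction=0.15, family_mode="genetic",
                                 family_threshold=0.1)],
)
study = hp.simulate_study(cfg)
g = study.genotypes
phenos = study.phenotypes["size"]

grm = hp.build_grm(g)
kin = hp.threshold_grm(grm, 0.1)
ped_a = hp.build_A(study.pedigree, ids=g.sample_ids)

fixed = [FixedEffect("sex", "categorical")]


def fit(genetic):
    spec = ModelSpec(trait="size", fixed_effects=fixed,
                     genetic_components=genetic)
    return reml_fit_design(spec, build_design(spec, phenos, g.sample_ids))


fit1 = fit([("pop", grm)])
fit2 = fit([("pop", grm), ("kin", kin)])
fit4 = fit([("ped", ped_a)])

h2_grm, se_grm = hp.h2_from_fit(fit1, ["pop"])
h2_ped, se_ped = hp.h2_from_fit(fit4, ["ped"])
part = hp.partition_heritability(fit2)
lrt = hp.likelihood_ratio_test(fit2, fit1, null_mode="mixture_50_50")

print(f"h2_GRM (single GRM)   = {h2_grm:.3f} ({se_grm:.3f})")
print(f"h2_pop (t=0.1)        = {part.h2_pop:.3f} ({part.se_pop:.3f})  truth 0.30")
print(f"h2_kin (t=0.1)        = {part.h2_kin:.3f} ({part.se_kin:.3f})  truth 0.15")
print(f"h2_pk = pop + kin     = {part.h2_pk:.3f}")
print(f"h2_ped (pedigree A)   = {h2_ped:.3f} ({se_ped:.3f})")
print(f"LRT kinship component: Lambda = {lrt.statistic:.2f}, "
      f"p = {lrt.p_value:.4f} (mixture null)")

comp = hp.compare_partitions(part, h2_ped, se_ped, h2_grm, se_grm)
print(f"h2_pk within 1 SE of h2_ped: {comp['pk_within_se_of_ped']}; "
      f"h2_pop/h2_GRM SE intervals overlap: {comp['pop_grm_se_overlap']}")
print("A small p-value says family-associated variance (here simulated on "
      "the kinship covariance) improves on the single-GRM model.")
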