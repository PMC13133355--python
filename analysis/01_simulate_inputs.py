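#!/usr/bin/env python
"""Generate the synthetic study inputs.

Produces, under results/data/:
  * ANM-regime summary statistics for the two carrier outcome regimes
    (per-year log-HR of log(1.04) and log(0.99)), 288 instruments each;
  * AAM summary statistics with a BMI mediator path calibrated so the
    total and direct effects sit at HR 0.93 / 0.90 per year;
  * an ascertained carrier cohort (2000 families) with a genetic score
    whose theoretical effect is 1.44 years of ANM per SD.
"""

import sys
from pathlib import Path

import numpy as np

from carriermr.scores import GeneticScoreModel, theoretical_sd_effect
from carriermr.sumstats import write_sumstats
from carriermr.synthetic import (
    CohortScenario,
    MediatorSpec,
    SumstatsScenario,
    gen_carrier_cohort,
    gen_twosample_sumstats,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)


def main():
    # summary statistics: ANM regimes
    for label, hr in (("brca2", 1.04), ("brca1", 0.99)):
        sc = SumstatsScenario(n_snps=288, theta=float(np.log(hr)), seed=SEED)
        ex, out, _, _ = gen_twosample_sumstats(sc)
        write_sumstats(ex, OUT / f"anm_exposure_{label}.tsv")
        write_sumstats(out, OUT / f"anm_outcome_{label}.tsv")
        print(f"ANM {label}: 288 SNPs at true HR {hr}/year")

    # AAM with BMI mediation: total 0.93, direct 0.90 per year
    theta_d = float(np.log(0.90))
    gamma = (np.log(0.93) - theta_d) / 0.05
    sc = SumstatsScenario(
        n_snps=323, theta=theta_d, seed=SEED + 1,
        mediator_spec=MediatorSpec(theta_m=0.05, beta_m_sd=0.05,
                                   exposure_to_mediator=gamma),
    )
    ex, out, med, _ = gen_twosample_sumstats(sc)
    write_sumstats(ex, OUT / "aam_exposure.tsv")
    write_sumstats(out, OUT / "aam_outcome_brca1.tsv")
    write_sumstats(med, OUT / "bmi_mediator.tsv")
    print(f"AAM: 323 SNPs, direct HR 0.90, exposure->BMI path {gamma:.3f}")

    # carrier cohort with a 1.44 y/SD score
    rng = np.random.default_rng(SEED + 2)
    n = 50
    w = rng.normal(0, 0.1, n)
    model0 = GeneticScoreModel(
        tuple(f"rs{i + 1}" for i in range(n)),
        tuple(rng.choice(list("ACGT"), n)),
        tuple(w), tuple(rng.uniform(0.05, 0.95, n)), "ANM-GS",
    )
    scale = 1.44 / theoretical_sd_effect(model0)
    model = GeneticScoreModel(model0.variant_id, model0.effect_allele,
                              tuple(scale * x for x in w), model0.eaf, "ANM-GS")
    model.write(OUT / "anm_gs_model.tsv")
    sc = CohortScenario(n_families=2000, gs_true_effect=1.44, seed=SEED + 3)
    cohort = gen_carrier_cohort(sc, model)
    cohort.to_csv(OUT / "carrier_cohort.tsv", sep="\t", index=False)
    sc.incidence().to_frame().to_csv(OUT / "incidence.tsv", sep="\t", index=False)
    print(f"cohort: {len(cohort)} women in 2000 families, "
          f"{cohort['affected'].mean():.1%} affected (ascertained), "
          f"score theoretical effect {theoretical_sd_effect(model):.2f} y/SD")


if __name__ == "__main__":
    main()
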