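"""Traditional arm: complete-case logistic regression + G-computation.

Reads results/cohort.csv (from 01_simulate_cohort.py), discards rows with
any missing value among exposure and the 14 confounders, fits the
main-effects logistic model for in-hospital death, and standardizes to
the ATU.  Writes the coefficient table and the effect estimate.
"""

import json
from pathlib import Path

from icucausal.cohort import Cohort
from icucausal.estimators import two_proportion_test
from icucausal.pipeline import AnalysisConfig, run_traditional

OUT = Path("results")


def main() -> None:
    cohort = Cohort.from_csv(OUT / "cohort.csv")
    cfg = AnalysisConfig.profile("paper", seed=2020)
    fit, atu, extras = run_traditional(cohort, cfg)

    fit.coefficient_frame().to_csv(OUT / "coefficients.csv", index=False)
    payload = {
        "n_total": len(cohort),
        "n_complete": extras["n_complete"],
        "n_discarded": extras["n_discarded"],
        "raw_rd_complete_A": extras["raw_rd_complete_A"].__dict__,
        "raw_rd_complete_AC": extras["raw_rd_complete_AC"].__dict__,
        "gcomp_atu": {k: v for k, v in atu.__dict__.items() if k != "extra"},
    }
    (OUT / "traditional_arm.json").write_text(json.dumps(payload, indent=2, default=str))

    obesity = next(r for r in fit.table if r.term == "obesity")
    rawA = extras["raw_rd_complete_A"]
    rawAC = extras["raw_rd_complete_AC"]
    print(f"complete cases: {extras['n_complete']} of {len(cohort)} "
          f"({100 * extras['n_discarded'] / len(cohort):.1f}% discarded)")
    print(f"adjusted obesity OR: {obesity.or_:.2f} "
          f"({obesity.ci_low:.2f}-{obesity.ci_high:.2f}), P = {obesity.p_value:.3f}")
    print(f"raw RD (complete A): {100 * rawA.point:.2f}% "
          f"({100 * rawA.ci_low:.2f} to {100 * rawA.ci_high:.2f})")
    print(f"raw RD (complete A,C): {100 * rawAC.point:.2f}%")
    print(f"traditional ATU: {100 * atu.point:.2f}% "
          f"({100 * atu.ci_low:.2f} to {100 * atu.ci_high:.2f}), "
          f"P = {atu.p_value:.3f}")

    # is missingness equally common in exposed and unexposed patients?
    df = cohort.data
    from icucausal.cohort import CONFOUNDERS, EXPOSURE
    incomplete = df[[EXPOSURE] + CONFOUNDERS].isna().any(axis=1)
    known = df[EXPOSURE].notna()
    exp = (df[EXPOSURE] == True) & known  # noqa: E712
    une = (df[EXPOSURE] == False) & known  # noqa: E712
    p = two_proportion_test(int(incomplete[exp].sum()), int(exp.sum()),
                            int(incomplete[une].sum()), int(une.sum()))
    print(f"missingness exposed vs unexposed: "
          f"{100 * incomplete[exp].mean():.1f}% vs {100 * incomplete[une].mean():.1f}%, "
          f"P = {p:.3f}")


if __name__ == "__main__":
    main()
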