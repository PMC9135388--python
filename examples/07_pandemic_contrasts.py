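"""Pandemic-era contrasts on the most-recent-appointment items.

Appointments are assigned to eras by the WHO declaration date (2020-03-11,
itself 'during'); partial dates are excluded.  Four contrasts follow:
case vs control within each era, and during vs pre within each group.
"""
from hcineq import (GeneratorConfig, apply_exclusions, era_contrasts,
                    generate_cohort)

bundle = generate_cohort(GeneratorConfig(n_case=1200, n_control=1300,
                                         n_duplicates=0, n_incomplete=0,
                                         n_unconfirmed=0, seed=19))
cohort, _ = apply_exclusions(bundle.frame)
table = era_contrasts(cohort)

for contrast, block in table.groupby("contrast"):
    print(f"\n{contrast}")
    print(block[["item", "or", "ci_low", "ci_high", "p_value", "sig"]]
          .round(3).to_string(index=False))
print()
print("Within-era contrasts show the group gap in both periods; the")
print("within-group contrasts sit near OR = 1 because the generator's")
print("recent-experience items do not depend on era (no pandemic effect")
print("planted), matching the study's null finding.")
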