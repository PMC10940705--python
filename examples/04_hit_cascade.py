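"""Run the full agonist-specific hit-selection cascade on a synthetic screen.

Profiles every well, applies duplicate DI filtering, normalizes to the
agonist-control mean (100 %), Z-scores per plate pair, and filters:
consistent -> active (|Z| > 4) -> agonist-specific -> inhibitor direction
-> artifact-free -> ADMET.  Prints the per-stage counts and the confusion
against the planted ground truth.
"""

import warnings

from calscreen import generate_screen, run_cascade

dataset, truth = generate_screen(n_compounds=320, seed=1)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    verdicts, report = run_cascade(dataset)

for agonist in ("CRP", "thrombin"):
    print(f"{agonist} cascade:")
    for stage, count in report.counts(agonist):
        print(f"  {stage:22s} {count:4d}")

for agonist, sel in (("CRP", "CRP_only"), ("thrombin", "thrombin_only")):
    planted = set(truth.ids_with("inhibitor", sel))
    hits = set(report.stages[agonist][-1]["ids"])
    print(
        f"{agonist}: {len(hits & planted)}/{len(planted)} planted specific "
        f"inhibitors recovered, {len(hits - planted)} false hits"
    )

print(
    "\nDual-agonist inhibitors fall at the specificity stage, potentiators"
    "\nand autofluorescent compounds at the direction stage, quenchers at"
    "\nthe artifact stage, and injection failures already at DI filtering."
)
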