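"""Generate a synthetic duplicate plate screen with known planted effects.

Builds A/B duplicate 1536-well plates for both agonists (CRP and
thrombin), plants inhibitors, potentiators, fluorescence interferers and
injection failures at the default fractions, and prints the ground-truth
composition.  The printed counts are what the hit-selection cascade is
later judged against.
"""

from calscreen import generate_screen

dataset, truth = generate_screen(n_compounds=320, seed=1)

print(f"plate pairs: {len(dataset.plate_pairs)}")
for pair in dataset.plate_pairs:
    counts = pair.layout_a.role_counts()
    print(f"  {pair.pair_id}: roles {counts}")

print("\nplanted effects (compound counts):")
composition = truth.to_frame().groupby(["kind", "selectivity"]).size()
print(composition.to_string())
print(
    "\nEach compound appears in the same well on both duplicates and on the"
    "\nplates of both agonists; only the selectivity-matched agonist shows"
    "\nthe planted effect."
)
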