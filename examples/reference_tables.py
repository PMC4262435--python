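"""Headline statistics of the published per-segment reference tables.

Loads the packaged summaries of the 25 constant-course trans-oceanic
osprey segments and prints the aggregate numbers the reporting stage
checks against.
"""

from natalnav.fixtures import natal_straightness, segment_summaries

seg = segment_summaries()
nat = natal_straightness()

print(f"segments: {len(seg)}")
print(f"mean Mercator straightness:     {seg['straightness'].mean():.4f}")
print(f"segments with straightness >= 0.98: {(seg['straightness'] >= 0.98).sum()}")
print(f"segments with straightness >= 0.95: {(seg['straightness'] >= 0.95).sum()}")
print(f"mean track direction:           {seg['direction_deg'].mean():.1f} deg")
print(f"mean y_T-z_T straightness:      {nat['straightness'].mean():.4f}")
print(f"segments with y_T-z_T straightness > 0.95: {(nat['straightness'] > 0.95).sum()}")
print(
    "\nA straightness of 1 is a perfectly straight movement; these birds "
    "held near-perfect constant courses over open ocean in both geographic "
    "and nest-origin magnetic coordinates."
)
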