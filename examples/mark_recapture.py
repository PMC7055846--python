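"""Estimate total faunal richness from the fraction of already-known species.

Species known before an inventory play the role of marked animals in a
mark-recapture study: the smaller the share of "recaptured" (already known)
species in the catch, the larger the total fauna must be.
"""

from specrich import mr_from_table_row

groups = [
    # (group, species known before the inventory, species caught, of which new)
    ("Dolichopodidae", 314, 204, 31),
    ("Phoridae", 182, 863, 743),
    ("Diplazontinae", 49, 63, 24),
]

print(f"{'group':16s} {'known':>6s} {'caught':>6s} {'new':>4s} {'estimated total':>16s}")
for group, known, caught, new in groups:
    est = mr_from_table_row(known_prior=known, spp=caught, new=new)
    print(f"{group:16s} {known:6d} {caught:6d} {new:4d} {est.point_rounded:16d}")

print(
    "\nEach estimate extrapolates the prior checklist by the inverse of the"
    "\nrecapture fraction (Chapman small-sample form). Phoridae's huge excess"
    "\nof new species signals a mostly undiscovered fauna."
)
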