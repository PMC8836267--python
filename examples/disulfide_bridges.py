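"""Detect disulfide bridges and ask which ones each variant breaks.

Builds a 300-residue mini-domain carrying the seven disulfide pairings of
the Tyrp2 intra-melanosomal domain, detects the bridges geometrically, and
reports the breakage caused by the three OCA8 variants.
"""

import melanostab as ms

structure = ms.make_cys_fixture(ms.default_fixture_spec())
bridges = ms.detect_disulfides(structure)

labeled = ms.label_domains(bridges, {"Cys-rich": (25, 125), "tyrosinase": (170, 450)})
print(f"{len(labeled)} disulfide bridges detected:")
for bridge in labeled:
    print(f"  {bridge}  SG-SG {bridge.sg_distance:.2f} A  [{bridge.domain_label}]")

print("\nbridge breakage by variant:")
for text in ms.OCA8_MUTATIONS:
    mutation = ms.MutationSpec.from_string(text)
    broken = ms.broken_bridges(bridges, mutation)
    outcome = ", ".join(str(b) for b in broken) or "none"
    print(f"  {text}: {outcome}")

# C40S and C61W each eliminate one bridge of the Cys-rich domain (C29-C40
# and C41-C61 respectively); G59V is not a cysteine substitution and leaves
# the disulfide topology intact.
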