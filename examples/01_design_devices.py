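"""Device catalog: Murray's-law geometry and laminar flow splits.

Builds the capillary-bifurcation device catalog, shows that each parent
channel's effective diameter obeys d0^3 = d1^3 + d2^3 on the daughters'
effective diameters, and prints the fraction of flow entering the larger
daughter branch — the quantity that governs where cells and fragments go.
"""

from ctctransit import build_catalog, effective_diameter

print(f"{'code':14s} {'widths um':>10s} {'parent um':>10s} {'de0':>7s} {'f2 (larger branch)':>20s}")
for dev in build_catalog():
    if not dev.bifurcating:
        print(f"{dev.code:14s} {'-':>10s} {dev.parent.width_a:10.2f} {'-':>7s} {'-':>20s}")
        continue
    widths = f"{dev.daughter1.width_a:g}/{dev.daughter2.width_a:g}"
    print(
        f"{dev.code:14s} {widths:>10s} {dev.parent.width_a:10.2f} "
        f"{dev.parent.effective_diameter:7.3f} {dev.flow_split():20.3f}"
    )

print()
print("f2 = 0.5 means an even split (equal daughters); f2 near 1 means the")
print("larger, lower-resistance branch captures nearly all the flow.")
print(f"Check: effective diameter of a 7x7 um channel = {effective_diameter(7, 7):.3f} um")
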