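"""Decode combinatorial fluorophore barcodes and screen a genus probe.

The nested panel identifies cells by which *combination* of probes lights
them up: a Granulosicoccus cell is positive for the domain probe (Atto532),
the Gammaproteobacteria class probe (Cy5) and the genus probe (TexasRedX).
"""

from clasifish import (
    SpecificityRule,
    decode_barcode,
    default_panel,
    probe_mismatches,
    screen_probe,
)

panel = default_panel()
print("Dyes (channel order):", ", ".join(panel.dye_list))
print("\nBarcode table:")
for taxon, code in panel.barcodes.items():
    print(f"  {taxon:32s} {sorted(code)}")

print("\nDecoding observed dye combinations:")
for combo in [
    {"Atto532", "Cy5", "TexasRedX"},   # full genus barcode
    {"Atto532", "Dy490"},              # Alphaproteobacteria
    {"Dy415"},                         # Verrucomicrobia/Planctomycetes
    {"Atto532"},                       # domain probe only
    set(),                             # no signal
]:
    print(f"  {sorted(combo) or '(none)'} -> {decode_barcode(combo, panel)}")

# Specificity screen: the genus probe must match its targets perfectly and
# carry >= 2 mismatches against every off-target 16S region.
gran737 = next(p for p in panel.probes if p.name == "Gran737")
site = "TCTGGAACAATACTGACGCTGA"  # the probe's reverse-complement binding site
target = "GGGAAC" + site + "CCTTGG"
offtarget = "GGGAAC" + site[:5] + "GG" + site[7:] + "CCTTGG"  # 2 substitutions
ok, table = screen_probe(gran737, [target], [offtarget], SpecificityRule())
print(f"\nGran737 vs target: {probe_mismatches(gran737, target)} mismatches")
print(f"Gran737 vs off-target: {probe_mismatches(gran737, offtarget)} mismatches")
print(f"Screen verdict: {'PASS' if ok else 'FAIL'}")
print("(pass requires a perfect target match and >= 2 off-target mismatches)")
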