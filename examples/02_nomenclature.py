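"""Name a ganglioside from its structure identifier.

The systematic Svennerholm name packs the total sialic-acid count (as a
letter), the core length, the series (sialylation of the inner
galactose) and the α2,6 decoration into a short code; the IUPAC name
lists the sialylated core positions explicitly.
"""

from gangliosim import (Structure, iupac_ganglioside_name, legacy_mapping,
                        systematic_svennerholm)

for ident in ["L3Vb4[S3]L4GT",            # GM1a
              "S3L3Vb4L4GT",              # 0-series GM1
              "S3L3[S6]Vb4[S8S8S3]L4GT",  # penta-sialylated c-series
              "[S3]LT"]:                  # sialylated galactosylceramide
    s = Structure.parse(ident)
    ssn = str(systematic_svennerholm(s))
    print(f"{ident:>24}  SSN {ssn:<6}  IUPAC {iupac_ganglioside_name(s)}")

# Four traditional names differ from the systematic system:
print("\nlegacy GM1b ->", legacy_mapping("GM1b", "legacy_to_ssn")[0],
      "(a 0-series ganglioside, despite the traditional 'b')")
print("legacy GD1c ->", legacy_mapping("GD1c", "legacy_to_ssn")[0])
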