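"""Classify chemotherapy regimens from component drug sets.

The label is a pure function of the ingredient set: nab-paclitaxel marks
GnP; two or more FOLFIRINOX components mark FFX; gemcitabine or S-1 alone
are their monotherapies; everything else (including gemcitabine +
erlotinib) is 'other'.
"""

from oncoclaims import classify_regimen
from oncoclaims.simulate import default_drug_dictionary

dd = default_drug_dictionary()
examples = [
    ({"GEM", "NAB"}, "gemcitabine + nab-paclitaxel"),
    ({"OXA", "IRI", "FU", "LV"}, "full FOLFIRINOX"),
    ({"OXA", "FU"}, "two FOLFIRINOX components (e.g. modified regimen)"),
    ({"GEM"}, "gemcitabine monotherapy"),
    ({"TS1"}, "S-1 monotherapy"),
    ({"GEM", "ERL"}, "gemcitabine + erlotinib"),
]
for drugs, desc in examples:
    print(f"{sorted(drugs)!s:<30} -> {classify_regimen(drugs, dd):<6} ({desc})")
print("\nEach set maps to exactly one of five labels; supportive-care drugs")
print("never enter a component set, so they cannot change the label.")
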