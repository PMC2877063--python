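"""Published reference values used as inputs by reports and checks.

``REFERENCE_BASE_COUNTS`` holds whole-mitogenome base counts (A, C, G, T)
for the two *Anopheles darlingi* genotypes and the comparator dipteran
mitogenomes, as printed in the source comparative table.  Derived
quantities (AT%, skews) are always recomputed from these counts by
:mod:`mitocomp.compstats`, never stored.
"""

from __future__ import annotations

from .compstats import CompositionProfile

#: species/genotype -> (A, C, G, T) counts over the whole mitogenome.
REFERENCE_BASE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "Anopheles darlingi N": (6189, 1920, 1434, 5843),
    "Anopheles darlingi S": (6181, 1920, 1444, 5840),
    "Anopheles gambiae": (6150, 1989, 1458, 5766),
    "Anopheles quadrimaculatus": (6221, 2067, 1432, 5735),
    "Anopheles funestus": (6178, 1936, 1404, 5836),
    "Aedes albopictus": (6680, 2014, 1396, 6575),
    "Aedes aegypti": (6690, 2118, 1380, 6467),
    "Drosophila yakuba": (6326, 1949, 1481, 6263),
}


def reference_profiles() -> dict[str, CompositionProfile]:
    """Composition profiles recomputed from the published base counts."""
    return {
        name: CompositionProfile(a=a, c=c, g=g, t=t)
        for name, (a, c, g, t) in REFERENCE_BASE_COUNTS.items()
    }
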