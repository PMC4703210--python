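"""Genotype labels and the %HbS bands they imply.

The screening test distinguishes hemoglobin genotypes by the fraction of
total hemoglobin that is sickle hemoglobin (%HbS).  The bands below are the
ranges observed in the validation cohort for each genotype: normal (AA)
samples carry no HbS, trait carriers (AS) 38-42%, HbSC disease 41-50%,
sickle cell anemia (SS) roughly 74-93%, and sickle-beta(+)-thalassemia
above 60%.
"""

from __future__ import annotations

import enum


class Genotype(str, enum.Enum):
    """Hemoglobin genotype classes the test can encounter."""

    AA = "AA"
    AS = "AS"
    SS = "SS"
    SC = "SC"
    SBETA = "SB+"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Inclusive (low, high) %HbS band for each genotype, in percent.
PERCENT_HBS_BANDS: dict[Genotype, tuple[float, float]] = {
    Genotype.AA: (0.0, 0.0),
    Genotype.AS: (38.0, 42.0),
    Genotype.SC: (41.0, 50.0),
    Genotype.SS: (74.0, 93.0),
    Genotype.SBETA: (60.0, 93.0),
}

#: Severity order used for conservative tie-breaking in classification.
SEVERITY_ORDER: tuple[Genotype, ...] = (Genotype.AA, Genotype.AS, Genotype.SS)


def band_contains(genotype: Genotype, percent_hbs: float) -> bool:
    """True if ``percent_hbs`` lies inside the genotype's %HbS band."""
    lo, hi = PERCENT_HBS_BANDS[genotype]
    if genotype is Genotype.SBETA:  # open lower bound: "> 60% HbS"
        return percent_hbs > lo
    return lo <= percent_hbs <= hi
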