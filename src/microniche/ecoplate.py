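"""Biolog EcoPlate layout constants.

The EcoPlate carries 31 distinct carbon substrates plus a water control,
each in triplicate.  Dye development (absorbance at 595 nm) reports
respiration on each substrate.  The substrate list below is the canonical
EcoPlate panel, ordered as wells are usually read (column-major across the
three replicate blocks).
"""

from __future__ import annotations

#: The 31 EcoPlate carbon substrates, in canonical well order.
CARBON_SOURCES: tuple[str, ...] = (
    "beta-methyl-D-glucoside",
    "D-galactonic acid gamma-lactone",
    "L-arginine",
    "pyruvic acid methyl ester",
    "D-xylose",
    "D-galacturonic acid",
    "L-asparagine",
    "Tween 40",
    "i-erythritol",
    "2-hydroxybenzoic acid",
    "L-phenylalanine",
    "Tween 80",
    "D-mannitol",
    "4-hydroxybenzoic acid",
    "L-serine",
    "alpha-cyclodextrin",
    "N-acetyl-D-glucosamine",
    "gamma-hydroxybutyric acid",
    "L-threonine",
    "glycogen",
    "D-glucosaminic acid",
    "itaconic acid",
    "glycyl-L-glutamic acid",
    "D-cellobiose",
    "glucose-1-phosphate",
    "alpha-ketobutyric acid",
    "phenylethylamine",
    "alpha-D-lactose",
    "D,L-alpha-glycerol phosphate",
    "D-malic acid",
    "putrescine",
)

#: Label used for the water (no-carbon) control wells.
WATER: str = "water"

#: Measurement days for the incubation series.
DAYS: tuple[int, ...] = (0, 4, 7)

#: Replicate labels (three independent biological replicates).
REPLICATES: tuple[int, ...] = (1, 2, 3)

#: Context id used for the co-culture of all community members.
COMMUNITY_ID: str = "ALL"

#: Long-format plate table schema.
PLATE_COLUMNS: tuple[str, ...] = (
    "culture_id",
    "partner_id",
    "source",
    "replicate",
    "day",
    "absorbance",
)


def source_names(n_sources: int) -> tuple[str, ...]:
    """Substrate names for a panel of ``n_sources`` carbon sources.

    The real EcoPlate panel is used when it is large enough; synthetic
    panels beyond 31 sources get generic names.
    """
    if n_sources <= len(CARBON_SOURCES):
        return CARBON_SOURCES[:n_sources]
    return tuple(f"source_{i + 1:02d}" for i in range(n_sources))


def context_id(culture_id: str, partner_id: str | None = None) -> str:
    """Canonical id for a culture context (monoculture, pair or community).

    Pairs are unordered: ``context_id("Q2", "Q1") == "Q1+Q2"``.
    """
    if partner_id is None or partner_id == "" or partner_id != partner_id:
        return str(culture_id)
    a, b = sorted((str(culture_id), str(partner_id)))
    return f"{a}+{b}"


def split_context(context: str) -> tuple[str, ...]:
    """Member strain ids of a context id ("Q1+Q2" -> ("Q1", "Q2"))."""
    return tuple(context.split("+"))
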