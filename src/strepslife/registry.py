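"""Per-taxon registry: species constants keyed by taxonomic code.

Each entry carries the species-level constants that the life-history
derivation needs but cannot compute from the two record files themselves:
expected gestation length (used to back-calculate conception dates), the
gestation range, whether the taxon breeds seasonally, its activity pattern,
whether it is actively breeding in the current colony, the number of
individuals with banked biological samples (pass-through metadata), and the
middle month of the breeding season in the country of origin (used when
assigning estimated dates of birth to wild-caught animals).

The shipped default registry covers the 27 strepsirrhine taxa held by the
Duke Lemur Center: lemurs, lorises and galagos, coded by the first letter of
the genus plus the first three letters of the species (hybrids by the first
three letters of the genus).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional


@dataclass(frozen=True)
class TaxonInfo:
    """Species constants for one taxon.

    Parameters
    ----------
    taxon_code:
        Short unique code, e.g. ``CMED``.
    latin_name, common_name:
        Nomenclature, passed through to outputs.
    expected_gestation_d:
        The gestation length (days) most commonly observed for the species;
        subtracted from an infant's date of birth to estimate conception.
    gestation_range_d:
        ``(low, high)`` range of observed gestation lengths, days.
    breeding_pattern:
        ``"S"`` seasonal or ``"NS"`` non-seasonal.
    activity:
        ``"N"`` nocturnal or ``"D"`` diurnal.
    active_dlc_breeding:
        ``"Y"``/``"N"``: actively breeding in the current colony.
    n_biosample_individuals:
        Individuals with banked biological samples (pass-through; may be
        ``None`` when no inventory exists for the taxon).
    origin_breeding_midmonth:
        Middle month (1-12) of the breeding season in the country of origin;
        required for seasonal breeders only, where it anchors estimated
        dates of birth of wild-caught individuals.
    """

    taxon_code: str
    latin_name: str
    common_name: str
    expected_gestation_d: int
    gestation_range_d: tuple[int, int]
    breeding_pattern: str
    activity: str
    active_dlc_breeding: str = "N"
    n_biosample_individuals: Optional[int] = None
    origin_breeding_midmonth: Optional[int] = None

    def __post_init__(self) -> None:
        low, high = self.gestation_range_d
        if not (low <= self.expected_gestation_d <= high):
            raise ValueError(
                f"{self.taxon_code}: expected gestation "
                f"{self.expected_gestation_d} outside range {low}-{high}"
            )
        if self.breeding_pattern not in ("S", "NS"):
            raise ValueError(f"{self.taxon_code}: bad breeding_pattern")
        if self.activity not in ("N", "D"):
            raise ValueError(f"{self.taxon_code}: bad activity")
        if self.breeding_pattern == "S" and self.origin_breeding_midmonth is None:
            raise ValueError(
                f"{self.taxon_code}: seasonal breeder needs origin_breeding_midmonth"
            )
        if self.origin_breeding_midmonth is not None and not (
            1 <= self.origin_breeding_midmonth <= 12
        ):
            raise ValueError(f"{self.taxon_code}: bad origin_breeding_midmonth")


class Registry:
    """An immutable mapping of taxon code -> :class:`TaxonInfo`."""

    def __init__(self, taxa: Iterable[TaxonInfo]):
        self._taxa: dict[str, TaxonInfo] = {}
        for t in taxa:
            if t.taxon_code in self._taxa:
                raise ValueError(f"duplicate taxon code {t.taxon_code}")
            self._taxa[t.taxon_code] = t

    def __getitem__(self, code: str) -> TaxonInfo:
        return self._taxa[code]

    def __contains__(self, code: str) -> bool:
        return code in self._taxa

    def __iter__(self):
        return iter(self._taxa.values())

    def __len__(self) -> int:
        return len(self._taxa)

    @property
    def codes(self) -> list[str]:
        return list(self._taxa)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                [
                    "Taxon", "Latin_Name", "Common_Name",
                    "Expected_Gestation_d", "Range_Gestation_d",
                    "Pattern_Breeding", "NocturnalOrDiurnal",
                    "Active_DLCBreeding", "N_Biosample_Individuals",
                    "Origin_Breeding_MidMonth",
                ]
            )
            for t in self:
                w.writerow(
                    [
                        t.taxon_code, t.latin_name, t.common_name,
                        t.expected_gestation_d,
                        f"{t.gestation_range_d[0]}-{t.gestation_range_d[1]}",
                        t.breeding_pattern, t.activity, t.active_dlc_breeding,
                        "" if t.n_biosample_individuals is None
                        else t.n_biosample_individuals,
                        "" if t.origin_breeding_midmonth is None
                        else t.origin_breeding_midmonth,
                    ]
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Registry":
        taxa = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rng = row["Range_Gestation_d"].replace("–", "-")
                low, high = (int(x) for x in rng.split("-"))
                bios = row.get("N_Biosample_Individuals", "").strip()
                mid = row.get("Origin_Breeding_MidMonth", "").strip()
                taxa.append(
                    TaxonInfo(
                        taxon_code=row["Taxon"],
                        latin_name=row["Latin_Name"],
                        common_name=row["Common_Name"],
                        expected_gestation_d=int(row["Expected_Gestation_d"]),
                        gestation_range_d=(low, high),
                        breeding_pattern=row["Pattern_Breeding"],
                        activity=row["NocturnalOrDiurnal"],
                        active_dlc_breeding=row["Active_DLCBreeding"],
                        n_biosample_individuals=(
                            None if bios in ("", ".", "NA") else int(bios)
                        ),
                        origin_breeding_midmonth=(
                            None if mid in ("", ".", "NA") else int(mid)
                        ),
                    )
                )
        return cls(taxa)


# code, latin, common, gestation_d, (range), pattern, activity, active,
# n_biosample, origin_midmonth.  origin_breeding_midmonth is the captive
# peak breeding month shifted by six months: the captive colony is in North
# America and its seasons are opposite those of the southern-hemisphere
# countries of origin.
_DEFAULTS = [
    ("CMED", "Cheirogaleus medius", "Fat-tailed dwarf lemur", 60, (60, 64), "S", "N", "Y", 43, 11),
    ("DMAD", "Daubentonia madagascariensis", "Aye-aye", 165, (157, 172), "NS", "N", "Y", 34, None),
    ("EALB", "Eulemur albifrons", "White-fronted brown lemur", 120, (120, 128), "S", "D", "N", 5, 6),
    ("ECOL", "Eulemur collaris", "Collared brown lemur", 120, (120, 128), "S", "D", "N", 35, 6),
    ("ECOR", "Eulemur coronatus", "Crowned lemur", 120, (120, 126), "S", "D", "Y", 34, 7),
    ("EFLA", "Eulemur flavifrons", "Blue-eyed black lemur", 120, (120, 129), "S", "D", "Y", None, 5),
    ("EFUL", "Eulemur fulvus", "Common brown lemur", 120, (120, 128), "S", "D", "N", 7, 6),
    ("EMAC", "Eulemur macaco", "Black lemur", 120, (120, 129), "S", "D", "N", None, 5),
    ("EMON", "Eulemur mongoz", "Mongoose lemur", 120, (120, 128), "S", "D", "Y", 48, 6),
    ("ERUB", "Eulemur rubriventer", "Red-bellied lemur", 120, (120, 127), "S", "D", "N", 13, 6),
    ("ERUF", "Eulemur rufus", "Red-fronted brown lemur", 120, (120, 128), "S", "D", "N", 32, 5),
    ("ESAN", "Eulemur sanfordi", "Sanford's brown lemur", 120, (120, 128), "S", "D", "N", 11, 7),
    ("EUL", "Eulemur", "Eulemur hybrid", 120, (120, 128), "S", "D", "N", 41, 6),
    ("GMOH", "Galago moholi", "Mohol bushbaby", 124, (110, 126), "NS", "N", "N", 57, None),
    ("HGG", "Hapalemur griseus griseus", "Eastern lesser bamboo lemur", 145, (145, 150), "S", "D", "N", 34, 6),
    ("LCAT", "Lemur catta", "Ring-tailed lemur", 130, (130, 136), "S", "D", "Y", 122, 5),
    ("LTAR", "Loris tardigradus", "Slender loris", 167, (150, 169), "NS", "N", "N", 19, None),
    ("MMUR", "Microcebus murinus", "Gray mouse lemur", 60, (57, 63), "S", "N", "Y", 46, 10),
    ("MZAZ", "Mirza coquereli", "Northern giant mouse lemur", 90, (89, 90), "NS", "N", "N", 28, None),
    ("NCOU", "Nycticebus coucang", "Slow loris", 193, (185, 197), "NS", "N", "N", 24, None),
    ("NPYG", "Nycticebus pygmaeus", "Pygmy slow loris", 185, (183, 198), "NS", "N", "Y", 21, None),
    ("OGG", "Otolemur garnettii garnettii", "Northern greater galago", 129, (126, 134), "NS", "N", "N", 27, None),
    ("PCOQ", "Propithecus coquereli", "Coquerel's sifaka", 160, (155, 168), "S", "D", "Y", 85, 3),
    ("PPOT", "Perodicticus potto", "Potto", 170, (170, 172), "NS", "N", "N", 7, None),
    ("VAR", "Varecia", "Varecia hybrid", 98, (98, 102), "S", "D", "N", 2, 7),
    ("VRUB", "Varecia rubra", "Red ruffed lemur", 98, (98, 102), "S", "D", "Y", 53, 7),
    ("VVV", "Varecia variegata variegata", "Black-and-white ruffed lemur", 98, (98, 102), "S", "D", "Y", 43, 7),
]


def default_registry() -> Registry:
    """The shipped 27-taxon registry of colony species constants."""
    return Registry(
        TaxonInfo(
            taxon_code=c, latin_name=ln, common_name=cn,
            expected_gestation_d=g, gestation_range_d=rng,
            breeding_pattern=pat, activity=act, active_dlc_breeding=ab,
            n_biosample_individuals=nb, origin_breeding_midmonth=mid,
        )
        for c, ln, cn, g, rng, pat, act, ab, nb, mid in _DEFAULTS
    )
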