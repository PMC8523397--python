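"""Rule-based osteoarthritis labels from MOAKS score records.

MOAKS (MRI Osteoarthritis Knee Score) grades structural features of the knee
per anatomical site on ordinal 0-3 scales. This module implements the
rule-based definition of tibiofemoral osteoarthritis (tfOA) used for the
classification outcome, plus three medial-tibial sub-outcomes (any cartilage
damage, any osteophyte, any bone marrow lesion, each at grade >= 1).

The tfOA rule: a knee is positive when it has both primary features (a
definite osteophyte, i.e. osteophyte grade 2 or 3 at any tibiofemoral site,
and full-thickness cartilage loss, i.e. cartilage grade 3 at any site), or
one primary feature together with at least two of three secondary features:

1. a subchondral bone marrow lesion or cyst (grade >= 1) not associated with
   meniscal or ligamentous attachments,
2. meniscal maceration or degeneration (grade >= 1) or a horizontal tear,
3. cartilage loss counted as the partial-thickness secondary.

The partial-thickness secondary is satisfied by any cartilage loss of
grade >= 1; full-thickness loss subsumes partial thickness when counted as a
secondary. This reading keeps the rule monotone in every grade (raising a
grade can never flip a positive knee to negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CARTILAGE_SITES: tuple[str, ...] = (
    "medial_tibia_anterior",
    "medial_tibia_central",
    "medial_tibia_posterior",
    "lateral_tibia_anterior",
    "lateral_tibia_central",
    "lateral_tibia_posterior",
    "medial_femur",
    "lateral_femur",
)
#: Sites that count toward the medial-tibial sub-outcomes.
MEDIAL_TIBIA_SURFACE_SITES: tuple[str, ...] = CARTILAGE_SITES[:3]

OSTEOPHYTE_SITES: tuple[str, ...] = (
    "medial_tibia",
    "lateral_tibia",
    "medial_femur",
    "lateral_femur",
)

BML_SITES: tuple[str, ...] = CARTILAGE_SITES

MAX_GRADE = 3


def _validate_grades(grades: dict[str, int], sites: tuple[str, ...], what: str) -> None:
    for site, g in grades.items():
        if site not in sites:
            raise ValueError(f"unknown {what} site {site!r}")
        if not (0 <= int(g) <= MAX_GRADE):
            raise ValueError(f"{what} grade at {site!r} out of range 0-{MAX_GRADE}: {g}")


@dataclass
class MoaksRecord:
    """Per-knee MOAKS grades; unspecified sites default to grade 0."""

    osteophyte: dict[str, int] = field(default_factory=dict)
    cartilage: dict[str, int] = field(default_factory=dict)
    bml: dict[str, int] = field(default_factory=dict)
    cyst: dict[str, int] = field(default_factory=dict)
    bml_or_cyst_nonattachment: bool = False
    meniscus_degeneration_grade: int = 0
    meniscus_horizontal_tear: bool = False

    def __post_init__(self) -> None:
        _validate_grades(self.osteophyte, OSTEOPHYTE_SITES, "osteophyte")
        _validate_grades(self.cartilage, CARTILAGE_SITES, "cartilage")
        _validate_grades(self.bml, BML_SITES, "bone marrow lesion")
        _validate_grades(self.cyst, BML_SITES, "cyst")
        if not (0 <= int(self.meniscus_degeneration_grade) <= MAX_GRADE):
            raise ValueError("meniscus degeneration grade out of range")

    # -- boolean reductions used by the tfOA rule --------------------------

    @property
    def definite_osteophyte(self) -> bool:
        return any(g >= 2 for g in self.osteophyte.values())

    @property
    def full_thickness_cartilage_loss(self) -> bool:
        return any(g == 3 for g in self.cartilage.values())

    @property
    def partial_thickness_cartilage_loss(self) -> bool:
        # Secondary feature: any cartilage loss; full thickness subsumes partial.
        return any(g >= 1 for g in self.cartilage.values())

    @property
    def bml_or_cyst_secondary(self) -> bool:
        present = any(g >= 1 for g in self.bml.values()) or any(
            g >= 1 for g in self.cyst.values()
        )
        return present and self.bml_or_cyst_nonattachment

    @property
    def meniscal_secondary(self) -> bool:
        return self.meniscus_degeneration_grade >= 1 or self.meniscus_horizontal_tear

    def to_row(self) -> dict[str, int | bool]:
        """Flatten to one CSV row (columns per site-feature)."""
        row: dict[str, int | bool] = {}
        for site in OSTEOPHYTE_SITES:
            row[f"osteophyte_{site}"] = self.osteophyte.get(site, 0)
        for site in CARTILAGE_SITES:
            row[f"cartilage_{site}"] = self.cartilage.get(site, 0)
        for site in BML_SITES:
            row[f"bml_{site}"] = self.bml.get(site, 0)
            row[f"cyst_{site}"] = self.cyst.get(site, 0)
        row["bml_or_cyst_nonattachment"] = self.bml_or_cyst_nonattachment
        row["meniscus_degeneration_grade"] = self.meniscus_degeneration_grade
        row["meniscus_horizontal_tear"] = self.meniscus_horizontal_tear
        return row

    @classmethod
    def from_row(cls, row) -> "MoaksRecord":
        return cls(
            osteophyte={s: int(row[f"osteophyte_{s}"]) for s in OSTEOPHYTE_SITES},
            cartilage={s: int(row[f"cartilage_{s}"]) for s in CARTILAGE_SITES},
            bml={s: int(row[f"bml_{s}"]) for s in BML_SITES},
            cyst={s: int(row[f"cyst_{s}"]) for s in BML_SITES},
            bml_or_cyst_nonattachment=bool(row["bml_or_cyst_nonattachment"]),
            meniscus_degeneration_grade=int(row["meniscus_degeneration_grade"]),
            meniscus_horizontal_tear=bool(row["meniscus_horizontal_tear"]),
        )


@dataclass(frozen=True)
class KneeLabels:
    tfoa: bool
    medial_cartilage_damage: bool
    medial_osteophyte: bool
    medial_bml: bool


def classify_tibiofemoral_oa(record: MoaksRecord) -> bool:
    """Apply the tfOA rule: both primaries, or one primary + >=2 secondaries."""
    primary_osteo = record.definite_osteophyte
    primary_cart = record.full_thickness_cartilage_loss
    if primary_osteo and primary_cart:
        return True
    if not (primary_osteo or primary_cart):
        return False
    n_secondary = sum(
        (
            record.bml_or_cyst_secondary,
            record.meniscal_secondary,
            record.partial_thickness_cartilage_loss,
        )
    )
    return n_secondary >= 2


def label_medial_cartilage_damage(record: MoaksRecord) -> bool:
    """Any cartilage loss (grade >= 1) in the medial anterior/central/posterior tibia."""
    return any(record.cartilage.get(s, 0) >= 1 for s in MEDIAL_TIBIA_SURFACE_SITES)


def label_medial_osteophyte(record: MoaksRecord) -> bool:
    """Any osteophyte (grade >= 1) in the medial tibia."""
    return record.osteophyte.get("medial_tibia", 0) >= 1


def label_medial_bml(record: MoaksRecord) -> bool:
    """Any bone marrow lesion (grade >= 1) in the medial anterior/central/posterior tibia."""
    return any(record.bml.get(s, 0) >= 1 for s in MEDIAL_TIBIA_SURFACE_SITES)


def label_knee(record: MoaksRecord) -> KneeLabels:
    return KneeLabels(
        tfoa=classify_tibiofemoral_oa(record),
        medial_cartilage_damage=label_medial_cartilage_damage(record),
        medial_osteophyte=label_medial_osteophyte(record),
        medial_bml=label_medial_bml(record),
    )


def records_to_frame(records: list[MoaksRecord], append_labels: bool = True) -> pd.DataFrame:
    """Serialize records (one row per knee), optionally appending label columns."""
    rows = []
    for rec in records:
        row = rec.to_row()
        if append_labels:
            lab = label_knee(rec)
            row.update(
                label_tfoa=lab.tfoa,
                label_cartilage=lab.medial_cartilage_damage,
                label_osteophyte=lab.medial_osteophyte,
                label_bml=lab.medial_bml,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def percent(count: int, total: int) -> float:
    """A count expressed as a percentage rounded to one decimal, as reported."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def summarize_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of each boolean label column over the cohort."""
    out = []
    n = len(labels)
    for col in labels.columns:
        if labels[col].dtype == bool:
            c = int(labels[col].sum())
            out.append({"label": col, "count": c, "total": n, "percent": percent(c, n)})
    return pd.DataFrame(out)
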