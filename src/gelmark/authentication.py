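"""Species calls, per-sample verdicts, and market-survey aggregation.

A species counts as present in a sample when its specific marker's
gelatin content exceeds the presence threshold (default 5%; "not more
than 5%" reads as not detected). A sample is authentic donkey-hide
gelatin iff donkey — called from its own specific marker DM4, never from
the donkey-horse-shared pharmacopoeia marker — is the only species
present. Fake samples are binned by their adulterant combination.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .constants import CONTENT_THRESHOLD

#: Marker ids accepted in a sample's content map, and the species each
#: species-specific marker calls. CP is carried for reporting only.
MARKER_SPECIES = {"DM4": "donkey", "HM1": "horse", "CM2": "cattle", "PM2": "pig"}
KNOWN_MARKERS = frozenset(MARKER_SPECIES) | {"CP"}

CATEGORIES = (
    "donkey_only",
    "cattle",
    "horse",
    "pig_horse",
    "cattle_horse",
    "donkey_horse",
    "none_detected",
    "other_mixture",
)

#: Adulterant combination -> category. The {horse} entry splits further:
#: horse alone is "horse", horse alongside donkey is "donkey_horse".
_ADULTERANT_CATEGORY = {
    frozenset(): None,  # resolved to donkey_only / none_detected
    frozenset({"cattle"}): "cattle",
    frozenset({"horse"}): "horse",
    frozenset({"pig", "horse"}): "pig_horse",
    frozenset({"cattle", "horse"}): "cattle_horse",
}


@dataclass
class SampleContents:
    """Per-marker percent contents of one commercial sample."""

    sample_id: str
    contents: Mapping[str, float | None]  # marker_id -> % content, None = not detected
    price: float | None = None
    licensed: bool | None = None

    def __post_init__(self) -> None:
        unknown = set(self.contents) - KNOWN_MARKERS
        if unknown:
            raise ValueError(f"unknown marker id(s): {sorted(unknown)}")


@dataclass(frozen=True)
class Verdict:
    sample_id: str
    species_present: frozenset[str]
    label: str  # authentic | fake
    category: str

    def __post_init__(self) -> None:
        if (self.label == "authentic") != (self.species_present == frozenset({"donkey"})):
            raise ValueError("authentic iff donkey is the only species present")


@dataclass
class MarketSummary:
    n_total: int
    n_fake: int
    fake_pct: float
    category_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_fake": self.n_fake,
            "fake_pct": self.fake_pct,
            "category_counts": dict(self.category_counts),
        }


def call_species(content: float | None, threshold: float = CONTENT_THRESHOLD) -> bool:
    """Present iff the marker content exceeds the threshold.

    A content of exactly the threshold ("not more than 5%") is absent,
    as is an undetected marker (None).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return content is not None and content > threshold


def identify_sample(
    contents: SampleContents,
    threshold: float = CONTENT_THRESHOLD,
) -> Verdict:
    """Verdict for one sample from its species-specific marker contents.

    Donkey presence is decided by DM4 alone; the CP content plays no part
    (it cross-reacts with horse). The category names the adulterant
    combination; the lone exception is a horse-only adulterant set, which
    is reported as donkey_horse when donkey is also present.
    """
    present = frozenset(
        sp
        for marker, sp in MARKER_SPECIES.items()
        if call_species(contents.contents.get(marker), threshold)
    )
    adulterants = present - {"donkey"}
    if not present:
        category = "none_detected"
    elif present == frozenset({"donkey"}):
        category = "donkey_only"
    else:
        category = _ADULTERANT_CATEGORY.get(adulterants, "other_mixture")
        if category == "horse" and "donkey" in present:
            category = "donkey_horse"
    label = "authentic" if present == frozenset({"donkey"}) else "fake"
    return Verdict(contents.sample_id, present, label, category)


def summarize_market(verdicts: Sequence[Verdict]) -> MarketSummary:
    """Aggregate verdicts into a market survey summary."""
    n = len(verdicts)
    counts = Counter(v.category for v in verdicts)
    n_fake = sum(1 for v in verdicts if v.label == "fake")
    fake_pct = round(100.0 * n_fake / n, 1) if n else 0.0
    return MarketSummary(
        n_total=n,
        n_fake=n_fake,
        fake_pct=fake_pct,
        category_counts={c: counts.get(c, 0) for c in CATEGORIES},
    )


def verdicts_from_frame(
    survey: pd.DataFrame,
    threshold: float = CONTENT_THRESHOLD,
) -> list[Verdict]:
    """Verdicts for a survey table with one row per sample.

    Expects a ``sample_id`` column plus per-marker content columns named
    by marker id (case-insensitive); NaN means not detected.
    """
    colmap = {c.upper(): c for c in survey.columns}
    verdicts = []
    for row in survey.itertuples(index=False):
        contents: dict[str, float | None] = {}
        for marker in KNOWN_MARKERS:
            col = colmap.get(marker)
            if col is None:
                continue
            value = getattr(row, col)
            contents[marker] = None if pd.isna(value) else float(value)
        verdicts.append(
            identify_sample(SampleContents(str(row.sample_id), contents), threshold)
        )
    return verdicts


def verdicts_to_frame(verdicts: Iterable[Verdict]) -> pd.DataFrame:
    verdicts = list(verdicts)
    return pd.DataFrame(
        {
            "sample_id": [v.sample_id for v in verdicts],
            "species_present": [",".join(sorted(v.species_present)) for v in verdicts],
            "label": [v.label for v in verdicts],
            "category": [v.category for v in verdicts],
        }
    )
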