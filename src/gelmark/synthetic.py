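"""Synthetic multi-species gelatin peptide profiles with planted truth.

The generator emulates the study conditions the screening assumes:
multi-charge (2+..4+) tryptic-peptide ion features in the m/z 100-1200
scan range with 3-peak isotope envelopes, log-normal intensities around
and below the 1e4 detection criterion, retention times across the
gradient, per-batch m/z and RT jitter, singly charged contaminants,
sub-threshold noise peaks, and a planted presence structure (ions shared
by all species, shared by subsets such as donkey+horse, species-specific
markers, and low-consistency candidates seen in a single batch).

Every planted ion is kept well separated from every other co-eluting
peak — in m/z (so 0.1 Da EIC matching is unambiguous and isotope chains
never interleave) and in neutral-mass isotope offsets (so variant
deduplication never merges two distinct planted ions) — which makes the
planted classification counts exact recovery targets rather than
probabilistic ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import ISOTOPE_SPACING, SCAN_RANGE, SPECIES
from .feature_detection import neutral_mass_to_mz
from .peaklist_io import PeakList, SampleMeta
from .quantification import CalibrationCurve
from .reference import (
    INCONSISTENT_HORSE_CANDIDATES,
    load_published_calibration,
    load_specific_markers,
)


class GeneratorError(RuntimeError):
    """Raised when a configuration cannot be satisfied (window too tight)."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions for one simulated reference-sample set.

    Counts describe planted ions per sharing class; windows are (low,
    high) bounds. ``min_separation_mz`` is the minimum monoisotopic m/z
    distance between co-eluting peaks (must exceed twice the screening
    m/z tolerance); ``min_separation_mass`` keeps co-eluting neutral
    masses away from 0/1-isotope offsets of each other so dedup cannot
    merge distinct ions.
    """

    seed: int = 0
    batches: Mapping[str, int] = field(
        default_factory=lambda: {"donkey": 4, "horse": 3, "cattle": 4, "pig": 4}
    )
    shared_all: int = 20
    shared_subsets: Mapping[tuple[str, ...], int] = field(default_factory=dict)
    specific: Mapping[str, int] = field(
        default_factory=lambda: {"donkey": 2, "horse": 1, "cattle": 1, "pig": 1}
    )
    inconsistent: Mapping[str, int] = field(default_factory=dict)
    plant_panel: bool = False  # plant the published marker panel verbatim
    plant_inconsistent_candidates: bool = False
    rt_window: tuple[float, float] = (1.0, 29.0)
    mass_window: tuple[float, float] = (800.0, 3400.0)
    scan_range: tuple[float, float] = SCAN_RANGE
    charge_weights: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.45, 3: 0.40, 4: 0.15}
    )
    log10_intensity_mean: float = 5.0
    log10_intensity_sd: float = 0.5
    min_marker_intensity: float = 1.5e4
    envelope_peaks: int = 3
    mz_jitter: float = 0.02
    rt_jitter: float = 0.1
    contaminants_per_sample: int = 50
    noise_per_sample: int = 200
    noise_log10_mean: float = 3.0
    noise_log10_sd: float = 0.4
    noise_ceiling: float = 9.5e3
    min_separation_mz: float = 4.0
    min_separation_mass: float = 0.2
    # separation window must cover cross-run RT matching (0.5 min) plus
    # two-sided RT jitter, else two planted ions can collapse into one
    # cross-run candidate cluster
    co_elution_window: float = 0.7

    def __post_init__(self) -> None:
        if self.shared_all < 0 or any(v < 0 for v in self.specific.values()):
            raise ValueError("planted counts must be >= 0")
        if any(v < 0 for v in self.shared_subsets.values()):
            raise ValueError("planted counts must be >= 0")
        if self.min_separation_mz <= 0.2:
            raise ValueError("min m/z separation must exceed twice the 0.1 Da tolerance")
        for subset in self.shared_subsets:
            if not set(subset) <= set(SPECIES) or len(subset) < 2 or len(subset) >= len(SPECIES):
                raise ValueError(f"invalid sharing subset {subset!r}")


def paper_scale_config(seed: int = 0) -> GeneratorConfig:
    """The full-scale study preset.

    Plants the published specific markers and low-consistency horse
    candidates at their printed coordinates, 421 shared-all ions, 80
    donkey+horse ions, and enough further shared subsets to pad the four
    species inventories to 569 (donkey), 575 (horse), 474 (cattle), and
    453 (pig) multiply charged ions.
    """
    return GeneratorConfig(
        seed=seed,
        shared_all=421,
        shared_subsets={
            ("donkey", "horse"): 80,
            ("cattle", "donkey", "horse"): 38,
            ("donkey", "horse", "pig"): 20,
            ("cattle", "donkey", "pig"): 1,
            ("cattle", "horse", "pig"): 2,
            ("cattle", "donkey"): 1,
            ("donkey", "pig"): 1,
            ("cattle", "horse"): 8,
            ("horse", "pig"): 2,
        },
        specific={"donkey": 7, "horse": 1, "cattle": 3, "pig": 6},
        inconsistent={"horse": 3},
        plant_panel=True,
        plant_inconsistent_candidates=True,
    )


@dataclass
class PlantedTruth:
    """Ground truth serialized beside every simulated sample set."""

    ions: pd.DataFrame  # ion_id, marker_id, classification, subset, species, mz, charge, rt, neutral_mass, intensity
    presence: pd.DataFrame  # ion_id, sample_id

    def expected_profile_size(self, sample_id: str) -> int:
        """Planted multiply charged ions present in one sample."""
        return int((self.presence.sample_id == sample_id).sum())

    def expected_class_counts(self) -> dict[str, int]:
        """Planted counts keyed by classification / subset / species."""
        counts: dict[str, int] = {}
        for rec in self.ions.itertuples(index=False):
            if rec.classification == "shared_subset":
                key = "shared_subset:" + rec.subset
            elif rec.classification == "specific":
                key = "specific:" + rec.species
            else:
                key = rec.classification
            counts[key] = counts.get(key, 0) + 1
        return counts


def sample_peptide_ion(rng: np.random.Generator, config: GeneratorConfig) -> dict:
    """Draw one peptide-ion prototype consistent with the configuration.

    Neutral mass is uniform in the mass window; charge is drawn from the
    configured 2+/3+/4+ weights; prototypes whose m/z would fall outside
    the scan range are resampled. Intensity is log-normal, clipped up to
    the planted-marker floor so planted ions always clear the detection
    criterion.
    """
    charges = sorted(config.charge_weights)
    weights = np.array([config.charge_weights[z] for z in charges], dtype=float)
    weights /= weights.sum()
    lo, hi = config.scan_range
    # charge first, then mass: resampling only the mass keeps the charge
    # marginals at the configured weights even when part of the mass
    # window maps outside the scan range for a given z
    z = int(rng.choice(charges, p=weights))
    for _ in range(1000):
        mass = rng.uniform(*config.mass_window)
        mz = neutral_mass_to_mz(mass, z)
        if lo <= mz <= hi:
            break
    else:
        raise GeneratorError("mass window incompatible with scan range")
    rt = rng.uniform(*config.rt_window)
    intensity = max(
        10.0 ** rng.normal(config.log10_intensity_mean, config.log10_intensity_sd),
        config.min_marker_intensity,
    )
    return {"neutral_mass": mass, "charge": z, "mz": mz, "rt": rt, "intensity": intensity}


def make_envelope(
    mz_mono: float,
    charge: int,
    rt: float,
    intensity: float,
    n_peaks: int = 3,
    decay: float = 0.6,
) -> pd.DataFrame:
    """Isotope envelope peaks for one ion prototype.

    Peaks sit at mz_mono + k*1.00335/z with geometrically decaying
    intensities from the monoisotopic peak; all share the ion's RT.
    """
    if n_peaks < 1:
        raise ValueError("need at least one peak")
    k = np.arange(n_peaks)
    return pd.DataFrame(
        {
            "mz": mz_mono + k * ISOTOPE_SPACING / charge,
            "intensity": intensity * decay**k,
            "rt": rt,
        }
    )


class _Placer:
    """Rejection-sampling guard enforcing co-elution separation rules."""

    def __init__(self, config: GeneratorConfig) -> None:
        self.cfg = config
        self.rts: list[float] = []
        self.mzs: list[float] = []
        self.masses: list[float] = []

    def conflicts(self, mz: float, rt: float, mass: float | None) -> bool:
        if not self.rts:
            return False
        rts = np.asarray(self.rts)
        close = np.abs(rts - rt) < self.cfg.co_elution_window
        if not close.any():
            return False
        mzs = np.asarray(self.mzs)[close]
        if (np.abs(mzs - mz) < self.cfg.min_separation_mz).any():
            return True
        if mass is not None:
            masses = np.asarray(self.masses)[close]
            masses = masses[masses > 0]
            if masses.size:
                dm = np.abs(masses - mass)
                near_offset = np.minimum(dm % ISOTOPE_SPACING, ISOTOPE_SPACING - dm % ISOTOPE_SPACING)
                if ((dm < 2 * ISOTOPE_SPACING) & (near_offset < self.cfg.min_separation_mass)).any():
                    return True
        return False

    def add(self, mz: float, rt: float, mass: float | None) -> None:
        self.rts.append(rt)
        self.mzs.append(mz)
        self.masses.append(mass if mass is not None else -1.0)


def _plant_ions(rng: np.random.Generator, config: GeneratorConfig) -> pd.DataFrame:
    """Lay out all planted ions with their sharing classes."""
    placer = _Placer(config)
    rows: list[dict] = []

    def register(row: dict) -> None:
        placer.add(row["mz"], row["rt"], row["neutral_mass"])
        row["ion_id"] = f"I{len(rows) + 1:04d}"
        rows.append(row)

    def draw(classification: str, subset: tuple[str, ...], species: str | None) -> None:
        for _ in range(2000):
            proto = sample_peptide_ion(rng, config)
            if not placer.conflicts(proto["mz"], proto["rt"], proto["neutral_mass"]):
                break
        else:
            raise GeneratorError("could not place ion with required separation")
        register(
            {
                "marker_id": "",
                "classification": classification,
                "subset": "+".join(subset),
                "species": species or "",
                "mz": proto["mz"],
                "charge": proto["charge"],
                "rt": proto["rt"],
                "neutral_mass": proto["neutral_mass"],
                "intensity": proto["intensity"],
            }
        )

    specific_counts = dict(config.specific)
    if config.plant_panel:
        panel = load_specific_markers()
        for rec in panel.itertuples(index=False):
            mz, z, rt = float(rec.mz), int(rec.charge), float(rec.rt)
            mass = z * mz - z * 1.007276
            if placer.conflicts(mz, rt, mass):
                raise GeneratorError(f"published marker {rec.marker_id} conflicts with layout")
            intensity = max(
                10.0 ** rng.normal(config.log10_intensity_mean, config.log10_intensity_sd),
                config.min_marker_intensity,
            )
            register(
                {
                    "marker_id": rec.marker_id,
                    "classification": "specific",
                    "subset": rec.species,
                    "species": rec.species,
                    "mz": mz,
                    "charge": z,
                    "rt": rt,
                    "neutral_mass": mass,
                    "intensity": intensity,
                }
            )
            specific_counts[rec.species] = specific_counts.get(rec.species, 0) - 1
        if any(v < 0 for v in specific_counts.values()):
            raise ValueError("specific counts below the published panel size")

    inconsistent_counts = dict(config.inconsistent)
    if config.plant_inconsistent_candidates:
        for mz, z in INCONSISTENT_HORSE_CANDIDATES:
            mass = z * mz - z * 1.007276
            for _ in range(2000):
                rt = rng.uniform(*config.rt_window)
                if not placer.conflicts(mz, rt, mass):
                    break
            else:
                raise GeneratorError("could not place low-consistency candidate")
            intensity = max(
                10.0 ** rng.normal(config.log10_intensity_mean, config.log10_intensity_sd),
                config.min_marker_intensity,
            )
            register(
                {
                    "marker_id": "",
                    "classification": "rejected_inconsistent",
                    "subset": "horse",
                    "species": "horse",
                    "mz": mz,
                    "charge": z,
                    "rt": rt,
                    "neutral_mass": mass,
                    "intensity": intensity,
                }
            )
            inconsistent_counts["horse"] = inconsistent_counts.get("horse", 0) - 1
        if any(v < 0 for v in inconsistent_counts.values()):
            raise ValueError("inconsistent counts below the published candidate list")

    for _ in range(config.shared_all):
        draw("shared_all", tuple(sorted(SPECIES)), None)
    for subset, count in config.shared_subsets.items():
        for _ in range(count):
            draw("shared_subset", tuple(sorted(subset)), None)
    for species, count in specific_counts.items():
        for _ in range(count):
            draw("specific", (species,), species)
    for species, count in inconsistent_counts.items():
        for _ in range(count):
            draw("rejected_inconsistent", (species,), species)

    frame = pd.DataFrame(rows)
    cols = [
        "ion_id", "marker_id", "classification", "subset", "species",
        "mz", "charge", "rt", "neutral_mass", "intensity",
    ]
    return frame.loc[:, cols]


def generate_profiles(config: GeneratorConfig) -> tuple[dict[str, PeakList], PlantedTruth]:
    """Simulate one reference-sample set.

    Returns per-sample peak lists (keyed by sample id) plus the planted
    truth. Every planted ion appears, with seeded per-sample m/z and RT
    jitter, in exactly the batches its sharing class dictates;
    low-consistency candidates appear only in the first batch of their
    species. Singly charged contaminant envelopes and sub-threshold
    noise peaks are added per sample, kept clear of planted envelopes.
    """
    rng = np.random.default_rng(config.seed)
    ions = _plant_ions(rng, config)

    metas = [
        SampleMeta(f"{sp}_b{b}", species=sp, batch=str(b), kind="reference")
        for sp in SPECIES
        for b in range(1, config.batches.get(sp, 0) + 1)
    ]

    presence_rows: list[tuple[str, str]] = []
    for rec in ions.itertuples(index=False):
        member_species = rec.subset.split("+")
        for meta in metas:
            if meta.species not in member_species:
                continue
            if rec.classification == "rejected_inconsistent" and meta.batch != "1":
                continue
            presence_rows.append((rec.ion_id, meta.sample_id))
    presence = pd.DataFrame(presence_rows, columns=["ion_id", "sample_id"])

    ion_index = ions.set_index("ion_id")
    profiles: dict[str, PeakList] = {}
    for meta in metas:
        ion_ids = presence.loc[presence.sample_id == meta.sample_id, "ion_id"]
        parts: list[pd.DataFrame] = []
        local = _Placer(config)
        for ion_id in ion_ids:
            rec = ion_index.loc[ion_id]
            mz = float(rec.mz) + rng.uniform(-config.mz_jitter, config.mz_jitter)
            rt = float(rec.rt) + rng.uniform(-config.rt_jitter, config.rt_jitter)
            intensity = float(rec.intensity) * rng.uniform(0.8, 1.2)
            parts.append(make_envelope(mz, int(rec.charge), rt, intensity, config.envelope_peaks))
            local.add(mz, rt, None)
        for _ in range(config.contaminants_per_sample):
            mz, rt = _place_artifact(rng, config, local)
            intensity = 10.0 ** rng.normal(4.5, 0.4)
            n = int(rng.integers(2, config.envelope_peaks + 1))
            parts.append(make_envelope(mz, 1, rt, intensity, n))
            local.add(mz, rt, None)
        for _ in range(config.noise_per_sample):
            mz, rt = _place_artifact(rng, config, local)
            intensity = min(
                10.0 ** rng.normal(config.noise_log10_mean, config.noise_log10_sd),
                config.noise_ceiling,
            )
            parts.append(pd.DataFrame({"mz": [mz], "intensity": [intensity], "rt": [rt]}))
            local.add(mz, rt, None)
        table = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=["mz", "intensity", "rt"])
        )
        profiles[meta.sample_id] = PeakList(meta, table)

    return profiles, PlantedTruth(ions=ions, presence=presence)


def _place_artifact(
    rng: np.random.Generator, config: GeneratorConfig, local: _Placer
) -> tuple[float, float]:
    lo, hi = config.scan_range
    for _ in range(2000):
        mz = rng.uniform(lo, hi - 2 * ISOTOPE_SPACING)
        rt = rng.uniform(*config.rt_window)
        if not local.conflicts(mz, rt, None):
            return mz, rt
    raise GeneratorError("could not place contaminant/noise peak")


def reported_marker_profiles(
    reported: pd.DataFrame,
    seed: int = 0,
    present_intensity: float = 1.0e5,
    absent_intensity: float = 1.0e3,
) -> list:
    """Plant reported markers into per-species profiles for re-evaluation.

    ``reported`` needs columns mz, charge, plus one 0/1 presence column
    per species. Every marker is planted in every species' profile — at
    ``present_intensity`` where the presence matrix says it was
    observable and at the sub-threshold ``absent_intensity`` otherwise —
    so the detection criteria (peak found, intensity >= 1e4), not the
    planting, decide the outcome. RTs are seeded random (literature
    markers print none).
    """
    from .feature_detection import IonFeature, SampleProfile

    rng = np.random.default_rng(seed)
    rts = rng.uniform(2.0, 28.0, size=len(reported))
    profiles = []
    for sp in SPECIES:
        feats = [
            IonFeature(
                mz_mono=float(rec.mz),
                charge=int(rec.charge),
                rt=float(rt),
                intensity=present_intensity if getattr(rec, sp) else absent_intensity,
            )
            for rec, rt in zip(reported.itertuples(index=False), rts)
        ]
        profiles.append(
            SampleProfile(SampleMeta(f"{sp}_reported", species=sp, batch="1"), feats)
        )
    return profiles


# ---------------------------------------------------------------------------
# Simulated commercial MRM survey
# ---------------------------------------------------------------------------

#: Content ranges (%) drawn per composition category; absent markers get
#: blank-level areas.
_CATEGORY_CONTENTS: dict[str, dict[str, tuple[float, float]]] = {
    "donkey_only": {"donkey": (55.0, 95.0)},
    "cattle": {"cattle": (30.0, 80.0)},
    "horse": {"horse": (40.0, 110.0)},
    "pig_horse": {"pig": (30.0, 50.0), "horse": (15.0, 30.0)},
    "cattle_horse": {"cattle": (30.0, 45.0), "horse": (30.0, 45.0)},
    "donkey_horse": {"donkey": (8.0, 15.0), "horse": (90.0, 110.0)},
    "none_detected": {},
}

_SPECIES_MARKER = {"donkey": "DM4", "horse": "HM1", "cattle": "CM2", "pig": "PM2"}

#: Observed market composition: counts per category in the 110-sample survey.
MARKET_CATEGORY_COUNTS = {
    "donkey_only": 53,
    "cattle": 45,
    "horse": 5,
    "pig_horse": 3,
    "cattle_horse": 1,
    "donkey_horse": 2,
    "none_detected": 1,
}


@dataclass(frozen=True)
class MarketConfig:
    """Conditions for one simulated commercial survey."""

    seed: int = 0
    category_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(MARKET_CATEGORY_COUNTS)
    )
    rel_noise: float = 0.03
    sample_mass_mg: float = 5.0
    cp_donkey_response: float = 0.95
    cp_horse_ratio: tuple[float, float] = (0.45, 0.60)


def generate_market_samples(
    config: MarketConfig,
    curves: Mapping[str, CalibrationCurve] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate MRM peak-area tables for a commercial survey.

    Each sample draws a composition from its category's content ranges;
    areas are the calibration-curve image of those contents with seeded
    relative noise. Absent markers sit at the blank response (the
    curve's intercept), so inverting through the curve recovers ~zero
    content. The pharmacopoeia CP marker responds to donkey and, with a
    per-sample ratio, to horse. Returns (area table, truth table).
    """
    rng = np.random.default_rng(config.seed)
    if curves is None:
        curves = dict(load_published_calibration())
        curves.setdefault("CP", CalibrationCurve("CP", slope=44.607, intercept=49.776, r2=1.0))
    missing = {m for m in _SPECIES_MARKER.values()} | {"CP"}
    missing -= set(curves)
    if missing:
        raise ValueError(f"no calibration curve for marker(s): {sorted(missing)}")

    categories = [
        cat for cat, n in config.category_counts.items() for _ in range(n)
    ]
    rng.shuffle(categories)

    area_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i, cat in enumerate(categories, start=1):
        sample_id = f"M{i:03d}"
        ranges = _CATEGORY_CONTENTS[cat]
        contents = {sp: rng.uniform(*rng_range) for sp, rng_range in ranges.items()}
        cp = config.cp_donkey_response * contents.get("donkey", 0.0)
        cp += rng.uniform(*config.cp_horse_ratio) * contents.get("horse", 0.0)
        truth_rows.append(
            {
                "sample_id": sample_id,
                "category": cat,
                **{sp: contents.get(sp, 0.0) for sp in SPECIES},
                "cp": cp,
            }
        )
        for marker, content in [("CP", cp)] + [
            (_SPECIES_MARKER[sp], contents.get(sp, 0.0)) for sp in SPECIES
        ]:
            curve = curves[marker]
            if content > 0:
                amount = content * config.sample_mass_mg / 100.0
                area = curve.amount_to_area(amount) * (1 + rng.normal(0, config.rel_noise))
            else:
                area = max(curve.intercept * (1 + rng.normal(0, config.rel_noise)), 0.0)
            area_rows.append({"sample_id": sample_id, "marker_id": marker, "area": area})

    return pd.DataFrame(area_rows), pd.DataFrame(truth_rows)


def scaled_config(seed: int = 0, scale: float = 0.1) -> GeneratorConfig:
    """A smaller copy of the full-scale preset for quick runs."""
    full = paper_scale_config(seed)
    return replace(
        full,
        shared_all=max(1, int(full.shared_all * scale)),
        shared_subsets={k: max(1, int(v * scale)) for k, v in full.shared_subsets.items()},
        contaminants_per_sample=10,
        noise_per_sample=30,
    )
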