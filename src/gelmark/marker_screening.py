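"""Cross-species marker screening by tolerant feature matching.

Each candidate ion is looked up in every sample's inventory the way an
extracted ion chromatogram (EIC) is read: the closest feature within the
m/z (and optionally RT) tolerance is taken as the candidate's signal in
that run, and the candidate counts as detected only if that signal meets
the intensity criterion. Set operations over the resulting presence grid
classify every candidate as shared by all species, shared by a subset,
species-specific, or rejected for poor batch consistency.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .constants import MIN_INTENSITY, MZ_TOL, RT_TOL, SPECIES, ISOTOPE_SPACING
from .feature_detection import IonFeature, SampleProfile
from .peaklist_io import SampleMeta

SPECIES_PREFIX = {"donkey": "DM", "horse": "HM", "cattle": "CM", "pig": "PM"}


class MatchResult(NamedTuple):
    detected: bool
    intensity: float | None
    dmz: float | None
    drt: float | None


def match_feature(
    query: IonFeature,
    target: SampleProfile,
    mz_tol: float = MZ_TOL,
    rt_tol: float | None = RT_TOL,
    min_intensity: float = MIN_INTENSITY,
) -> MatchResult:
    """Look a query ion up in a target inventory (EIC-style).

    Among target features within ``mz_tol`` (and ``rt_tol`` when given;
    pass None for reported markers that carry no RT), the best match is
    the one with the smallest |dmz|, ties broken by smallest |drt|. The
    query is detected iff that best match reaches ``min_intensity`` —
    the decision is made on the closest peak, so an intense unrelated
    neighbour further away inside the window cannot stand in for a weak
    candidate at the query m/z.
    """
    best: tuple[float, float, float] | None = None  # (|dmz|, |drt|, intensity)
    for feat in target.features:
        dmz = abs(feat.mz_mono - query.mz_mono)
        if dmz > mz_tol:
            continue
        drt = abs(feat.rt - query.rt)
        if rt_tol is not None and drt > rt_tol:
            continue
        key = (dmz, drt, feat.intensity)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return MatchResult(False, None, None, None)
    dmz, drt, intensity = best
    return MatchResult(intensity >= min_intensity, intensity, dmz, drt)


@dataclass
class PresenceMatrix:
    """Candidate x sample detection grid with matched intensities."""

    candidates: list[IonFeature]
    samples: list[SampleMeta]
    detected: np.ndarray  # bool (n_candidates, n_samples)
    intensity: np.ndarray  # float, NaN where unmatched

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.detected,
            index=[f"{c.mz_mono:.4f}@{c.rt:.2f}" for c in self.candidates],
            columns=[s.sample_id for s in self.samples],
        )


@dataclass
class MarkerCandidate:
    """Screening outcome for one candidate ion."""

    feature: IonFeature
    batch_fraction: dict[str, float]  # species -> detected batches / batches
    classification: str  # shared_all | shared_subset | specific | rejected_inconsistent
    subset: tuple[str, ...]  # species with >=1 detected batch
    species: str | None = None  # set iff classification == "specific"


@dataclass
class MarkerPanel:
    """The final panel of species-specific marker ions."""

    markers: pd.DataFrame  # marker_id, species, mz, rt, charge, intensity

    def __len__(self) -> int:
        return len(self.markers)

    def for_species(self, species: str) -> pd.DataFrame:
        return self.markers[self.markers.species == species]


def collect_candidates(
    profiles: Sequence[SampleProfile],
    mz_tol: float = MZ_TOL,
    rt_tol: float = RT_TOL,
) -> list[IonFeature]:
    """Merge per-sample inventories into one cross-run candidate list.

    Features from all profiles are clustered by single linkage on
    (|dmz| <= mz_tol, |drt| <= rt_tol); each cluster contributes its
    highest-intensity member as the candidate ion.
    """
    feats = [f for p in profiles for f in p.features]
    if not feats:
        return []
    feats.sort(key=lambda f: f.mz_mono)
    mzs = np.array([f.mz_mono for f in feats])
    parent = list(range(len(feats)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(feats)):
        j = i + 1
        while j < len(feats) and mzs[j] - mzs[i] <= mz_tol:
            if abs(feats[j].rt - feats[i].rt) <= rt_tol:
                parent[find(i)] = find(j)
            j += 1
    clusters: dict[int, list[IonFeature]] = {}
    for i, f in enumerate(feats):
        clusters.setdefault(find(i), []).append(f)
    reps = [max(members, key=lambda f: f.intensity) for members in clusters.values()]
    reps.sort(key=lambda f: (f.rt, f.mz_mono))
    return reps


def build_presence_matrix(
    candidates: Sequence[IonFeature],
    profiles: Sequence[SampleProfile],
    mz_tol: float = MZ_TOL,
    rt_tol: float | None = RT_TOL,
    min_intensity: float = MIN_INTENSITY,
    required_species: Sequence[str] = SPECIES,
) -> PresenceMatrix:
    """Screen every candidate against every sample inventory."""
    present_species = {p.meta.species for p in profiles}
    missing = [s for s in required_species if s not in present_species]
    if missing:
        raise ValueError(f"no profiles supplied for species: {', '.join(missing)}")
    n_c, n_s = len(candidates), len(profiles)
    detected = np.zeros((n_c, n_s), dtype=bool)
    intensity = np.full((n_c, n_s), np.nan)
    for i, cand in enumerate(candidates):
        for j, prof in enumerate(profiles):
            res = match_feature(cand, prof, mz_tol, rt_tol, min_intensity)
            detected[i, j] = res.detected
            if res.intensity is not None:
                intensity[i, j] = res.intensity
    return PresenceMatrix(list(candidates), [p.meta for p in profiles], detected, intensity)


def classify_candidates(
    matrix: PresenceMatrix,
    consistency: float = 1.0,
) -> list[MarkerCandidate]:
    """Classify each candidate from its presence pattern.

    A candidate seen (in at least one batch) in every species is
    ``shared_all``; seen in several but not all species, ``shared_subset``;
    seen in a single species in at least ``consistency`` of its batches,
    ``specific``; seen in a single species but in too few batches,
    ``rejected_inconsistent`` (low-consistency candidates are not trusted
    as markers).
    """
    species_cols: dict[str, list[int]] = {}
    for j, meta in enumerate(matrix.samples):
        species_cols.setdefault(meta.species, []).append(j)
    all_species = sorted(species_cols)
    out: list[MarkerCandidate] = []
    for i, feat in enumerate(matrix.candidates):
        frac = {
            sp: float(matrix.detected[i, cols].mean()) for sp, cols in species_cols.items()
        }
        subset = tuple(sorted(sp for sp in all_species if frac[sp] > 0))
        if len(subset) == len(all_species):
            cls, sp = "shared_all", None
        elif len(subset) == 1:
            sp = subset[0]
            if frac[sp] >= consistency:
                cls = "specific"
            else:
                cls, sp = "rejected_inconsistent", None
        else:
            cls, sp = "shared_subset", None
        out.append(MarkerCandidate(feat, frac, cls, subset, sp))
    return out


def dedup_variants(
    candidates: Sequence[MarkerCandidate],
    mass_tol: float = 0.05,
    rt_tol: float = 0.1,
) -> list[MarkerCandidate]:
    """Merge charge-state and first-isotope variants of the same peptide.

    Two candidates are the same molecule observed differently when their
    neutral masses differ by k*1.00335 Da (k in {0, 1}: same isotopologue
    at another charge, or the first heavy isotopologue) within
    ``mass_tol``, at the same retention time within ``rt_tol``. Merging is
    symmetric and idempotent; each merged group keeps its
    highest-intensity member.
    """
    n = len(candidates)
    order = sorted(range(n), key=lambda i: candidates[i].feature.neutral_mass)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    masses = [candidates[i].feature.neutral_mass for i in order]
    for a in range(n):
        for b in range(a + 1, n):
            dm = masses[b] - masses[a]
            if dm > ISOTOPE_SPACING + mass_tol:
                break
            ia, ib = order[a], order[b]
            if abs(candidates[ia].feature.rt - candidates[ib].feature.rt) > rt_tol:
                continue
            if min(abs(dm), abs(dm - ISOTOPE_SPACING)) <= mass_tol:
                parent[find(ia)] = find(ib)
    groups: dict[int, list[MarkerCandidate]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(candidates[i])
    reps = [max(g, key=lambda c: c.feature.intensity) for g in groups.values()]
    reps.sort(key=lambda c: (c.feature.rt, c.feature.mz_mono))
    return reps


def build_marker_panel(candidates: Sequence[MarkerCandidate]) -> MarkerPanel:
    """Assemble specific candidates into an id-bearing marker panel.

    Ids are per-species (DM1..., HM1..., CM1..., PM1...), numbered in
    ascending m/z.
    """
    rows = []
    for species in SPECIES:
        specs = sorted(
            (c for c in candidates if c.classification == "specific" and c.species == species),
            key=lambda c: c.feature.mz_mono,
        )
        for k, cand in enumerate(specs, start=1):
            f = cand.feature
            rows.append(
                {
                    "marker_id": f"{SPECIES_PREFIX[species]}{k}",
                    "species": species,
                    "mz": f.mz_mono,
                    "rt": f.rt,
                    "charge": f.charge,
                    "intensity": f.intensity,
                }
            )
    return MarkerPanel(pd.DataFrame(rows, columns=["marker_id", "species", "mz", "rt", "charge", "intensity"]))


def evaluate_reported_markers(
    reported: pd.DataFrame,
    profiles: Sequence[SampleProfile],
    mz_tol: float = MZ_TOL,
    min_intensity: float = MIN_INTENSITY,
) -> pd.DataFrame:
    """Re-evaluate previously reported markers under the detection criteria.

    ``reported`` needs columns ``mz`` and ``charge`` (no RT is available
    for literature markers, so matching is m/z-only). A marker counts as
    detected in a species iff the closest profile feature within
    ``mz_tol`` reaches ``min_intensity`` in at least one of that species'
    profiles. Returns one row per marker with a detected flag per species.
    """
    if reported.empty:
        return pd.DataFrame(columns=["mz", "charge", *SPECIES])
    rows = []
    for rec in reported.itertuples(index=False):
        query = IonFeature(mz_mono=float(rec.mz), charge=int(rec.charge), rt=0.0, intensity=1.0)
        row = {"mz": float(rec.mz), "charge": int(rec.charge)}
        for sp in SPECIES:
            row[sp] = any(
                match_feature(query, p, mz_tol, rt_tol=None, min_intensity=min_intensity).detected
                for p in profiles
                if p.meta.species == sp
            )
        rows.append(row)
    return pd.DataFrame(rows)
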