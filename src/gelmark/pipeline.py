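"""End-to-end workflows tying the pipeline stages together."""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .authentication import (
    MarketSummary,
    Verdict,
    summarize_market,
    verdicts_from_frame,
)
from .constants import CONTENT_THRESHOLD, MIN_INTENSITY, MZ_TOL, RT_TOL, SAMPLE_MASS_MG
from .feature_detection import SampleProfile, build_profile, group_envelopes
from .marker_screening import (
    MarkerCandidate,
    MarkerPanel,
    build_marker_panel,
    build_presence_matrix,
    classify_candidates,
    collect_candidates,
    dedup_variants,
)
from .peaklist_io import PeakList
from .quantification import CalibrationCurve, content_direct


def profile_sample(peaklist: PeakList, **kwargs) -> SampleProfile:
    """Envelope grouping, charge inference, and inventory filtering."""
    envelopes = group_envelopes(peaklist)
    return build_profile(envelopes, peaklist.meta, **kwargs)


def discover_markers(
    profiles: Sequence[SampleProfile],
    mz_tol: float = MZ_TOL,
    rt_tol: float = RT_TOL,
    min_intensity: float = MIN_INTENSITY,
    consistency: float = 1.0,
) -> tuple[MarkerPanel, list[MarkerCandidate]]:
    """Cross-screen sample inventories and assemble the marker panel.

    Candidates are the union of all inventories (cross-run clustered);
    each is matched EIC-style against every sample, classified by its
    presence pattern with full batch-consistency checking, and
    charge/isotope variants are merged before the specific survivors are
    assigned panel ids.
    """
    candidates = collect_candidates(profiles, mz_tol, rt_tol)
    matrix = build_presence_matrix(
        candidates, profiles, mz_tol, rt_tol, min_intensity,
        required_species=sorted({p.meta.species for p in profiles}),
    )
    classified = dedup_variants(classify_candidates(matrix, consistency))
    return build_marker_panel(classified), classified


def classification_counts(classified: Sequence[MarkerCandidate]) -> dict[str, int]:
    """Screening outcome tally keyed like PlantedTruth.expected_class_counts."""
    counts: dict[str, int] = {}
    for cand in classified:
        if cand.classification == "shared_subset":
            key = "shared_subset:" + "+".join(cand.subset)
        elif cand.classification == "specific":
            key = "specific:" + (cand.species or "")
        else:
            key = cand.classification
        counts[key] = counts.get(key, 0) + 1
    return counts


def quantify_mrm(
    mrm_table: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    sample_mass_mg: float = SAMPLE_MASS_MG,
) -> pd.DataFrame:
    """Convert an MRM area table to a per-sample content table.

    Returns one row per sample with lower-case marker-id columns; an
    absent-flagged content (signal at or below blank) becomes NaN.
    """
    records: dict[str, dict[str, float]] = {}
    for row in mrm_table.itertuples(index=False):
        curve = curves.get(row.marker_id)
        if curve is None:
            raise ValueError(f"no calibration curve for marker {row.marker_id!r}")
        result = content_direct(row.area, curve, sample_mass_mg)
        records.setdefault(str(row.sample_id), {})[row.marker_id.lower()] = (
            float("nan") if result.absent else result.content
        )
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample_id"
    return out.reset_index()


def authenticate_survey(
    survey: pd.DataFrame,
    threshold: float = CONTENT_THRESHOLD,
) -> tuple[list[Verdict], MarketSummary]:
    """Species calls, verdicts, and market summary for a content table."""
    verdicts = verdicts_from_frame(survey, threshold)
    return verdicts, summarize_market(verdicts)
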