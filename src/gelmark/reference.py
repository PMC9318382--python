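"""Published reference data bundled with the package.

These tables transcribe the printed results of the study the pipeline
reimplements: the 17-ion species-specific marker panel, the 32
previously reported donkey markers with their observed presence pattern,
the MRM transitions, the published calibration lines with LOD/LOQ, and
the 110-sample commercial market survey (per-marker percent contents;
'/' in the original prints is an empty cell here, read as NaN).
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .quantification import CalibrationCurve, MrmTransition

#: Horse marker candidates seen in only one horsehide batch and therefore
#: rejected for low consistency (m/z, charge).
INCONSISTENT_HORSE_CANDIDATES = ((455.2539, 2), (552.7825, 2), (716.4201, 2))


def _read(name: str) -> pd.DataFrame:
    with resources.files("gelmark.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


@lru_cache(maxsize=None)
def load_specific_markers() -> pd.DataFrame:
    """The published marker panel: marker_id, species, mz, rt, charge."""
    return _read("specific_markers.tsv")


@lru_cache(maxsize=None)
def load_reported_markers() -> pd.DataFrame:
    """Previously reported donkey markers and their presence pattern.

    Columns: no, mz, charge, then one 0/1 column per species recording
    where each marker was actually observable at >= 1e4 intensity.
    """
    return _read("reported_donkey_markers.tsv")


@lru_cache(maxsize=None)
def load_mrm_transitions() -> list[MrmTransition]:
    """The scheduled MRM transitions (instrument metadata, never computed on)."""
    df = _read("mrm_transitions.tsv")
    return [
        MrmTransition(
            marker_id=r.marker_id,
            precursor_mz=float(r.precursor_mz),
            product_mz=float(r.product_mz),
            charge=int(r.charge),
            rt=float(r.rt),
            fragmentor=float(r.fragmentor),
            collision_energy=float(r.collision_energy),
            role=r.role,
        )
        for r in df.itertuples(index=False)
    ]


@lru_cache(maxsize=None)
def load_published_calibration() -> dict[str, CalibrationCurve]:
    """Published calibration lines keyed by marker id."""
    df = _read("published_calibration.tsv")
    return {
        r.marker_id: CalibrationCurve(
            marker_id=r.marker_id,
            slope=float(r.slope),
            intercept=float(r.intercept),
            r2=float(r.r2),
            lod=float(r.lod_mg),
            loq=float(r.loq_mg),
        )
        for r in df.itertuples(index=False)
    }


@lru_cache(maxsize=None)
def load_market_survey() -> pd.DataFrame:
    """The 110-sample commercial survey: per-marker percent contents.

    Columns: sample_id, cp, dm4, hm1, cm2, pm2, cp_indirect. NaN means
    the marker was not detected ('/' in the printed table).
    """
    with resources.files("gelmark.data").joinpath("market_survey.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values=["/", "NA"], dtype={"sample_id": str})
    for col in ("cp", "dm4", "hm1", "cm2", "pm2", "cp_indirect"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
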