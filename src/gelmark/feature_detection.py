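"""Isotope-envelope grouping, charge inference, and ion-inventory building.

A tryptic peptide carrying z protons produces an isotope envelope whose
peaks are spaced 1.00335/z Th apart (one heavy-isotope increment in
neutral mass per step). Reading that spacing off centroided MS1 peaks
gives the charge state; ions confirmed as doubly, triply, or quadruply
charged are retained as peptide candidates, which removes singly charged
contaminants from the inventory.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    ISOTOPE_SPACING,
    MAX_CHARGE,
    MIN_INTENSITY,
    MZ_LINK_TOL,
    PEPTIDE_CHARGES,
    PROTON_MASS,
    RT_LINK_TOL,
    SPACING_TOL,
)
from .peaklist_io import PeakList, SampleMeta

#: Longest credible gap (Th) between successive isotope peaks (z = 1 plus
#: margin); chains are never extended across a larger gap.
MAX_ENVELOPE_GAP = 1.2


def mz_to_neutral_mass(mz: float, z: int) -> float:
    """Neutral monoisotopic mass M = z*(m/z) - z*m_proton (Da)."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return z * mz - z * PROTON_MASS


def neutral_mass_to_mz(mass: float, z: int) -> float:
    """Inverse of :func:`mz_to_neutral_mass`."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (mass + z * PROTON_MASS) / z


def convert_charge_state(mz: float, z_from: int, z_to: int) -> float:
    """Re-express an ion's m/z at a different charge state.

    The same neutral species observed at z_from and z_to satisfies
    (z_from*mz - z_from*m_p + z_to*m_p) / z_to = mz'.
    """
    if z_from < 1 or z_to < 1:
        raise ValueError("charges must be >= 1")
    return (z_from * mz - z_from * PROTON_MASS + z_to * PROTON_MASS) / z_to


@dataclass(frozen=True)
class IsotopeEnvelope:
    """A chain of co-eluting centroid peaks with a common m/z spacing."""

    mzs: tuple[float, ...]
    intensities: tuple[float, ...]
    rt: float

    def __post_init__(self) -> None:
        if not self.mzs:
            raise ValueError("envelope needs at least one peak")
        if any(b <= a for a, b in zip(self.mzs, self.mzs[1:])):
            raise ValueError("envelope peaks must be strictly increasing in m/z")

    def __len__(self) -> int:
        return len(self.mzs)

    @property
    def spacing(self) -> float | None:
        """Mean successive m/z gap (Th); None for a singleton."""
        if len(self.mzs) < 2:
            return None
        return float(np.mean(np.diff(self.mzs)))

    @property
    def apex_intensity(self) -> float:
        return max(self.intensities)


def infer_charge(env: IsotopeEnvelope, spacing_tol: float = SPACING_TOL) -> int | None:
    """Deduce the charge state from the envelope's isotope spacing.

    The spacing of a z-charged envelope is 1.00335/z Th, so z is the
    nearest integer to 1/spacing; it is accepted only if the observed
    spacing matches 1.00335/z within ``spacing_tol``. Singletons carry no
    spacing information and return None, as do spacings no integer charge
    in [1, MAX_CHARGE] can explain.
    """
    spacing = env.spacing
    if spacing is None or spacing <= 0:
        return None
    z = int(round(1.0 / spacing))
    if not 1 <= z <= MAX_CHARGE:
        return None
    if abs(spacing - ISOTOPE_SPACING / z) > spacing_tol:
        return None
    return z


@dataclass(frozen=True)
class IonFeature:
    """One deisotoped, charge-assigned ion."""

    mz_mono: float
    charge: int
    rt: float
    intensity: float
    neutral_mass: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        expected = mz_to_neutral_mass(self.mz_mono, self.charge)
        if self.neutral_mass is None:
            object.__setattr__(self, "neutral_mass", expected)
        elif abs(self.neutral_mass - expected) > 1e-4:
            raise ValueError(
                f"neutral mass {self.neutral_mass} inconsistent with "
                f"m/z {self.mz_mono} at z={self.charge} (expected {expected:.4f})"
            )


@dataclass
class SampleProfile:
    """The multiply-charged ion inventory of one gelatin sample."""

    meta: SampleMeta
    features: list[IonFeature]

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.rt, f.mz_mono))

    def __len__(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mz_mono": [f.mz_mono for f in self.features],
                "charge": [f.charge for f in self.features],
                "rt": [f.rt for f in self.features],
                "intensity": [f.intensity for f in self.features],
                "neutral_mass": [f.neutral_mass for f in self.features],
                "sample_id": self.meta.sample_id,
            }
        )


def group_envelopes(
    peaklist: PeakList,
    mz_link_tol: float = MZ_LINK_TOL,
    rt_link_tol: float = RT_LINK_TOL,
) -> list[IsotopeEnvelope]:
    """Group centroid peaks into isotope envelopes.

    Peaks are first clustered in retention time (single linkage, gap <=
    ``rt_link_tol``); within each RT cluster, maximal chains are grown in
    ascending m/z: a chain's spacing is set by the gap to the nearest
    unassigned peak (at most MAX_ENVELOPE_GAP) and each further peak must
    continue that spacing within ``mz_link_tol``. Peaks that chain to
    nothing become singleton envelopes.
    """
    table = peaklist.table
    if table.empty:
        return []
    rts = table["rt"].to_numpy()
    # single-linkage RT clusters over the (already rt-sorted) peak list
    breaks = np.flatnonzero(np.diff(rts) > rt_link_tol) + 1
    envelopes: list[IsotopeEnvelope] = []
    for cluster in np.split(np.arange(len(table)), breaks):
        sub = table.iloc[cluster].sort_values("mz", kind="mergesort")
        envelopes.extend(_chain_cluster(sub, mz_link_tol))
    envelopes.sort(key=lambda e: (e.rt, e.mzs[0]))
    return envelopes


def _chain_cluster(sub: pd.DataFrame, mz_link_tol: float) -> list[IsotopeEnvelope]:
    mzs = sub["mz"].to_numpy()
    ints = sub["intensity"].to_numpy()
    rts = sub["rt"].to_numpy()
    n = len(sub)
    assigned = np.zeros(n, dtype=bool)
    out: list[IsotopeEnvelope] = []
    for i in range(n):
        if assigned[i]:
            continue
        chain = [i]
        assigned[i] = True
        spacing = None
        while True:
            last = chain[-1]
            lo = mzs[last]
            if spacing is None:
                # adopt the nearest unassigned peak within the maximal gap
                cand = [
                    j
                    for j in range(last + 1, n)
                    if not assigned[j] and 0 < mzs[j] - lo <= MAX_ENVELOPE_GAP
                ]
                if not cand:
                    break
                j = min(cand, key=lambda k: mzs[k] - lo)
                spacing = mzs[j] - lo
            else:
                target = lo + spacing
                cand = [
                    j
                    for j in range(last + 1, n)
                    if not assigned[j] and abs(mzs[j] - target) <= mz_link_tol
                ]
                if not cand:
                    break
                j = min(cand, key=lambda k: abs(mzs[k] - target))
            chain.append(j)
            assigned[j] = True
        out.append(
            IsotopeEnvelope(
                mzs=tuple(float(mzs[k]) for k in chain),
                intensities=tuple(float(ints[k]) for k in chain),
                rt=float(rts[chain[int(np.argmax([ints[k] for k in chain]))]]),
            )
        )
    return out


def build_profile(
    envelopes: list[IsotopeEnvelope],
    meta: SampleMeta,
    charge_keep: frozenset[int] | set[int] = PEPTIDE_CHARGES,
    min_intensity: float = MIN_INTENSITY,
    spacing_tol: float = SPACING_TOL,
) -> SampleProfile:
    """Build a sample's ion inventory from its envelopes.

    Each envelope whose inferred charge lies in ``charge_keep`` and whose
    apex intensity meets ``min_intensity`` contributes one
    :class:`IonFeature` at its monoisotopic (lowest-m/z) peak. Singletons
    and unexplained spacings carry no charge and are dropped here.
    """
    features = []
    for env in envelopes:
        z = infer_charge(env, spacing_tol)
        if z is None or z not in charge_keep:
            continue
        if env.apex_intensity < min_intensity:
            continue
        features.append(
            IonFeature(
                mz_mono=env.mzs[0],
                charge=z,
                rt=env.rt,
                intensity=env.apex_intensity,
            )
        )
    return SampleProfile(meta=meta, features=features)
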