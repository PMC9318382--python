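import numpy as np
import pandas as pd
import pytest

from gelmark import pipeline, reference, synthetic
from gelmark.feature_detection import IonFeature, SampleProfile
from gelmark.marker_screening import (
    build_presence_matrix,
    classify_candidates,
    collect_candidates,
    dedup_variants,
    evaluate_reported_markers,
    match_feature,
)
from gelmark.peaklist_io import SampleMeta


def _feat(mz, z=2, rt=10.0, intensity=5e4):
    return IonFeature(mz_mono=mz, charge=z, rt=rt, intensity=intensity)


def _profile(name, species, batch, feats):
    return SampleProfile(SampleMeta(name, species=species, batch=batch), feats)


class TestMatchFeature:
    def test_match_inside_mass_accuracy(self):
        target = _profile("h1", "horse", "1", [_feat(766.72, 3, 23.40, 5e4)])
        query = _feat(766.6952, 3, 23.36)
        assert match_feature(query, target).detected

    def test_no_match_outside_mass_accuracy(self):
        target = _profile("h1", "horse", "1", [_feat(766.85, 3, 23.36)])
        assert not match_feature(_feat(766.6952, 3, 23.36), target).detected

    def test_decision_made_on_closest_peak_not_strongest_neighbour(self):
        # a weak peak at the query m/z is the EIC signal even when an
        # intense unrelated ion sits further away inside the window
        target = _profile(
            "d1", "donkey", "1",
            [_feat(765.80, 2, 10.0, 1e3), _feat(765.8556, 2, 10.0, 1e5)],
        )
        res = match_feature(_feat(765.80, 2, 10.0), target)
        assert res.intensity == 1e3
        assert not res.detected

    def test_rt_constraint_can_be_disabled(self):
        target = _profile("d1", "donkey", "1", [_feat(500.0, 2, 25.0)])
        query = _feat(500.0, 2, 1.0)
        assert not match_feature(query, target, rt_tol=0.5).detected
        assert match_feature(query, target, rt_tol=None).detected


class TestPresenceMatrix:
    def _profiles(self):
        return [
            _profile("d1", "donkey", "1", [_feat(500.0), _feat(600.0)]),
            _profile("h1", "horse", "1", [_feat(500.0)]),
            _profile("c1", "cattle", "1", [_feat(500.0)]),
            _profile("p1", "pig", "1", [_feat(500.0)]),
        ]

    def test_complete_grid(self):
        cands = [_feat(500.0), _feat(600.0)]
        m = build_presence_matrix(cands, self._profiles())
        assert m.detected.shape == (2, 4)
        assert m.detected[0].all()
        assert list(m.detected[1]) == [True, False, False, False]

    def test_candidate_absent_everywhere_is_all_false(self):
        m = build_presence_matrix([_feat(900.0)], self._profiles())
        assert not m.detected.any()

    def test_species_without_profiles_is_configuration_error(self):
        with pytest.raises(ValueError, match="pig"):
            build_presence_matrix([_feat(500.0)], self._profiles()[:3])

    def test_published_panel_pattern_recovered_from_planted_run(self):
        config = synthetic.GeneratorConfig(
            seed=3,
            shared_all=10,
            shared_subsets={("donkey", "horse"): 3},
            specific={"donkey": 7, "horse": 1, "cattle": 3, "pig": 6},
            plant_panel=True,
            contaminants_per_sample=5,
            noise_per_sample=20,
        )
        peaklists, _ = synthetic.generate_profiles(config)
        profiles = [pipeline.profile_sample(pl) for pl in peaklists.values()]
        panel = reference.load_specific_markers()
        queries = [
            _feat(float(r.mz), int(r.charge), float(r.rt)) for r in panel.itertuples(index=False)
        ]
        matrix = build_presence_matrix(queries, profiles)
        frame = matrix.to_frame()
        for (_, marker), (_, row) in zip(panel.iterrows(), frame.iterrows()):
            for profile in profiles:
                expected = profile.meta.species == marker.species
                assert row[profile.meta.sample_id] == expected, marker.marker_id


class TestClassifyCandidates:
    def _matrix(self, pattern):
        """pattern: candidate -> {species: detected batch flags}."""
        profiles = []
        for sp, nb in [("donkey", 2), ("horse", 3), ("cattle", 2), ("pig", 2)]:
            for b in range(1, nb + 1):
                feats = []
                for mz, spec in pattern.items():
                    flags = spec.get(sp, [])
                    if len(flags) >= b and flags[b - 1]:
                        feats.append(_feat(mz, rt=5.0))
                profiles.append(_profile(f"{sp}{b}", sp, str(b), feats))
        cands = [_feat(mz, rt=5.0) for mz in pattern]
        return build_presence_matrix(cands, profiles)

    def test_single_batch_detection_is_rejected_inconsistent(self):
        m = self._matrix({455.2539: {"horse": [1, 0, 0]}})
        (cand,) = classify_candidates(m)
        assert cand.classification == "rejected_inconsistent"

    def test_detected_everywhere_is_shared_all(self):
        m = self._matrix({500.0: {sp: [1, 1, 1] for sp in ("donkey", "horse", "cattle", "pig")}})
        (cand,) = classify_candidates(m)
        assert cand.classification == "shared_all"

    def test_all_batches_of_one_species_is_specific(self):
        m = self._matrix({600.0: {"donkey": [1, 1]}})
        (cand,) = classify_candidates(m)
        assert cand.classification == "specific"
        assert cand.species == "donkey"

    def test_relaxed_consistency_accepts_partial_batches(self):
        m = self._matrix({600.0: {"horse": [1, 1, 0]}})
        assert classify_candidates(m)[0].classification == "rejected_inconsistent"
        assert classify_candidates(m, consistency=0.6)[0].classification == "specific"

    def test_every_candidate_gets_exactly_one_classification(self, paper_run):
        _, truth, _, classified = paper_run
        assert len(classified) == len(truth.ions)
        valid = {"shared_all", "shared_subset", "specific", "rejected_inconsistent"}
        assert {c.classification for c in classified} <= valid

    def test_adding_a_species_never_grows_specific_sets(self):
        rng = np.random.default_rng(0)
        mzs = np.sort(200 + 900 * rng.random(12))
        donkey = [_profile("d1", "donkey", "1", [_feat(m, rt=5.0) for m in mzs])]
        horse = [_profile("h1", "horse", "1", [_feat(m, rt=5.0) for m in mzs[:6]])]
        cattle = [_profile("c1", "cattle", "1", [_feat(m, rt=5.0) for m in mzs[6:9]])]
        cands = [_feat(m, rt=5.0) for m in mzs]
        before = classify_candidates(
            build_presence_matrix(cands, donkey + horse, required_species=["donkey", "horse"])
        )
        after = classify_candidates(
            build_presence_matrix(
                cands, donkey + horse + cattle,
                required_species=["donkey", "horse", "cattle"],
            )
        )
        spec_before = {c.feature.mz_mono for c in before if c.classification == "specific"}
        spec_after = {c.feature.mz_mono for c in after if c.classification == "specific"}
        assert spec_before  # donkey-only ions exist before cattle is added
        assert spec_after < spec_before


class TestBruteForceEquivalence:
    """The screening stack agrees with an independent all-pairs matcher."""

    @staticmethod
    def _brute_force(cands, profiles, mz_tol=0.1, rt_tol=0.5, min_int=1e4):
        out = []
        for cand in cands:
            per_species = {}
            for prof in profiles:
                hits = [
                    f
                    for f in prof.features
                    if abs(f.mz_mono - cand.mz_mono) <= mz_tol
                    and abs(f.rt - cand.rt) <= rt_tol
                ]
                det = False
                if hits:
                    best = min(
                        hits,
                        key=lambda f: (abs(f.mz_mono - cand.mz_mono), abs(f.rt - cand.rt)),
                    )
                    det = best.intensity >= min_int
                sp = prof.meta.species
                per_species.setdefault(sp, []).append(det)
            detected = {sp for sp, flags in per_species.items() if any(flags)}
            if not detected:
                cls = "shared_subset"
            elif detected == set(per_species):
                cls = "shared_all"
            elif len(detected) == 1:
                sp = next(iter(detected))
                cls = "specific" if all(per_species[sp]) else "rejected_inconsistent"
            else:
                cls = "shared_subset"
            out.append(cls)
        return out

    @pytest.mark.parametrize("seed", range(4))
    def test_small_profiles_agree(self, seed):
        config = synthetic.GeneratorConfig(
            seed=seed,
            shared_all=5,
            shared_subsets={("donkey", "horse"): 3, ("cattle", "pig"): 2},
            specific={"donkey": 2, "horse": 1, "cattle": 1, "pig": 1},
            inconsistent={"horse": 1},
            contaminants_per_sample=3,
            noise_per_sample=10,
        )
        peaklists, _ = synthetic.generate_profiles(config)
        profiles = [pipeline.profile_sample(pl) for pl in peaklists.values()]
        assert all(len(p) <= 50 for p in profiles)
        cands = collect_candidates(profiles)
        ours = [c.classification for c in classify_candidates(build_presence_matrix(cands, profiles))]
        brute = self._brute_force(cands, profiles)
        assert ours == brute


class TestDedupVariants:
    def _cand(self, mz, z, rt, intensity=1e5):
        m = build_presence_matrix(
            [_feat(mz, z, rt, intensity)],
            [_profile("d1", "donkey", "1", [_feat(mz, z, rt, intensity)])],
            required_species=["donkey"],
        )
        return classify_candidates(m)[0]

    def test_charge_variant_pair_merges(self):
        # the 3+ ion and its 2+ first-isotope form are one molecule
        a = self._cand(766.6952, 3, 23.36, 1e5)
        b = self._cand(1150.0366, 2, 23.36, 5e4)
        merged = dedup_variants([a, b])
        assert len(merged) == 1
        assert merged[0].feature.mz_mono == 766.6952  # highest-intensity member kept

    def test_non_isotope_mass_difference_kept_separate(self):
        a = self._cand(766.6952, 3, 23.36)
        b = self._cand(convert := (2297.563772 + 3 * 1.007276) / 3, 3, 23.36)
        assert abs((3 * convert - 3 * 1.007276) - 2297.563772) < 1e-9
        assert len(dedup_variants([a, b])) == 2

    def test_same_rt_different_peptides_not_merged(self):
        # four distinct co-eluting markers share RT 23.36 but differ by
        # many Da in neutral mass; none may merge
        panel = reference.load_specific_markers()
        co = panel[panel.rt == 23.36]
        cands = [self._cand(float(r.mz), int(r.charge), 23.36) for r in co.itertuples(index=False)]
        assert len(dedup_variants(cands)) == len(cands)

    def test_idempotent(self):
        cands = [
            self._cand(766.6952, 3, 23.36, 1e5),
            self._cand(1150.0366, 2, 23.36, 5e4),
            self._cand(386.2108, 2, 10.36),
        ]
        once = dedup_variants(cands)
        twice = dedup_variants(once)
        assert [c.feature.mz_mono for c in once] == [c.feature.mz_mono for c in twice]


class TestEvaluateReportedMarkers:
    def test_reported_markers_split_twenty_twelve(self):
        reported = reference.load_reported_markers()
        profiles = synthetic.reported_marker_profiles(reported, seed=5)
        table = evaluate_reported_markers(reported, profiles)
        in_both = (table.donkey & table.horse).sum()
        nowhere = (~table[["donkey", "horse", "cattle", "pig"]].any(axis=1)).sum()
        assert (in_both, nowhere) == (20, 12)

    def test_low_intensity_marker_not_detected(self):
        reported = pd.DataFrame({"mz": [767.7234], "charge": [3], "donkey": [0], "horse": [0], "cattle": [0], "pig": [0]})
        profiles = synthetic.reported_marker_profiles(reported)
        table = evaluate_reported_markers(reported, profiles)
        assert not table[["donkey", "horse", "cattle", "pig"]].any().any()

    def test_empty_reported_list(self):
        table = evaluate_reported_markers(pd.DataFrame(columns=["mz", "charge"]), [])
        assert table.empty
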