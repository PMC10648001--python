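"""Sub-formula annotation, recalibration recovery and spectrum cleanup."""

import itertools

import numpy as np
import pytest

from mixlib import annotate, chem
from mixlib.annotate import CleanPolicy, AnnotatedPeak
from mixlib.msio import CompoundEntry, Scan

AMINE = CompoundEntry.from_smiles(
    "A1", "benzofuranamine", "CC1(C)Cc2cccc(N)c2O1")
PRECURSOR_ION = chem.ion_formula(AMINE.formula, "[M+H]+")  # C10H14NO


def brute_force_subformulas(precursor_ion, fragment_mz, tol_ppm, sign=+1):
    """Exhaustive subset enumeration oracle (small precursors only)."""
    syms = sorted(precursor_ion)
    found = []
    for combo in itertools.product(
            *[range(precursor_ion[s] + 1) for s in syms]):
        counts = {s: n for s, n in zip(syms, combo) if n > 0}
        if not counts or chem.rdbe(counts) < -0.5:
            continue
        theo = chem.monoisotopic_mass(counts) - sign * chem.ELECTRON_MASS
        if abs(fragment_mz - theo) <= fragment_mz * tol_ppm * 1e-6:
            found.append(chem.hill_formula(counts))
    return sorted(found)


class TestEnumerateSubformulas:
    def test_identity_fragment(self):
        mz = annotate.ion_mz_of_formula(PRECURSOR_ION, +1)
        candidates = annotate.enumerate_subformulas(PRECURSOR_ION, mz, 5.0)
        assert candidates[0].formula == "C10H14NO"
        assert abs(candidates[0].error_ppm) < 1e-6

    def test_tropylium(self):
        candidates = annotate.enumerate_subformulas(
            PRECURSOR_ION, 91.0542, 5.0)
        assert "C7H7" in [c.formula for c in candidates]

    def test_no_candidate_far_from_any_subformula(self):
        assert annotate.enumerate_subformulas(PRECURSOR_ION, 50.0, 5.0) == []

    def test_sorted_by_absolute_error(self):
        candidates = annotate.enumerate_subformulas(
            PRECURSOR_ION, 120.0808, 20.0)
        errors = [abs(c.error_ppm) for c in candidates]
        assert errors == sorted(errors)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_agrees_with_exhaustive_enumeration(self, seed):
        """Oracle equivalence over random fragment masses on precursors
        with <= 12 heavy atoms."""
        rng = np.random.default_rng(seed)
        precursors = [
            chem.parse_formula("C10H14NO"),
            chem.parse_formula("C6H13O2"),
            chem.parse_formula("C5H12N3O2"),
            chem.parse_formula("C8H10ClO"),
        ]
        for _ in range(25):
            precursor = precursors[int(rng.integers(len(precursors)))]
            mz = float(rng.uniform(15, 220))
            tol = float(rng.uniform(3, 15))
            got = sorted(c.formula for c in annotate.enumerate_subformulas(
                precursor, mz, tol))
            assert got == brute_force_subformulas(precursor, mz, tol)

    def test_mass_conservation(self):
        """Every candidate's mass never exceeds the precursor ion mass."""
        limit = chem.monoisotopic_mass(PRECURSOR_ION)
        for mz in (60.0808, 91.0542, 120.0808, 164.1070):
            for c in annotate.enumerate_subformulas(PRECURSOR_ION, mz, 10.0):
                assert chem.monoisotopic_mass(c.counts) <= limit + 1e-9


class TestAnnotateSpectrum:
    def ground_truth_scan(self, formulas, error_ppm=0.0):
        mzs = []
        for f in formulas:
            theo = annotate.ion_mz_of_formula(chem.parse_formula(f), +1)
            mzs.append(theo * (1 + error_ppm * 1e-6))
        order = np.argsort(mzs)
        return Scan(2, 12.3, np.array(mzs)[order],
                    np.full(len(mzs), 1e5)[order],
                    precursor_mz=164.1070, collision_energy=30.0), \
            [formulas[i] for i in order]

    def test_planted_formulas_fully_assigned(self):
        scan, formulas = self.ground_truth_scan(
            ["C7H7", "C8H10N", "C10H14NO"])
        peaks = annotate.annotate_spectrum(scan, AMINE, "[M+H]+", 5.0)
        assert annotate.assignment_rate(peaks) == 1.0
        assert [p.best.formula for p in peaks] == formulas

    def test_random_noise_all_failpeaks(self):
        scan = Scan(2, 12.3, np.array([47.1113, 52.77, 63.99]),
                    np.array([1e4, 2e4, 3e4]), precursor_mz=164.1070)
        peaks = annotate.annotate_spectrum(scan, AMINE, "[M+H]+", 5.0)
        assert all(p.status == "failpeak" for p in peaks)
        assert annotate.assignment_rate(peaks) == 0.0

    def test_empty_peak_list_errors(self):
        scan = Scan(2, 12.3, np.array([]), np.array([]),
                    precursor_mz=164.1070)
        with pytest.raises(ValueError):
            annotate.annotate_spectrum(scan, AMINE, "[M+H]+", 5.0)


class TestRecalibration:
    def pairs_with_error(self, error_fn, n=40, lo=60.0, hi=600.0):
        theo = np.linspace(lo, hi, n)
        obs = theo * (1 + np.array([error_fn(m) for m in theo]) * 1e-6)
        return list(zip(obs, theo))

    def test_zero_error_model_predicts_zero(self):
        model = annotate.fit_recalibration(self.pairs_with_error(lambda m: 0.0))
        assert np.all(np.abs(model.predict(np.linspace(80, 500, 10))) < 0.1)

    def test_constant_offset_recovered(self):
        model = annotate.fit_recalibration(self.pairs_with_error(lambda m: 5.0))
        pred = model.predict(np.linspace(80, 500, 10))
        assert np.all(np.abs(pred - 5.0) < 0.5)

    def test_linear_curve_recovered(self):
        curve = lambda m: 3.0 + 0.01 * (m - 100.0)
        model = annotate.fit_recalibration(self.pairs_with_error(curve))
        probes = np.linspace(80, 500, 10)
        assert np.all(np.abs(model.predict(probes)
                             - np.array([curve(m) for m in probes])) < 0.5)

    def test_linear_fallback_below_min_pairs(self):
        model = annotate.fit_recalibration(
            self.pairs_with_error(lambda m: 2.0, n=5))
        assert model.kind == "linear-fallback"
        assert model.predict(np.array([300.0]))[0] == pytest.approx(2.0,
                                                                    abs=0.2)

    def test_fewer_than_two_pairs_errors(self):
        with pytest.raises(ValueError):
            annotate.fit_recalibration([(100.0, 100.0)])

    def test_extrapolation_clamped(self):
        curve = lambda m: 3.0 + 0.01 * (m - 100.0)
        model = annotate.fit_recalibration(
            self.pairs_with_error(curve, lo=100, hi=400))
        assert model.predict(np.array([1000.0]))[0] == pytest.approx(
            model.predict(model.x[-1:])[0])
        assert model.predict(np.array([10.0]))[0] == pytest.approx(
            model.predict(model.x[:1])[0])

    def test_identity_model_leaves_scan_unchanged(self):
        scan = Scan(2, 1.0, np.array([100.0, 200.0]), np.array([1.0, 2.0]),
                    precursor_mz=150.0)
        model = annotate.fit_recalibration(
            self.pairs_with_error(lambda m: 0.0))
        out = annotate.apply_recalibration(scan, model)
        assert np.allclose(out.mz, scan.mz, rtol=1e-7)

    def test_idempotence(self):
        """Applying the fitted model to already-corrected data moves m/z
        by < 0.2 ppm median."""
        curve = lambda m: 3.0 + 0.01 * (m - 100.0)
        pairs = self.pairs_with_error(curve)
        model = annotate.fit_recalibration(pairs)
        obs = np.array([p[0] for p in pairs])
        once = obs * (1 - model.predict(obs) * 1e-6)
        pairs2 = list(zip(once, [p[1] for p in pairs]))
        model2 = annotate.fit_recalibration(pairs2)
        twice = once * (1 - model2.predict(once) * 1e-6)
        shift_ppm = np.abs(twice - once) / once * 1e6
        assert np.median(shift_ppm) < 0.2

    def test_median_residual_after_correction(self):
        for curve in (lambda m: 5.0, lambda m: 3.0 + 0.01 * (m - 100.0),
                      lambda m: 2.0 + 3.0 * np.sin(m / 200.0)):
            pairs = self.pairs_with_error(curve)
            model = annotate.fit_recalibration(pairs)
            obs = np.array([p[0] for p in pairs])
            theo = np.array([p[1] for p in pairs])
            corrected = obs * (1 - model.predict(obs) * 1e-6)
            residual = np.abs(corrected - theo) / theo * 1e6
            assert np.median(residual) < 0.5

    def test_assignment_rate_improves_after_recalibration(self):
        """With a +6 ppm planted offset, re-annotation at 2.5 ppm after
        recalibration assigns at least as many peaks as before."""
        formulas = ["C7H7", "C8H10N", "C9H12N", "C10H14NO"]
        theo = [annotate.ion_mz_of_formula(chem.parse_formula(f), +1)
                for f in formulas]
        obs = np.array([m * (1 + 6.0e-6) for m in theo])
        scan = Scan(2, 12.3, obs, np.full(len(obs), 1e5),
                    precursor_mz=164.108, collision_energy=30.0)
        before = annotate.annotate_spectrum(scan, AMINE, "[M+H]+", 2.5)
        wide = annotate.annotate_spectrum(scan, AMINE, "[M+H]+", 10.0)
        model = annotate.fit_recalibration(
            annotate.collect_calibration_pairs([wide]))
        corrected = annotate.apply_recalibration(scan, model)
        after = annotate.annotate_spectrum(corrected, AMINE, "[M+H]+", 2.5)
        assert annotate.assignment_rate(after) \
            >= annotate.assignment_rate(before)
        assert annotate.assignment_rate(after) == 1.0


class TestCleanSpectrum:
    def peak(self, mz, intensity, formula=None):
        candidates = ()
        if formula:
            counts = chem.parse_formula(formula)
            candidates = (annotate.FormulaCandidate(
                counts, annotate.ion_mz_of_formula(counts, +1), 0.0),)
        return AnnotatedPeak(mz=mz, intensity=intensity,
                             candidates=candidates)

    def clean(self, peaks, **kwargs):
        return annotate.clean_spectrum(
            peaks, compound_id="A1", mix="m", polarity="+",
            collision_energy=30.0, precursor_mz=164.1070,
            retention_time=12.3, **kwargs)

    def test_all_assigned_identical_peak_set(self):
        peaks = [self.peak(91.0542, 1e5, "C7H7"),
                 self.peak(164.1070, 2e5, "C10H14NO")]
        out = self.clean(peaks)
        assert out.n_peaks == 2
        assert list(out.mz) == [91.0542, 164.1070]

    def test_failpeak_dropped_by_default(self):
        peaks = [self.peak(91.0542, 1e5, "C7H7"), self.peak(77.7, 9e4)]
        out = self.clean(peaks)
        assert out.n_peaks == 1
        assert out.formulas == ["C7H7"]

    def test_failpeak_retained_when_configured(self):
        peaks = [self.peak(91.0542, 1e5, "C7H7"), self.peak(77.7, 9e4)]
        out = self.clean(peaks, policy=CleanPolicy(drop_failpeaks=False))
        assert out.n_peaks == 2

    def test_duplicate_centroids_merged_intensity_summed(self):
        mz = 150.0
        within = mz * (1 + 3e-6)  # inside the 5 ppm merge width
        peaks = [self.peak(mz, 1e5, "C7H7"), self.peak(within, 3e5, "C7H7")]
        out = self.clean(peaks)
        assert out.n_peaks == 1
        assert out.intensity[0] == pytest.approx(4e5)
        # intensity-weighted position between the two centroids
        assert mz < out.mz[0] < within

    def test_relative_floor_drops_trace_peaks(self):
        peaks = [self.peak(91.0542, 1e6, "C7H7"),
                 self.peak(120.0808, 100.0, "C8H10N")]
        out = self.clean(peaks)
        assert out.n_peaks == 1

    def test_json_round_trip(self):
        peaks = [self.peak(91.0542, 1e5, "C7H7"),
                 self.peak(164.1070, 2e5, "C10H14NO")]
        out = self.clean(peaks)
        back = annotate.spectrum_from_json(annotate.spectrum_to_json(out))
        assert np.array_equal(back.mz, out.mz)
        assert np.array_equal(back.intensity, out.intensity)
        assert back.formulas == out.formulas
        assert back.compound_id == out.compound_id
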