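"""MS1 annotation, ppm mass error, and MS/MS class confirmation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidkit.annotate import (
    DEFAULT_FRAGMENT_RULES,
    PHOSPHOCHOLINE_MZ,
    Annotation,
    FragmentRule,
    MsmsAllScan,
    PeakList,
    Tolerance,
    annotate_peaks,
    identify_msms_all,
    mass_error_ppm,
)
from lipidkit.registry import POSITIVE_ADDUCTS, make_species, theoretical_mz
from lipidkit.simulate import SimConfig, simulate_peaklist


class TestMassErrorPpm:
    def test_identical_inputs_zero(self):
        assert mass_error_ppm(734.5694, 734.5694) == 0.0

    @pytest.mark.parametrize(
        "obs, theo, expected",
        [(734.5700, 734.5694, 0.8168), (734.5688, 734.5694, -0.8168)],
    )
    def test_printed_formula(self, obs, theo, expected):
        # (observed - theoretical) / observed * 1e6, observed in denominator
        assert mass_error_ppm(obs, theo) == pytest.approx(expected, abs=1e-4)

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            mass_error_ppm(0.0, 700.0)

    @given(
        a=st.floats(min_value=100.0, max_value=2000.0),
        delta=st.floats(min_value=-0.5, max_value=0.5),
    )
    def test_asymmetry_bounded(self, a, delta):
        """Swapping arguments flips the sign only approximately (the
        denominator is the observed m/z); the defect is second order."""
        b = a + delta
        if b <= 0:
            return
        fwd, back = mass_error_ppm(a, b), mass_error_ppm(b, a)
        bound = abs(fwd) * abs(a - b) / min(a, b) + 1e-9
        assert abs(fwd + back) <= bound


class TestAnnotatePeaks:
    def test_nearest_candidate_wins_within_window(self, registry):
        sp = make_species("PC", 34, 1)
        target = theoretical_mz(sp, POSITIVE_ADDUCTS[0])
        peaks = PeakList("+", np.array([760.585]), np.array([1.0]))
        anns = annotate_peaks(peaks, registry, POSITIVE_ADDUCTS[:1], Tolerance.imaging())
        assert anns[0] is not None and anns[0].species_id == "PC 34:1"
        assert abs(anns[0].theoretical_mz - target) < 1e-9

    def test_outside_window_unannotated(self, registry):
        peaks = PeakList("+", np.array([500.0]), np.array([1.0]))
        anns = annotate_peaks(peaks, registry, POSITIVE_ADDUCTS[:1], Tolerance(0.05, "Da"))
        assert anns[0] is None

    def test_exact_match_zero_error(self, registry, proton_adduct):
        mz = theoretical_mz(make_species("PC", 32, 0), proton_adduct)
        peaks = PeakList("+", np.array([mz]), np.array([1.0]))
        ann = annotate_peaks(peaks, registry, [proton_adduct], Tolerance.imaging())[0]
        assert ann.delta_mda == 0.0 and ann.ppm == 0.0

    def test_stored_ppm_recomputable_bit_for_bit(self, registry, proton_adduct):
        cfg = SimConfig(seed=5, mz_jitter_sd=0.03, n_decoys=5)
        peaks, _ = simulate_peaklist(cfg, registry, [proton_adduct])
        for ann in annotate_peaks(peaks, registry, [proton_adduct], Tolerance.imaging()):
            if ann is not None:
                assert ann.ppm == mass_error_ppm(ann.observed_mz, ann.theoretical_mz)

    def test_brute_force_candidate_oracle(self, registry, proton_adduct):
        """Exhaustive scan over all (species, adduct) candidates agrees."""
        rng = np.random.default_rng(11)
        cands = [(theoretical_mz(sp, proton_adduct), sp) for sp in registry]
        mzs = np.sort(rng.uniform(400, 1000, size=60))
        peaks = PeakList("+", mzs, np.ones(60))
        tol = Tolerance.imaging()
        anns = annotate_peaks(peaks, registry, [proton_adduct], tol)
        for mz, ann in zip(mzs, anns):
            inside = [(abs(c - mz), sp.total_double_bonds, sp.id) for c, sp in cands
                      if abs(c - mz) <= tol.window(mz)]
            if not inside:
                assert ann is None
            else:
                assert ann is not None and ann.species_id == min(inside)[2]

    def test_undeclared_tolerance_unit_rejected(self, registry):
        peaks = PeakList("+", np.array([760.0]), np.array([1.0]))
        with pytest.raises(TypeError):
            annotate_peaks(peaks, registry, POSITIVE_ADDUCTS, 0.5)
        with pytest.raises(ValueError):
            Tolerance(0.5, "mDa")

    def test_planted_identities_recovered_with_decoys(self, registry, proton_adduct):
        cfg = SimConfig(seed=7, mz_jitter_sd=0.0, n_decoys=20)
        peaks, truth = simulate_peaklist(cfg, registry, [proton_adduct])
        anns = annotate_peaks(peaks, registry, [proton_adduct], Tolerance.imaging())
        for ann, sid in zip(anns, truth.peak_identities):
            if sid is None:
                assert ann is None
            else:
                assert ann is not None and ann.species_id == sid


def _scan(precursor, product_mz, product_intensity, polarity="+"):
    order = np.argsort(product_mz)
    return MsmsAllScan(
        precursor,
        PeakList(polarity, np.asarray(product_mz, float)[order],
                 np.asarray(product_intensity, float)[order]),
    )


class TestIdentifyMsmsAll:
    def test_pc_confirmed_by_head_group_fragment(self, registry):
        scan = _scan(760.58, [184.0733, 500.0], [40.0, 100.0])
        anns = identify_msms_all([scan], registry, POSITIVE_ADDUCTS[:1])
        assert anns[0].species_id.startswith("PC") and anns[0].confirmed is True

    def test_missing_fragment_downgrades_to_ms1(self, registry):
        scan = _scan(760.58, [500.0], [100.0])
        anns = identify_msms_all([scan], registry, POSITIVE_ADDUCTS[:1])
        assert anns[0] is not None and anns[0].confirmed is False

    def test_fragment_below_intensity_floor_not_confirmed(self, registry):
        scan = _scan(760.58, [184.0733, 500.0], [0.5, 100.0])
        anns = identify_msms_all(
            [scan], registry, POSITIVE_ADDUCTS[:1], intensity_floor=0.01
        )
        assert anns[0].confirmed is False

    def test_neutral_loss_rule_confirms_pe(self, registry, proton_adduct):
        pe = make_species("PE", 34, 1)
        prec = theoretical_mz(pe, proton_adduct)
        scan = _scan(prec, [prec - 141.0191, 300.0], [50.0, 100.0])
        anns = identify_msms_all([scan], registry, [proton_adduct])
        assert anns[0].species_id == "PE 34:1" and anns[0].confirmed is True

    def test_polarity_mismatched_rule_skipped_with_warning(self, registry):
        rules = (FragmentRule("PC", "-", PHOSPHOCHOLINE_MZ, "product-ion"),)
        scan = _scan(760.58, [184.0733], [100.0], polarity="+")
        with pytest.warns(UserWarning, match="polarity"):
            anns = identify_msms_all([scan], registry, POSITIVE_ADDUCTS[:1], rules)
        assert anns[0].confirmed is False

    def test_precursor_outside_scan_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            MsmsAllScan(1500.0, PeakList("+", np.array([100.0]), np.array([1.0])))


class TestPeakListInvariants:
    def test_strictly_increasing_required(self):
        with pytest.raises(ValueError):
            PeakList("+", np.array([700.0, 700.0]), np.array([1.0, 1.0]))

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            PeakList("+", np.array([700.0]), np.array([-1.0]))

    def test_default_fragment_rules_cover_confirmable_classes(self):
        assert {r.lipid_class for r in DEFAULT_FRAGMENT_RULES} == {
            "PC", "LysoPC", "SM", "PE", "TAG",
        }
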