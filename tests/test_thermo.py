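"""Two-state model, c*/offset fit, and hydropathy-blob weighting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import foldphase as fp
from foldphase._scales import KYTE_DOOLITTLE_01
from foldphase.thermo import BlobProfile, ThermoConfig, picking_weights


class TestFractionUnfolded:
    def test_symmetry_point(self):
        assert fp.fraction_unfolded(0.0) == 0.5

    @pytest.mark.parametrize("R", [8.314, 8.131])
    def test_stable_variant_mostly_folded(self, R):
        """At dG_U = 13 kJ/mol and 293 K over 99% of molecules are folded."""
        pu = fp.fraction_unfolded(13.0, ThermoConfig(R=R))
        assert 1.0 - pu > 0.99

    @given(st.floats(-500, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_logistic_complement(self, dg):
        assert fp.fraction_unfolded(dg) + fp.fraction_unfolded(-dg) == pytest.approx(1.0)

    def test_monotone_decreasing_and_bounded(self):
        dg = np.linspace(-50, 50, 201)
        pu = fp.fraction_unfolded(dg)
        assert np.all(np.diff(pu) < 0)
        assert np.all((pu > 0) & (pu < 1))

    def test_overflow_safe(self):
        assert fp.fraction_unfolded(1e6) == 0.0
        assert fp.fraction_unfolded(-1e6) == 1.0


class TestPredictCsat:
    def test_half_unfolded_doubles_cstar(self):
        assert fp.predict_csat(12.9, 10.83, shift=-12.9) == pytest.approx(2 * 10.83)

    def test_fully_unfolded_limit_equals_cstar(self):
        assert fp.predict_csat(-100.0, 10.83) == pytest.approx(10.83)

    def test_monotone_in_stability(self):
        dg = np.linspace(-20, 20, 50)
        cs = fp.predict_csat(dg, 10.0)
        assert np.all(np.diff(cs) > 0)

    def test_cap_reports_inaccessible(self):
        assert np.isinf(fp.predict_csat(100.0, 10.0, cap=1e6))

    def test_rejects_nonpositive_cstar(self):
        with pytest.raises(ValueError):
            fp.predict_csat(0.0, -1.0)


class TestFitCstarShift:
    def test_noiseless_recovery(self, noiseless_variants):
        fit = fp.fit_cstar_shift(noiseless_variants)
        assert fit.c_star == pytest.approx(10.83, rel=1e-4)
        assert fit.dG_shift == pytest.approx(-12.9, rel=1e-4)

    def test_permutation_invariance(self, noiseless_variants):
        shuffled = noiseless_variants.sample(frac=1, random_state=3)
        fit = fp.fit_cstar_shift(shuffled)
        assert fit.c_star == pytest.approx(10.83, rel=1e-6)

    def test_intensity_rescaling(self, noiseless_variants):
        """c* scales with the intensity units; the offset does not."""
        scaled = noiseless_variants.copy()
        scaled["csat_au"] *= 7.5
        fit = fp.fit_cstar_shift(scaled)
        assert fit.c_star == pytest.approx(7.5 * 10.83, rel=1e-4)
        assert fit.dG_shift == pytest.approx(-12.9, rel=1e-4)

    def test_identity_csat_times_pu(self, noiseless_variants):
        fit = fp.fit_cstar_shift(noiseless_variants)
        pu = fp.fraction_unfolded(
            noiseless_variants["dG_kJmol"].to_numpy(), shift=fit.dG_shift
        )
        np.testing.assert_allclose(
            noiseless_variants["csat_au"] * pu, fit.c_star, rtol=1e-6
        )

    def test_single_variant_rejected(self, noiseless_variants):
        with pytest.raises(ValueError):
            fp.fit_cstar_shift(noiseless_variants.iloc[:1])

    def test_degenerate_dg_rejected(self):
        df = pd.DataFrame(
            {"dG_kJmol": [5.0] * 5, "csat_au": [12.0] * 5, "name": list("abcde")}
        )
        with pytest.raises(ValueError, match="identifiable"):
            fp.fit_cstar_shift(df)


def _brute_force_blobs(seq):
    """Independent window-enumeration oracle for blob detection."""
    scores = [
        sum(KYTE_DOOLITTLE_01[a] for a in seq[i : i + 3]) / 3
        for i in range(len(seq) - 2)
    ]
    hydro = [s > 0.37 for s in scores]
    phobic, philic = [], []
    i = 0
    while i < len(hydro):
        j = i
        while j + 1 < len(hydro) and hydro[j + 1] == hydro[i]:
            j += 1
        if j - i + 1 >= 4:
            (phobic if hydro[i] else philic).append((i, j + 2))
        i = j + 1
    return phobic, philic


class TestBlobs:
    def test_poly_ile_single_hydrophobic_blob(self):
        prof = fp.detect_blobs("I" * 30)
        assert prof.hydrophobic_blobs == [(0, 29)]
        assert prof.hydrophilic_blobs == []

    def test_poly_gln_single_hydrophilic_blob(self):
        prof = fp.detect_blobs("Q" * 30)
        assert prof.hydrophilic_blobs == [(0, 29)]
        assert prof.hydrophobic_blobs == []

    def test_alternating_tracts_match_hand_table(self):
        # 12 I then 12 K: windows 0-9 hydrophobic; window 10/11 mixed; K-tract
        # windows hydrophilic.  Verified against the enumeration oracle.
        seq = "I" * 12 + "K" * 12
        prof = fp.detect_blobs(seq)
        phobic, philic = _brute_force_blobs(seq)
        assert prof.hydrophobic_blobs == phobic
        assert prof.hydrophilic_blobs == philic

    def test_agrees_with_oracle_on_random_sequences(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(100):
            seq = "".join(rng.choice(aas, 50))
            prof = fp.detect_blobs(seq)
            phobic, philic = _brute_force_blobs(seq)
            assert prof.hydrophobic_blobs == phobic
            assert prof.hydrophilic_blobs == philic

    def test_short_sequence_warns_empty(self):
        with pytest.warns(UserWarning):
            prof = fp.detect_blobs("IK")
        assert len(prof.window_scores) == 0


class TestBlobChange:
    def test_identical_sequences_zero(self):
        p = fp.detect_blobs("I" * 10 + "Q" * 20)
        assert fp.blob_change(p, p) == 0.0

    def test_constructed_pair_hand_count(self):
        """Mutating away an Ile tract loses its hydrophobic blob and gains
        hydrophilic residues; both directions of change are summed.

        Reference Q12-I6-Q12: windows 10..17 contain an Ile (score 0.407 >
        0.37), giving a hydrophobic blob over residues 10..19 (10 residues)
        and hydrophilic blobs 0..11 and 18..29 (24 residues).  The all-Q
        variant is one 30-residue hydrophilic blob, so the change is
        (10 - 0) + (30 - 24) = 16.
        """
        ref = fp.detect_blobs("Q" * 12 + "I" * 6 + "Q" * 12)
        var = fp.detect_blobs("Q" * 30)
        assert ref.hydrophobic_blobs == [(10, 19)]
        assert fp.blob_change(var, ref) == 16.0

    def test_hydrophobic_gains_not_penalized(self):
        ref = fp.detect_blobs("Q" * 30)
        var = fp.detect_blobs("Q" * 12 + "I" * 6 + "Q" * 12)
        assert fp.blob_change(var, ref) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fp.blob_change(fp.detect_blobs("I" * 10), fp.detect_blobs("I" * 11))


class TestConfidenceInterval:
    def test_noiseless_data_gives_tight_interval(self, noiseless_variants):
        ci = fp.cstar_confidence_interval(noiseless_variants, seed=4, n_trials=100)
        assert ci["c_star_mean"] == pytest.approx(10.83, rel=1e-4)
        assert ci["c_star_sd"] == pytest.approx(0.0, abs=1e-6)
        assert ci["dG_shift_sd"] == pytest.approx(0.0, abs=1e-6)

    def test_high_blob_change_variant_floored_not_zeroed(self):
        ref = "Q" * 12 + "I" * 18
        var_df = pd.DataFrame({"sequence": ["Q" * 30]})
        w = picking_weights(var_df, ref)
        assert w[0] == pytest.approx(0.05)

    def test_envelope_brackets_truth_with_noise(self):
        df = fp.gen_variant_table(
            fp.SyntheticVariantParams(noise_cv=0.05, seed=9)
        )
        ci = fp.cstar_confidence_interval(df, seed=9, n_trials=200)
        hi_c, _ = ci["envelope_upper"]
        lo_c, _ = ci["envelope_lower"]
        assert lo_c <= 10.83 * 1.05 and hi_c >= 10.83 * 0.95
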