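"""Patterning z-scores, composition panel, patches, and KS enrichment."""

import numpy as np
import pandas as pd
import pytest

import foldphase as fp
from foldphase.grammar import STUDY_RETAINED_PATCHES, retained_patch_features


class TestPatterningZscores:
    def test_vector_has_36_pairs(self):
        z = fp.patterning_zscores("ACDEFGHIKLMNPQRSTVWY" * 2,
                                  fp.PatterningConfig(seed=0, n_scrambles=100))
        assert len(z) == 36

    def test_homopolymer_all_zero(self):
        z = fp.patterning_zscores("A" * 40, fp.PatterningConfig(seed=0, n_scrambles=100))
        assert (z == 0).all()

    def test_diblock_charge_blockiness_positive(self):
        z = fp.patterning_zscores("K" * 20 + "E" * 20,
                                  fp.PatterningConfig(seed=1, n_scrambles=500))
        assert z["pos-neg"] > 2.0

    def test_reproducible_under_seed(self):
        cfg = fp.PatterningConfig(seed=5, n_scrambles=200)
        seq = "KEKEKKEEKEKKEEAGAGPAPG" * 2
        pd.testing.assert_series_equal(
            fp.patterning_zscores(seq, cfg), fp.patterning_zscores(seq, cfg)
        )

    def test_absent_group_pairs_zero(self):
        z = fp.patterning_zscores("K" * 10 + "E" * 10,
                                  fp.PatterningConfig(seed=0, n_scrambles=100))
        assert z["aro-aro"] == 0.0 and z["pro-gly"] == 0.0

    def test_scrambles_of_sequence_score_near_zero(self):
        """A scrambled sequence evaluated against its own scramble null has
        mean z near 0 across scramble seeds."""
        rng = np.random.default_rng(3)
        base = list("KKEEKKEEGGPPAAFFYYLLSSQQNNHHTT" * 2)
        zs = []
        for seed in range(50):
            rng.shuffle(base)
            z = fp.patterning_zscores(
                "".join(base), fp.PatterningConfig(seed=seed, n_scrambles=150)
            )
            zs.append(z["pos-neg"])
        assert abs(np.mean(zs)) < 0.2


class TestCompositionFeatures:
    def test_panel_has_55_features(self):
        comp = fp.composition_features("ACDEFGHIKLMNPQRSTVWY" * 3)
        assert len(comp) == 55

    def test_poly_arginine(self):
        comp = fp.composition_features("R" * 30)
        assert comp["fraction_R"] == 1.0
        assert comp["ratio_RK"] == 30.0  # no Lys: reported as the Arg count
        assert comp["ncpr"] == 1.0
        assert comp["count_RY"] == 30.0

    def test_rg_and_ala_patch_fractions(self):
        comp = fp.composition_features("RGRGAAAA")
        assert comp["patch_RG"] == pytest.approx(0.5)
        assert comp["patch_A"] == pytest.approx(0.5)

    def test_fractions_bounded(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
        comp = fp.composition_features(seq)
        frac = comp[[c for c in comp.index if c.startswith(("fraction_", "patch_"))]]
        assert ((frac >= 0) & (frac <= 1)).all()

    def test_full_sequence_feature_count_91(self):
        table = fp.grammar_feature_table(
            {"p1": "ACDEFGHIKLMNPQRSTVWY" * 2},
            fp.PatterningConfig(seed=0, n_scrambles=50),
        )
        assert table.shape[1] == 91

    def test_study_patch_retention_has_19_features(self):
        assert len(STUDY_RETAINED_PATCHES) == 19
        assert "patch_M" not in STUDY_RETAINED_PATCHES
        assert "patch_W" not in STUDY_RETAINED_PATCHES

    def test_data_driven_patch_retention(self):
        seqs = {"a": "RRRRGGGG" + "A" * 8, "b": "SSSS" + "Q" * 10}
        kept = retained_patch_features(seqs)
        assert "patch_R" in kept and "patch_A" in kept and "patch_S" in kept
        assert "patch_W" not in kept and "patch_M" not in kept


def _brute_force_patches(seq, target, min_occ, max_gap=2):
    """Enumerate all valid patch substrings; return their union coverage."""
    span = 2 if target == "RG" else 1
    if target == "RG":
        occ = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "RG"]
    else:
        occ = [i for i, a in enumerate(seq) if a == target]
    covered = set()
    for a in range(len(occ)):
        for b in range(a + min_occ - 1, len(occ)):
            gaps_ok = all(
                occ[k + 1] - (occ[k] + span) <= max_gap for k in range(a, b)
            )
            if gaps_ok:
                covered.update(range(occ[a], occ[b] + span))
    return covered


class TestFindPatches:
    def test_minimal_run(self):
        patches, cov = fp.find_patches("AAAA", "A")
        assert patches == [(0, 3)] and cov == 1.0

    def test_long_interruption_splits_and_disqualifies(self):
        patches, cov = fp.find_patches("AAXXXAA", "A")
        assert patches == [] and cov == 0.0

    def test_rg_dipeptide_with_interruption(self):
        patches, cov = fp.find_patches("RGXRG", "RG")
        assert patches == [(0, 4)] and cov == 1.0

    @pytest.mark.parametrize("target", ["A", "R", "RG"])
    def test_agrees_with_enumeration_oracle(self, target):
        rng = np.random.default_rng(13)
        min_occ = 2 if target == "RG" else 4
        for _ in range(200):
            seq = "".join(rng.choice(list("ARGX"), 60))
            patches, cov = fp.find_patches(seq, target)
            mine = set()
            for a, b in patches:
                mine.update(range(a, b + 1))
            oracle = _brute_force_patches(seq, target, min_occ)
            assert mine == oracle, seq


class TestReferenceZscores:
    def test_reference_set_standardised(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(rng.normal(5, 2, (30, 4)),
                             index=[f"p{i}" for i in range(30)],
                             columns=list("wxyz"))
        z = fp.reference_zscores(feats, feats.index)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=0), 1.0, rtol=1e-12)

    def test_protein_at_reference_mean_scores_zero(self):
        feats = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        z = fp.reference_zscores(feats, ["a", "b", "c"])
        assert z.loc["b", "f"] == 0.0

    def test_constant_feature_dropped_not_nan(self):
        feats = pd.DataFrame({"f": [1.0, 1.0, 1.0], "g": [0.0, 1.0, 2.0]},
                             index=["a", "b", "c"])
        z = fp.reference_zscores(feats, ["a", "b", "c"])
        assert "f" not in z.columns
        assert z.attrs["dropped_features"] == ["f"]


class TestAbundanceZscore:
    @staticmethod
    def _table(vals):
        cols = pd.MultiIndex.from_tuples(
            [(g, r) for g in ("A", "B") for r in (1, 2)],
            names=["group", "replicate"],
        )
        return pd.DataFrame(vals, columns=cols)

    def test_uniform_table_all_zero(self):
        tab = self._table(np.ones((5, 4)))
        assert (fp.abundance_zscore(tab) == 0).all()

    def test_enriched_protein_positive(self):
        vals = np.ones((10, 4))
        vals[0] *= 3.0
        tab = self._table(vals)
        assert fp.abundance_zscore(tab, tab.index[0]) > 0

    def test_replicate_permutation_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(0, 0.5, (8, 4))
        tab = self._table(vals)
        shuffled = tab[tab.columns[::-1]]
        pd.testing.assert_series_equal(
            fp.abundance_zscore(tab), fp.abundance_zscore(shuffled)
        )

    def test_missing_protein_rejected(self):
        with pytest.raises(KeyError):
            fp.abundance_zscore(self._table(np.ones((3, 4))), "nope")


class TestKsEnrichment:
    def test_identical_distributions_record_nothing(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.standard_normal((40, 5)),
                         index=[f"p{i}" for i in range(40)])
        out = fp.ks_feature_enrichment(z.iloc[:20], z.iloc[20:].set_index(
            pd.Index([f"q{i}" for i in range(20)])))
        # same-distribution draws: no more than chance-level flags
        assert len(out) <= 1

    def test_shifted_feature_flagged_positive(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame({"f": rng.normal(2.0, 1, 15)},
                         index=[f"a{i}" for i in range(15)])
        b = pd.DataFrame({"f": rng.normal(0.0, 1, 60)},
                         index=[f"b{i}" for i in range(60)])
        out = fp.ks_feature_enrichment(a, b)
        assert len(out) == 1 and out["signed_log10_p"].iloc[0] > 0

    def test_overlapping_sets_rejected(self):
        z = pd.DataFrame({"f": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="disjoint"):
            fp.ks_feature_enrichment(z, z)

    def test_single_member_set_warns(self):
        a = pd.DataFrame({"f": [3.0]}, index=["a"])
        b = pd.DataFrame({"f": np.linspace(-1, 1, 20)},
                         index=[f"b{i}" for i in range(20)])
        with pytest.warns(UserWarning, match="power"):
            fp.ks_feature_enrichment(a, b)
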