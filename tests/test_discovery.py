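"""NSAF, ordination statistics and candidate selection."""

import numpy as np
import pandas as pd
import pytest

from srmkit.discovery import (
    anosim,
    axis_loadings,
    bray_curtis,
    bray_curtis_matrix,
    filter_inferences,
    nsaf,
    select_candidates,
)


class TestFilterInferences:
    def test_survivors_match_hand_count(self, toy_psm_table):
        out = filter_inferences(toy_psm_table, min_peptides=2)
        assert set(out["protein"]) == {"PA", "PD"}

    def test_single_peptide_protein_dropped(self, toy_psm_table):
        out = filter_inferences(toy_psm_table, min_peptides=2)
        assert "PB" not in set(out["protein"])

    def test_no_tryptic_terminus_dropped(self, toy_psm_table):
        # PC has 2 peptides but no row with a tryptic terminus
        out = filter_inferences(toy_psm_table, min_peptides=2)
        assert "PC" not in set(out["protein"])


class TestNSAF:
    def test_single_protein_is_one(self):
        df = pd.DataFrame(
            [{"protein": "P1", "sample": "s1", "spectral_count": 7}]
        )
        mat = nsaf(df, {"P1": 100})
        assert mat.loc["P1", "s1"] == pytest.approx(1.0)

    def test_length_weighting(self):
        df = pd.DataFrame(
            [
                {"protein": "P1", "sample": "s1", "spectral_count": 10},
                {"protein": "P2", "sample": "s1", "spectral_count": 10},
            ]
        )
        mat = nsaf(df, {"P1": 100, "P2": 50})
        assert mat.loc["P1", "s1"] == pytest.approx(1 / 3)
        assert mat.loc["P2", "s1"] == pytest.approx(2 / 3)

    def test_columns_sum_to_one_and_scale_invariance(self, rng):
        rows = [
            {"protein": f"P{i}", "sample": s, "spectral_count": int(rng.integers(1, 50))}
            for i in range(12)
            for s in ("s1", "s2", "s3")
        ]
        df = pd.DataFrame(rows)
        lengths = {f"P{i}": int(rng.integers(80, 400)) for i in range(12)}
        mat = nsaf(df, lengths)
        assert np.allclose(mat.sum(axis=0), 1.0, atol=1e-9)
        scaled = df.assign(spectral_count=df["spectral_count"] * 5)
        assert np.allclose(nsaf(scaled, lengths), mat, atol=1e-12)

    def test_missing_length_names_protein(self):
        df = pd.DataFrame([{"protein": "PX", "sample": "s1", "spectral_count": 3}])
        with pytest.raises(KeyError, match="PX"):
            nsaf(df, {})


class TestBrayCurtis:
    def test_identical_is_zero(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_is_one(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == pytest.approx(1.0)

    def test_known_value(self):
        assert bray_curtis([1, 2, 3], [3, 2, 1]) == pytest.approx(1 / 3)

    def test_bounds_and_symmetry(self, rng):
        for _ in range(30):
            x = rng.uniform(0, 1, size=8)
            y = rng.uniform(0, 1, size=8)
            d = bray_curtis(x, y)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(bray_curtis(y, x))

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


class TestAxisLoadings:
    @pytest.fixture
    def scores(self):
        # 12 samples: the identity permutation is essentially never redrawn,
        # so a perfect loading attains the exact permutation-p floor
        return pd.Series(np.arange(1.0, 13.0), index=list("abcdefghijkl"))

    def test_perfect_correlation_hits_p_floor(self, scores):
        mat = pd.DataFrame([scores * 2.0, scores * 0.5], index=["P1", "P2"])
        res = axis_loadings(mat, scores, n_perm=1000, seed=0)
        assert np.allclose(res["loading"], 1.0)
        assert np.allclose(res["p_value"], 1 / 1001)

    def test_p_floor_matches_reported_minimum(self, scores):
        # permutation floor with 1000 permutations is 1/1001 = 0.000999...
        mat = pd.DataFrame([scores], index=["P1"])
        res = axis_loadings(mat, scores, n_perm=1000, seed=0)
        assert res["p_value"].iloc[0] == pytest.approx(0.000999, abs=1e-6)

    def test_anticorrelated_two_sided(self, scores):
        mat = pd.DataFrame([-scores], index=["P1"])
        res = axis_loadings(mat, scores, n_perm=500, seed=0)
        assert res["loading"].iloc[0] == pytest.approx(-1.0)
        assert res["p_value"].iloc[0] == pytest.approx(1 / 501)

    def test_null_protein_p_uniformish(self, scores, rng):
        mats = pd.DataFrame(
            rng.normal(size=(40, len(scores))), columns=scores.index
        )
        res = axis_loadings(mats, scores, n_perm=200, seed=1)
        assert (res["p_value"] > 0.05).mean() >= 0.9

    def test_constant_row_reported_missing(self, scores):
        mat = pd.DataFrame([[1.0] * 12], index=["P1"], columns=scores.index)
        res = axis_loadings(mat, scores, n_perm=100, seed=0)
        assert np.isnan(res["loading"].iloc[0])
        assert np.isnan(res["p_value"].iloc[0])


class TestAnosim:
    def _dm(self, d):
        labels = list("abcd")
        return pd.DataFrame(d, index=labels, columns=labels)

    def test_perfect_separation_r_one(self):
        # 2 groups of 2; all between-group dissimilarities exceed within
        d = np.array(
            [
                [0.0, 0.1, 0.8, 0.9],
                [0.1, 0.0, 0.7, 0.85],
                [0.8, 0.7, 0.0, 0.2],
                [0.9, 0.85, 0.2, 0.0],
            ]
        )
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        r, p = anosim(self._dm(d), groups, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_tied_dissimilarities_r_zero(self):
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        r, _ = anosim(self._dm(d), groups, n_perm=49, seed=0)
        assert r == pytest.approx(0.0)

    def test_label_invariant_data_r_near_zero_on_average(self, rng):
        n = 8
        labels = [f"s{i}" for i in range(n)]
        rs = []
        for trial in range(30):
            x = rng.normal(size=(n, 5))
            d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
            dm = pd.DataFrame(d, index=labels, columns=labels)
            groups = pd.Series(["g1"] * 4 + ["g2"] * 4, index=labels)
            r, _ = anosim(dm, groups, n_perm=9, seed=trial)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.15

    def test_r_bounds_and_p_floor(self, rng):
        x = rng.normal(size=(6, 4))
        d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        labels = [f"s{i}" for i in range(6)]
        dm = pd.DataFrame(d, index=labels, columns=labels)
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=labels)
        r, p = anosim(dm, groups, n_perm=99, seed=0)
        assert -1.0 <= r <= 1.0
        assert p >= 1 / 100

    def test_single_group_raises(self):
        d = self._dm(np.zeros((4, 4)))
        groups = pd.Series(["g"] * 4, index=list("abcd"))
        with pytest.raises(ValueError):
            anosim(d, groups, n_perm=9, seed=0)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, anosim as sk_anosim

        x = rng.normal(size=(8, 3))
        x[4:] += 2.0
        d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
        labels = [f"s{i}" for i in range(8)]
        dm = pd.DataFrame(d, index=labels, columns=labels)
        groups = pd.Series(["g1"] * 4 + ["g2"] * 4, index=labels)
        r, _ = anosim(dm, groups, n_perm=99, seed=0)
        res = sk_anosim(DistanceMatrix(d, ids=labels), groups.to_numpy(), permutations=99)
        assert r == pytest.approx(res["test statistic"], abs=1e-12)


class TestSelectCandidates:
    @pytest.fixture
    def engineered_table(self):
        """Each criterion fires for exactly one peptide; one shared peptide."""
        dilutions = ["62:1", "250:1", "1000:1"]
        reps = [1, 2]
        rows = []

        def add(dil, rep, prot, pep):
            rows.append(
                {"sample": f"{dil}|rep{rep}", "replicate": rep, "dilution_label": dil,
                 "protein": prot, "peptide": pep, "spectral_count": 3,
                 "tryptic_termini": 2}
            )

        for d in dilutions:
            for r in reps:
                add(d, r, "PU", "UBIQK")       # everywhere -> ubiquitous
                add(d, r, "PS", "SHAREDK")     # everywhere but shared
        add("62:1", 1, "PL", "LOWONLYK")       # only at the low dilution
        add("62:1", 2, "PL", "LOWONLYK")
        for d in dilutions[:2]:
            add(d, 1, "PD", "DRIVERK")         # driver protein, patchy detection
        return pd.DataFrame(rows)

    def test_each_criterion_fires_once(self, engineered_table):
        loadings = pd.DataFrame(
            {"loading": [0.995, 0.2], "p_value": [0.001, 0.4]}, index=["PD", "PU"]
        )
        cands = select_candidates(
            engineered_table,
            loadings,
            shared={"SHAREDK"},
            low_dilutions=["62:1"],
        )
        assert cands.reasons["UBIQK"] == {"ubiquitous"}
        assert cands.reasons["LOWONLYK"] == {"unique-to-low-dilution"}
        assert cands.reasons["DRIVERK"] == {"ordination-driver"}
        assert cands.excluded_shared == {"SHAREDK"}

    def test_shared_excluded_regardless(self, engineered_table):
        cands = select_candidates(
            engineered_table, pd.DataFrame(columns=["loading", "p_value"]),
            shared={"SHAREDK", "UBIQK"}, low_dilutions=["62:1"],
        )
        assert not cands.peptides & {"SHAREDK", "UBIQK"}

    def test_empty_union_is_empty_set(self, engineered_table):
        # keep only the two patchy peptides; no criterion can fire
        sub = engineered_table[
            engineered_table["peptide"].isin(["LOWONLYK", "DRIVERK"])
        ]
        cands = select_candidates(
            sub, pd.DataFrame(columns=["loading", "p_value"]), shared=set()
        )
        assert cands.peptides == set()
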