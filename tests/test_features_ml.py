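"""Feature extraction, benchmark assembly, PPV-rank CV, and scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcrstab import params
from gpcrstab.features import (
    FEATURE_NAMES,
    N_FEATURES,
    FeatureVector,
    assemble_benchmark,
    extract_features,
    feature_matrix,
    _residue_block,
)
from gpcrstab.fixtures import synth_benchmark
from gpcrstab.ml import (
    PredictionModel,
    cv_grid_search,
    default_grid_values,
    enumerate_mutant_space,
    load_ensemble,
    ml_score_features,
    ppv,
    ppv_matrix_to_ranks,
    rank_sums_to_scores,
    save_ensemble,
    select_models,
)
from gpcrstab.numbering import AMINO_ACIDS, Mutation, ReceptorAnnotation


class TestExtractFeatures:
    def test_schema_length_and_order(self, small_bundle):
        model, ann = small_bundle
        pos = model.residues()[4]
        wt = model.residue_type(pos)
        mut_aa = "L" if wt != "L" else "V"
        fv = extract_features(model, Mutation.single(pos, wt, mut_aa), seed=1)
        assert fv.values.shape == (N_FEATURES,)
        assert fv.names == FEATURE_NAMES

    def test_two_mutations_share_vector_length(self, small_bundle):
        model, ann = small_bundle
        vs = []
        for pos in model.residues()[3:5]:
            wt = model.residue_type(pos)
            mut_aa = "K" if wt != "K" else "R"
            vs.append(
                extract_features(model, Mutation.single(pos, wt, mut_aa), seed=1)
            )
        assert len(vs[0].values) == len(vs[1].values)

    def test_sequence_block_matches_packaged_scale(self, small_bundle):
        model, _ = small_bundle
        pos = model.residues()[4]
        wt = model.residue_type(pos)
        fv = extract_features(model, Mutation.single(pos, wt, "A"), seed=1)
        s = fv.as_series()
        scales = params.aa_scales()
        assert s["wt_hydrophobicity"] == float(scales.at[wt, "hydrophobicity"])
        assert s["mut_hydrophobicity"] == float(scales.at["A", "hydrophobicity"])
        assert s["mut_volume"] == float(scales.at["A", "volume"])

    def test_wt_block_is_pure_function_of_the_model(self, small_bundle):
        model, _ = small_bundle
        pos = model.residues()[4]
        assert _residue_block(model, pos) == _residue_block(model, pos)

    def test_double_mutation_rejected(self, small_bundle):
        model, _ = small_bundle
        m = Mutation.from_label("A1^-^C/A7^-^C")
        with pytest.raises(ValueError):
            extract_features(model, m, seed=1)

    def test_unknown_position_rejected(self, small_bundle):
        model, _ = small_bundle
        with pytest.raises(ValueError):
            extract_features(model, Mutation.single(9999, "A", "L"), seed=1)


class TestAssembleBenchmark:
    @staticmethod
    def _stub_extractor(model, mutation, seed):
        return FeatureVector(values=np.zeros(N_FEATURES))

    def test_stabilizing_record_gives_positive_and_reverse(self, small_bundle):
        model, _ = small_bundle
        pos = model.residues()[4]
        wt = model.residue_type(pos)
        records = pd.DataFrame(
            [{"receptor": "r1", "position": pos, "wt": wt, "mut": "A" if wt != "A" else "L", "stabilizing": True}]
        )
        examples = assemble_benchmark(
            records, {"r1": model}, extractor=self._stub_extractor
        )
        assert [e.label for e in examples] == [+1, -1]
        fwd, rev = examples
        assert fwd.mutation.sites[0].wt_aa == rev.mutation.sites[0].mut_aa

    def test_empty_records_give_empty_benchmark(self, small_bundle):
        model, _ = small_bundle
        records = pd.DataFrame(
            columns=["receptor", "position", "wt", "mut", "stabilizing"]
        )
        assert assemble_benchmark(records, {"r1": model}) == []

    def test_label_counts_match_flags(self, small_bundle):
        model, _ = small_bundle
        rows = []
        residues = model.residues()
        for i, pos in enumerate(residues[:10]):
            wt = model.residue_type(pos)
            rows.append(
                {
                    "receptor": "r1",
                    "position": pos,
                    "wt": wt,
                    "mut": "A" if wt != "A" else "L",
                    "stabilizing": i < 3,
                }
            )
        examples = assemble_benchmark(
            pd.DataFrame(rows), {"r1": model}, extractor=self._stub_extractor
        )
        labels = [e.label for e in examples]
        assert labels.count(+1) == 3          # flagged
        assert labels.count(-1) == 3 + 7      # reverses + unflagged

    def test_unknown_receptor_listed_in_error(self, small_bundle):
        model, _ = small_bundle
        records = pd.DataFrame(
            [{"receptor": "nope", "position": 1, "wt": "A", "mut": "L", "stabilizing": False}]
        )
        with pytest.raises(ValueError, match="nope"):
            assemble_benchmark(records, {"r1": model})


class TestPPV:
    @pytest.mark.parametrize(
        "tpr,fpr,expected", [(0.5, 0.5, 0.5), (0.8, 0.2, 0.8), (0.0, 0.3, 0.0)]
    )
    def test_examples(self, tpr, fpr, expected):
        assert ppv(tpr, fpr) == pytest.approx(expected)

    def test_undefined_at_origin(self):
        with pytest.raises(ZeroDivisionError):
            ppv(0.0, 0.0)

    @given(
        t=st.floats(0.001, 1.0), f=st.floats(0.001, 1.0), k=st.floats(0.01, 1.0)
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance_and_range(self, t, f, k):
        assert ppv(k * t, k * f) == pytest.approx(ppv(t, f))
        assert 0.0 <= ppv(t, f) <= 1.0


class TestRankScoring:
    def test_toy_grid_ranks_match_hand_computation(self):
        # 3x3 PPVs; rank 1 = max, ties share the average rank
        ppv_mat = np.array(
            [
                [0.9, 0.5, 0.5],
                [0.2, np.nan, 0.7],
                [0.9, 0.1, 0.0],
            ]
        )
        # sorted desc: 0.9, 0.9 -> ranks (1+2)/2; 0.7 -> 3; 0.5, 0.5 -> 4.5;
        # 0.2 -> 6; 0.1 -> 7; 0.0 -> 8; NaN (undefined) -> n_valid + 1 = 9
        expected = np.array(
            [
                [1.5, 4.5, 4.5],
                [6.0, 9.0, 3.0],
                [1.5, 7.0, 8.0],
            ]
        )
        assert np.allclose(ppv_matrix_to_ranks(ppv_mat), expected)

    def test_rank_sum_normalization(self):
        sums = np.array([[3.0, 6.0], [12.0, 4.0]])
        scores = rank_sums_to_scores(sums)
        assert np.allclose(scores, sums / 12.0)
        assert scores.max() == 1.0

    def test_valid_ranks_sum_to_triangular_number(self):
        rng = np.random.default_rng(0)
        mat = rng.random((5, 5))
        mat[0, 0] = np.nan
        ranks = ppv_matrix_to_ranks(mat)
        valid = np.isfinite(mat)
        n = valid.sum()
        assert ranks[valid].sum() == pytest.approx(n * (n + 1) / 2)


class TestCVGridSearch:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_data():
        examples = synth_benchmark(20, 80, effect=3.0, seed=2)
        return feature_matrix(examples)

    def test_default_grid_axis(self):
        vals = default_grid_values()
        assert len(vals) == 250
        assert vals[0] == pytest.approx(0.2)
        assert vals[-1] == pytest.approx(50.0)
        assert np.all(vals > 0)

    def test_deterministic_given_seed(self, tiny_data):
        X, y = tiny_data
        vals = default_grid_values(4, 10.0)
        a = cv_grid_search(X, y, vals, vals, repeats=2, seed=3)
        b = cv_grid_search(X, y, vals, vals, repeats=2, seed=3)
        assert np.array_equal(a.rank_scores, b.rank_scores)

    def test_single_class_rejected(self):
        X = np.zeros((10, N_FEATURES))
        y = np.ones(10)
        with pytest.raises(ValueError):
            cv_grid_search(X, y, repeats=1)

    def test_scores_normalized_to_max_one(self, tiny_data):
        X, y = tiny_data
        vals = default_grid_values(4, 10.0)
        grid = cv_grid_search(X, y, vals, vals, repeats=2, seed=3)
        assert grid.rank_scores.max() == pytest.approx(1.0)
        assert grid.n_cells == 16


class TestSelectModels:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted():
        examples = synth_benchmark(20, 80, effect=3.0, seed=2)
        X, y = feature_matrix(examples)
        vals = default_grid_values(6, 8.0)
        grid = cv_grid_search(X, y, vals, vals, repeats=3, seed=3)
        return grid, X, y

    def test_k_one_is_single_best_cell(self, fitted):
        grid, X, y = fitted
        models = select_models(grid, X, y, k=1)
        best = np.unravel_index(
            np.argmin(grid.rank_scores), grid.rank_scores.shape
        )
        assert models[0].c_param == grid.c_values[best[0]]
        assert models[0].gamma_param == grid.gamma_values[best[1]]

    def test_weights_sum_to_one(self, fitted):
        grid, X, y = fitted
        models = select_models(grid, X, y, k=3)
        assert sum(m.weight for m in models) == pytest.approx(1.0, abs=1e-9)

    def test_spacing_constraint_separates_cells(self, fitted):
        grid, X, y = fitted
        models = select_models(grid, X, y, k=3, min_spacing=2)
        cells = [
            (
                list(grid.c_values).index(m.c_param),
                list(grid.gamma_values).index(m.gamma_param),
            )
            for m in models
        ]
        for a in range(len(cells)):
            for b in range(a + 1, len(cells)):
                di = abs(cells[a][0] - cells[b][0])
                dj = abs(cells[a][1] - cells[b][1])
                assert max(di, dj) >= 2

    def test_unsatisfiable_k_rejected(self, fitted):
        grid, X, y = fitted
        with pytest.raises(ValueError):
            select_models(grid, X, y, k=50, min_spacing=5)

    def test_ensemble_roundtrips_through_archive(self, fitted, tmp_path):
        grid, X, y = fitted
        models = select_models(grid, X, y, k=2)
        path = tmp_path / "ensemble.joblib"
        save_ensemble(models, grid, path)
        loaded, loaded_grid = load_ensemble(path)
        assert [m.c_param for m in loaded] == [m.c_param for m in models]
        assert np.array_equal(loaded_grid.rank_scores, grid.rank_scores)
        assert np.array_equal(
            ml_score_features(X[:5], loaded), ml_score_features(X[:5], models)
        )


class _StubPipe:
    def __init__(self, votes):
        self.votes = np.asarray(votes)

    def predict(self, X):
        return np.full(len(np.atleast_2d(X)), self.votes)


def _stub_models(weights, votes):
    return [
        PredictionModel(
            c_param=1.0,
            gamma_param=1.0,
            pipeline=_StubPipe(v),
            est_tpr=0.5,
            est_fpr=0.1,
            weight=w,
        )
        for w, v in zip(weights, votes)
    ]


class TestMLScore:
    def test_all_negative_votes_score_zero(self):
        models = _stub_models([0.4, 0.3, 0.3], [-1, -1, -1])
        assert ml_score_features(np.zeros((1, 4)), models)[0] == 0.0

    def test_all_positive_votes_score_one(self):
        models = _stub_models([0.4, 0.3, 0.3], [1, 1, 1])
        assert ml_score_features(np.zeros((1, 4)), models)[0] == pytest.approx(1.0)

    def test_partial_votes_sum_their_weights(self):
        models = _stub_models([0.5, 0.3, 0.2], [1, 1, -1])
        assert ml_score_features(np.zeros((1, 4)), models)[0] == pytest.approx(0.8)

    def test_monotone_in_the_voting_set(self):
        base = _stub_models([0.5, 0.3, 0.2], [-1, 1, -1])
        more = _stub_models([0.5, 0.3, 0.2], [1, 1, -1])
        x = np.zeros((1, 4))
        assert ml_score_features(x, more)[0] >= ml_score_features(x, base)[0]


class TestEnumerateMutantSpace:
    def test_mini_receptor_count(self, mini):
        annotation, _, _ = mini
        muts = enumerate_mutant_space(annotation)
        assert len(muts) == 19 * len(annotation.tm_positions())
        assert len({m.label for m in muts}) == len(muts)

    def test_single_tm_residue_gives_nineteen(self):
        ann = ReceptorAnnotation(sequence="MAW", tm_map={2: "3.50"})
        muts = enumerate_mutant_space(ann)
        assert len(muts) == 19
        assert {m.sites[0].mut_aa for m in muts} == set(AMINO_ACIDS) - {"A"}

    def test_no_tm_residues_gives_empty(self):
        ann = ReceptorAnnotation(sequence="MAW", tm_map={})
        assert enumerate_mutant_space(ann) == []
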