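import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idrscan.alphabet import CANONICAL, AA_INDEX
from idrscan.predictor import (
    InteractionModel,
    energies_to_scores,
    fit_interaction_matrix,
    matrix_entries,
    pair_energy_profile,
    predict_energy,
    predict_scores,
    read_model,
    symmetric_random_matrix,
    write_model,
)


def brute_force_energy(sequence, model):
    """O(L^2) oracle: mean pairwise energy over the separation window."""
    m = model.extended_matrix()
    idx = [AA_INDEX.get(aa, 20) for aa in sequence]
    n = len(idx)
    energies = np.zeros(n)
    for i in range(n):
        terms = [
            m[idx[i], idx[j]]
            for j in range(n)
            if model.k_min <= abs(i - j) <= model.k_max
        ]
        energies[i] = np.mean(terms) if terms else 0.0
    return energies


@pytest.fixture
def model(rng):
    return InteractionModel(M=symmetric_random_matrix(rng), k_min=2, k_max=25, w=1)


aa_text = st.text(alphabet=CANONICAL, min_size=1, max_size=100)


class TestEnergy:
    def test_homopolymer_interior_equals_diagonal_entry(self, model):
        seq = "K" * 200
        energies = pair_energy_profile(seq, model)
        interior = energies[model.k_max : -model.k_max]
        k = AA_INDEX["K"]
        np.testing.assert_allclose(interior, model.M[k, k], atol=1e-12)

    def test_palindrome_energy_is_reversible(self, model):
        seq = "MKPEQ" + "QEPKM"
        energies = pair_energy_profile(seq, model)
        np.testing.assert_allclose(energies, energies[::-1], atol=1e-12)

    def test_random_60mer_matches_bruteforce(self, rng, model):
        seq = "".join(rng.choice(list(CANONICAL), size=60))
        np.testing.assert_allclose(
            predict_energy(seq, model), brute_force_energy(seq, model), atol=1e-10
        )

    @given(seq=aa_text, k_min=st.integers(1, 5), k_max=st.integers(5, 30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_for_all_short_sequences(self, seq, k_min, k_max):
        rng = np.random.default_rng(0)
        model = InteractionModel(
            M=symmetric_random_matrix(rng), k_min=k_min, k_max=k_max, w=1
        )
        np.testing.assert_allclose(
            predict_energy(seq, model), brute_force_energy(seq, model), atol=1e-10
        )

    def test_nonstandard_residue_uses_column_mean(self, model):
        # energy of the neighbor of an X equals what a column-mean partner gives
        e_with_x = pair_energy_profile("KXK", InteractionModel(M=model.M, k_min=1, k_max=1, w=1))
        k = AA_INDEX["K"]
        expected_mid = model.M[:, k].mean()  # X's own energy: mean over column K
        assert e_with_x[1] == pytest.approx(expected_mid)

    def test_empty_sequence_and_strict_mode(self, model):
        with pytest.raises(ValueError, match="empty"):
            predict_energy("", model)
        with pytest.raises(ValueError, match="position 2"):
            predict_energy("KXK", model, strict=True)

    def test_smoothing_window_truncates_at_ends(self, rng):
        m = symmetric_random_matrix(rng)
        raw = pair_energy_profile("MKPEQWLTNV" * 4, InteractionModel(M=m, w=1))
        smooth = predict_energy("MKPEQWLTNV" * 4, InteractionModel(M=m, w=5))
        assert smooth[0] == pytest.approx(raw[:3].mean())
        assert smooth[10] == pytest.approx(raw[8:13].mean())
        assert smooth[-1] == pytest.approx(raw[-3:].mean())


class TestScores:
    def test_logistic_midpoint(self, model):
        scores = energies_to_scores(np.array([model.b]), model)
        assert scores.scores[0] == pytest.approx(0.5)

    def test_saturation_at_large_slope(self, rng):
        steep = InteractionModel(M=symmetric_random_matrix(rng), a=500.0, b=0.0)
        scores = energies_to_scores(np.array([0.5, -0.5]), steep).scores
        assert scores[0] > 0.999
        assert scores[1] < 0.001

    def test_matches_closed_form_and_monotone(self, rng, model):
        energies = np.sort(rng.normal(size=50))
        scores = energies_to_scores(energies, model).scores
        expected = 1 / (1 + np.exp(-model.a * (energies - model.b)))
        np.testing.assert_allclose(scores, expected, atol=1e-12)
        assert np.all(np.diff(scores) >= 0)
        assert np.all((scores > 0) & (scores < 1))

    def test_extreme_energies_clamped_not_overflowing(self, model):
        scores = energies_to_scores(np.array([-1e9, 1e9]), model).scores
        assert np.all((scores >= 0) & (scores <= 1))


def planted_training(rng, n_sequences, model, length=(100, 300)):
    aas = np.array(list(CANONICAL))
    training = []
    for _ in range(n_sequences):
        n = int(rng.integers(*length))
        freqs = rng.dirichlet(np.full(20, 0.5))
        seq = "".join(rng.choice(aas, size=n, p=freqs))
        scores = predict_scores(seq, model).scores
        training.append((seq, (scores >= 0.5).astype(int)))
    return training


class TestFit:
    def test_recovers_planted_matrix(self, rng):
        planted = InteractionModel(
            M=symmetric_random_matrix(rng), k_min=2, k_max=10, w=1
        )
        training = planted_training(rng, 300, planted)
        fitted = fit_interaction_matrix(training, k_min=2, k_max=10, w=1, ridge=1e-8)
        r = np.corrcoef(matrix_entries(fitted), matrix_entries(planted))[0, 1]
        assert r >= 0.9

    def test_degenerate_single_label_rejected(self, rng):
        seqs = ["".join(rng.choice(list(CANONICAL), size=50)) for _ in range(10)]
        training = [(s, [1] * len(s)) for s in seqs]
        with pytest.raises(ValueError, match="degenerate"):
            fit_interaction_matrix(training, ridge=1.0)

    def test_duplicating_training_leaves_fit_unchanged(self, rng):
        planted = InteractionModel(M=symmetric_random_matrix(rng), k_max=10, w=1)
        training = planted_training(rng, 40, planted)
        fit1 = fit_interaction_matrix(training, k_max=10, w=1, ridge=1e-6)
        fit2 = fit_interaction_matrix(training * 2, k_max=10, w=1, ridge=2e-6)
        np.testing.assert_allclose(fit1.M, fit2.M, atol=1e-6)

    def test_too_little_data_without_ridge_rejected(self, rng):
        seq = "".join(rng.choice(list(CANONICAL), size=60))
        labels = [i % 2 for i in range(60)]  # mixed labels, too few residues
        with pytest.raises(ValueError, match="ridge"):
            fit_interaction_matrix([(seq, labels)], ridge=0.0)

    def test_direction_check_on_composition_biased_regions(self, rng):
        """A matrix fitted on synthetic block proteins scores a
        disorder-promoting-biased region above an order-promoting one."""
        from idrscan.synthetic import (
            SyntheticConfig,
            class_biased_frequencies,
            synthesize_proteome,
        )
        from idrscan.alphabet import DISORDER_PROMOTING

        config = SyntheticConfig(
            n_proteins=60, length_range=(80, 250), score_noise_sd=0.0, seed=5
        )
        records, tracks, _ = synthesize_proteome(config)
        training = [
            (r.sequence, (t.scores >= 0.5).astype(int))
            for r, t in zip(records, tracks)
        ]
        fitted = fit_interaction_matrix(training, k_max=10, w=1, ridge=1e-4)
        aas = np.array(list(CANONICAL))
        dp_seq = "".join(rng.choice(aas, size=120, p=class_biased_frequencies(0.9)))
        op_seq = "".join(rng.choice(aas, size=120, p=class_biased_frequencies(0.1)))
        assert (
            predict_scores(dp_seq, fitted).scores.mean()
            > predict_scores(op_seq, fitted).scores.mean()
        )


def test_model_serialization_round_trip(rng, tmp_path):
    model = InteractionModel(
        M=symmetric_random_matrix(rng), k_min=3, k_max=17, w=7, a=1.5, b=-0.2
    )
    path = tmp_path / "model.tsv"
    write_model(model, path)
    loaded = read_model(path)
    np.testing.assert_allclose(loaded.M, model.M, atol=1e-9)
    assert (loaded.k_min, loaded.k_max, loaded.w) == (3, 17, 7)
    assert (loaded.a, loaded.b) == (1.5, -0.2)


def test_model_validation():
    bad = np.zeros((20, 20))
    bad[0, 1] = 1.0  # asymmetric
    with pytest.raises(ValueError, match="symmetric"):
        InteractionModel(M=bad)
    with pytest.raises(ValueError, match="odd"):
        InteractionModel(M=np.zeros((20, 20)), w=4)
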