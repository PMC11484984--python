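"""Active learning: MC-dropout uncertainty, Fisher correlation, greedy batches."""

import numpy as np
import pytest

import cacseg
from cacseg import MultiTaskConfig, MultiTaskModel, PhantomConfig
from cacseg.active_learning import (fisher_information_correlation,
                                    mc_dropout_uncertainty, run_al_loop,
                                    select_batch, select_uncertain_subsets)
from cacseg.multitask import N_CLASSES, SliceSample, build_slice_dataset


SMALL_PHANTOM = PhantomConfig(
    shape=(8, 32, 32), tube_radius=1.8, tube_z_radius=1.4,
    lesion_radius_range=(1.1, 1.3), lesion_z_radius_range=(0.6, 1.0),
    n_lesions=3)


def _sample(channels, z=0.5):
    size = channels.shape[-1]
    return SliceSample(channels=channels, z_frac=z,
                       main_target=np.zeros((size, size), dtype=np.int64),
                       aux_target=np.zeros((size, size), dtype=np.int64),
                       has_cac=False, has_region=False)


def _uniform_model(size=16):
    """Model whose heads output identical logits everywhere."""
    m = MultiTaskModel(MultiTaskConfig(seed=0, dropout=0.0))
    for head in (m.net.head_main, m.net.head_aux):
        head.W.value[...] = 0.0
        head.b.value[...] = 0.0
    return m


# ---------------------------------------------------------------------------
# Monte-Carlo dropout uncertainty

def test_uniform_predictions_have_maximum_entropy():
    m = _uniform_model()
    channels = np.random.default_rng(0).random((6, 16, 16))
    channels[5] = 1.0  # all pixels are candidates
    u = mc_dropout_uncertainty(m, _sample(channels), "main", T=4, seed=0)
    assert u == pytest.approx(np.log(N_CLASSES), abs=1e-6)
    u_aux = mc_dropout_uncertainty(m, _sample(channels), "aux", T=4, seed=0)
    assert u_aux == pytest.approx(np.log(N_CLASSES), abs=1e-6)


def test_one_hot_predictions_have_zero_entropy():
    m = _uniform_model()
    m.net.head_main.b.value[0] = 50.0  # effectively one-hot background
    channels = np.ones((6, 16, 16))
    u = mc_dropout_uncertainty(m, _sample(channels), "main", T=4, seed=0)
    assert u == pytest.approx(0.0, abs=1e-6)


def test_mc_dropout_is_seeded_and_validates_T():
    m = MultiTaskModel(MultiTaskConfig(seed=1))
    channels = np.random.default_rng(1).random((6, 16, 16))
    channels[5] = (channels[5] > 0.5).astype(float)
    s = _sample(channels)
    u1 = mc_dropout_uncertainty(m, s, "aux", T=5, seed=9)
    u2 = mc_dropout_uncertainty(m, s, "aux", T=5, seed=9)
    assert u1 == u2
    assert u1 != mc_dropout_uncertainty(m, s, "aux", T=5, seed=10)
    with pytest.raises(ValueError):
        mc_dropout_uncertainty(m, s, "main", T=1)


def test_main_uncertainty_restricted_to_candidates():
    m = MultiTaskModel(MultiTaskConfig(seed=0))
    channels = np.random.default_rng(2).random((6, 16, 16))
    channels[5] = 0.0  # no candidates: main-task uncertainty defined as 0
    assert mc_dropout_uncertainty(m, _sample(channels), "main", T=3, seed=0) == 0.0


def test_select_uncertain_subsets_rules():
    m = _uniform_model()  # all-equal uncertainties
    rng = np.random.default_rng(0)
    pool = []
    for i in range(6):
        ch = rng.random((6, 16, 16))
        ch[5] = 1.0
        pool.append(_sample(ch, z=i / 5))
    X_U = list(range(6))
    X_M, X_A = select_uncertain_subsets(m, pool, X_U, k_M=6, k_A=3, T=3, seed=0)
    assert X_M == X_U  # k = |X_U| returns everything
    assert X_A == [0, 1, 2]  # ties broken by canonical order
    # a slice with no candidates has zero main uncertainty -> ranked last
    pool[0].channels[5] = 0.0
    X_M, _ = select_uncertain_subsets(m, pool, X_U, k_M=5, k_A=1, T=3, seed=0)
    assert 0 not in X_M
    with pytest.raises(ValueError):
        select_uncertain_subsets(m, pool, [], 1, 1)


# ---------------------------------------------------------------------------
# Fisher information correlation

def brute_force_rho(M, A):
    M, A = np.atleast_2d(M), np.atleast_2d(A)
    i_c = 0.0
    for m in M:
        for a in A:
            i_c += float(np.dot(m, a))
    i_c /= len(M) * len(A)
    i_f_m = float(np.mean([np.dot(m, m) for m in M]))
    i_f_a = float(np.mean([np.dot(a, a) for a in A]))
    return i_c / np.sqrt(i_f_m * i_f_a)


def test_rho_identical_vectors_is_one():
    v = np.array([[1.0, 2.0, -3.0]])
    assert fisher_information_correlation(v, v) == pytest.approx(1.0)


def test_rho_orthogonal_vectors_is_zero():
    a = np.array([[1.0, 0.0, 0.0]])
    b = np.array([[0.0, 1.0, 0.0]])
    assert fisher_information_correlation(a, b) == pytest.approx(0.0, abs=1e-15)


def test_rho_matches_double_loop_oracle():
    rng = np.random.default_rng(7)
    for _ in range(30):
        M = rng.normal(size=(rng.integers(1, 6), 8))
        A = rng.normal(size=(rng.integers(1, 6), 8))
        assert fisher_information_correlation(M, A) == pytest.approx(
            brute_force_rho(M, A), abs=1e-12)


def test_rho_is_bounded_and_validates():
    rng = np.random.default_rng(8)
    for _ in range(50):
        M = rng.normal(size=(3, 5))
        A = rng.normal(size=(4, 5))
        assert abs(fisher_information_correlation(M, A)) <= 1.0 + 1e-12
    with pytest.raises(ValueError):
        fisher_information_correlation(np.zeros((2, 3)), np.ones((2, 3)))
    with pytest.raises(ValueError):
        fisher_information_correlation(np.empty((0, 3)), np.ones((2, 3)))


# ---------------------------------------------------------------------------
# greedy batch selection

def test_select_batch_single_step_is_argmax():
    rng = np.random.default_rng(3)
    M = rng.normal(size=(4, 6))
    A = rng.normal(size=(5, 6))
    cands = [10, 11, 12, 13, 14]
    best = max(range(5), key=lambda j: fisher_information_correlation(M, A[[j]]))
    assert select_batch(M, A, cands, 1) == [cands[best]]


def test_select_batch_full_pool_returns_everything():
    rng = np.random.default_rng(4)
    M = rng.normal(size=(3, 4))
    A = rng.normal(size=(4, 4))
    assert sorted(select_batch(M, A, [0, 1, 2, 3], 4)) == [0, 1, 2, 3]
    with pytest.raises(ValueError):
        select_batch(M, A, [0, 1, 2, 3], 5)


def test_greedy_equals_stepwise_exhaustive_argmax():
    """Each greedy step must pick exactly the exhaustive argmax over the
    remaining candidates (on pools small enough to enumerate)."""
    rng = np.random.default_rng(5)
    for trial in range(10):
        M = rng.normal(size=(4, 6))
        A = rng.normal(size=(8, 6))
        cands = list(range(8))
        got = select_batch(M, A, cands, 3)
        chosen: list[int] = []
        for _ in range(3):
            rest = [j for j in cands if j not in chosen]
            step_best = max(rest, key=lambda j: (
                fisher_information_correlation(M, A[chosen + [j]]),
                -j))  # ties toward lower index, as in the implementation
            chosen.append(step_best)
        assert got == chosen


# ---------------------------------------------------------------------------
# the full loop

@pytest.fixture(scope="module")
def al_pool():
    cases = [cacseg.generate_phantom(SMALL_PHANTOM, seed=300 + s)
             for s in range(3)]
    return build_slice_dataset(cases, region_fraction=1.0, seed=0)


def test_al_loop_bookkeeping_and_determinism(al_pool):
    cfg = MultiTaskConfig(seed=0, epochs=2)
    model, state = run_al_loop(al_pool, cfg, initial_labeled=4, n_rounds=2,
                               budget=3, k_uncertain=6, T=3,
                               epochs_per_round=1, final_epochs=1, seed=5)
    assert state.round_index == 2
    assert len(state.X_L) == 4 + 2 * 3
    assert set(state.X_L) | set(state.X_U) == set(range(len(al_pool)))
    assert not set(state.X_L) & set(state.X_U)
    assert [h["round"] for h in state.history] == [1, 2]
    selected = [i for h in state.history for i in h["selected"]]
    assert len(selected) == len(set(selected))  # no slice selected twice

    _, state2 = run_al_loop(al_pool, cfg, initial_labeled=4, n_rounds=2,
                            budget=3, k_uncertain=6, T=3,
                            epochs_per_round=1, final_epochs=1, seed=5)
    assert state2.history == state.history  # fully seeded


def test_al_loop_zero_rounds_trains_on_initial_only(al_pool):
    cfg = MultiTaskConfig(seed=0)
    model, state = run_al_loop(al_pool, cfg, initial_labeled=5, n_rounds=0,
                               budget=3, epochs_per_round=1, final_epochs=1,
                               seed=1)
    assert state.round_index == 0
    assert len(state.X_L) == 5
    assert state.history == []


def test_al_loop_budget_exhausting_pool_raises(al_pool):
    with pytest.raises(ValueError, match="budget"):
        run_al_loop(al_pool, initial_labeled=len(al_pool), n_rounds=1, budget=1)


def test_al_selection_enriched_for_informative_slices(al_pool):
    """With blank-air slices diluting the pool, AL selection should favour
    anatomy-bearing slices at least at the pool base rate."""
    blank = np.full((6, 32, 32), 0.0)
    blank[:5] = 0.013  # ~ -1950 HU normalized: air
    pool = list(al_pool) + [
        SliceSample(channels=blank.copy(), z_frac=0.5,
                    main_target=np.zeros((32, 32), dtype=np.int64),
                    aux_target=np.zeros((32, 32), dtype=np.int64),
                    has_cac=False, has_region=False)
        for _ in range(len(al_pool))
    ]
    n_anatomy = len(al_pool)
    base_rate = n_anatomy / len(pool)
    cfg = MultiTaskConfig(seed=0)
    _, state = run_al_loop(pool, cfg, initial_labeled=4, n_rounds=2, budget=4,
                           k_uncertain=10, T=3, epochs_per_round=1,
                           final_epochs=1, seed=3)
    selected = [i for h in state.history for i in h["selected"]]
    frac_anatomy = np.mean([i < n_anatomy for i in selected])
    assert frac_anatomy >= base_rate
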