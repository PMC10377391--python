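import numpy as np
import pytest

from voicegate import (
    NMFModel,
    ObjectiveVector,
    ParetoCandidate,
    SynthSpec,
    StftConfig,
    clean_spectrogram,
    generate,
    hoyer_sparsity,
    nmf_factorize,
    objective_vector,
    pareto_front,
    select_solution,
    stft,
)

_EPS = 1e-12


def reference_update_recursion(V, k, lam, n_iter, seed):
    """Independent straight-line re-implementation of the update recursion."""
    m, n = V.shape
    r = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = r.uniform(0.0, 1.0, size=(m, k)) * scale
    H = r.uniform(0.0, 1.0, size=(k, n)) * scale
    for _ in range(n_iter):
        H = H * (W.T @ V) / (W.T @ W @ H + lam + _EPS)
        W = W * (V @ H.T) / (W @ H @ H.T + _EPS)
        col = np.sqrt((W * W).sum(axis=0))
        col[col == 0] = 1.0
        W = W / col
        H = H * col[:, None]
    resid = V - W @ H
    return float((resid * resid).sum() + lam * np.abs(H).sum())


def test_rank1_exact_factorization():
    V = np.outer([1.0, 2.0], [3.0, 4.0, 5.0])
    model = nmf_factorize(V, k=1, max_iter=500, tol=0.0, seed=0)
    obj = objective_vector(V, model, k_max=1)
    assert obj.f1_recon < 1e-6


def test_diagonal_rank4_with_restarts():
    # multiplicative updates can stall in local minima on sparse targets
    # like a diagonal; the exact factorization is reached under restarts
    V = np.diag([1.0, 2.0, 3.0, 4.0])
    best = min(
        objective_vector(V, nmf_factorize(V, k=4, max_iter=5000, tol=0.0, seed=s), 4).f1_recon
        for s in range(8)
    )
    assert best < 1e-3


def test_matches_independent_update_recursion(rng):
    V = rng.uniform(0.1, 1.0, size=(6, 8))
    model = nmf_factorize(V, k=2, lambda_sparsity=0.0, max_iter=300, tol=0.0, seed=42)
    got = model.objective_history[-1]
    want = reference_update_recursion(V, 2, 0.0, 300, 42)
    assert got == pytest.approx(want, rel=1e-8)


def test_penalized_objective_matches_oracle_with_sparsity(rng):
    V = rng.uniform(0.0, 2.0, size=(7, 5))
    model = nmf_factorize(V, k=3, lambda_sparsity=0.5, max_iter=150, tol=0.0, seed=7)
    want = reference_update_recursion(V, 3, 0.5, 150, 7)
    assert model.objective_history[-1] == pytest.approx(want, rel=1e-8)


def test_objective_monotone_without_penalty():
    """Classical multiplicative-update monotonicity on 50 seeded problems."""
    for seed in range(50):
        r = np.random.default_rng(seed)
        V = r.uniform(0.0, 1.0, size=(10, 12))
        model = nmf_factorize(V, k=3, max_iter=60, tol=0.0, seed=seed)
        h = model.objective_history
        assert np.all(np.diff(h) <= 1e-10 * np.maximum(h[:-1], 1.0)), f"seed {seed}"


def test_nonnegativity_and_determinism(rng):
    V = rng.uniform(0.0, 1.0, size=(9, 11))
    a = nmf_factorize(V, k=4, lambda_sparsity=0.1, max_iter=100, seed=5)
    b = nmf_factorize(V, k=4, lambda_sparsity=0.1, max_iter=100, seed=5)
    assert np.all(a.W >= 0) and np.all(a.H >= 0)
    np.testing.assert_array_equal(a.W, b.W)
    np.testing.assert_array_equal(a.H, b.H)


def test_input_validation():
    with pytest.raises(ValueError, match="non-negative"):
        nmf_factorize(np.array([[-1.0, 2.0]]), k=1)
    with pytest.raises(ValueError, match="rank"):
        nmf_factorize(np.ones((3, 3)), k=5)


def test_hoyer_extremes():
    one_hot = np.zeros((3, 4))
    one_hot[1, 2] = 7.0
    assert hoyer_sparsity(one_hot) == pytest.approx(1.0)
    assert hoyer_sparsity(np.full((3, 4), 2.5)) == pytest.approx(0.0, abs=1e-12)
    assert hoyer_sparsity(np.zeros((2, 2))) == 1.0


def test_perfect_factorization_objective():
    W = np.array([[1.0], [2.0]])
    H = np.array([[3.0, 4.0]])
    model = NMFModel(W=W, H=H, k=1, lambda_sparsity=0.0, n_iter_run=0, converged=True)
    obj = objective_vector(W @ H, model, k_max=2)
    assert obj.f1_recon == pytest.approx(0.0, abs=1e-12)
    assert obj.f3_complexity == 0.5


def _cand(*objs):
    model = NMFModel(
        W=np.ones((1, 1)), H=np.ones((1, 1)), k=1, lambda_sparsity=0.0,
        n_iter_run=0, converged=True,
    )
    return ParetoCandidate(model, ObjectiveVector(*objs))


def test_worked_three_point_front():
    cands = [_cand(1, 2, 0), _cand(2, 1, 0), _cand(3, 3, 0)]
    front = pareto_front(cands)
    assert [c.objectives.f1_recon for c in front] == [1, 2]
    assert not cands[2].on_front


def test_single_candidate_on_front():
    cands = [_cand(5, 5, 5)]
    assert pareto_front(cands) == cands
    assert select_solution(cands) is cands[0]


def test_front_matches_brute_force(rng):
    objs = rng.uniform(0, 1, size=(20, 3))
    cands = [_cand(*row) for row in objs]
    front = pareto_front(cands)
    # independently written all-pairs dominance check
    def dominated(i):
        for j in range(20):
            if j != i and all(objs[j] <= objs[i]) and any(objs[j] < objs[i]):
                return True
        return False
    want = [cands[i] for i in range(20) if not dominated(i)]
    assert front == want
    # mutual non-domination on the front itself
    fo = np.stack([c.objectives.as_array() for c in front])
    for i in range(len(front)):
        for j in range(len(front)):
            if i != j:
                assert not (np.all(fo[j] <= fo[i]) and np.any(fo[j] < fo[i]))


def test_select_knee_point_hand_case():
    cands = [_cand(0, 1, 0), _cand(1, 0, 0), _cand(0.4, 0.4, 0)]
    front = pareto_front(cands)
    best = select_solution(front)
    assert best.objectives.f1_recon == pytest.approx(0.4)
    assert best.selected and best.on_front
    assert sum(c.selected for c in cands) == 1


def test_select_matches_normalize_argmin_oracle(rng):
    objs = rng.uniform(0, 1, size=(10, 3))
    cands = [_cand(*row) for row in objs]
    best = select_solution(cands)
    lo, hi = objs.min(0), objs.max(0)
    normed = (objs - lo) / np.where(hi - lo > 0, hi - lo, 1.0)
    normed[:, hi - lo == 0] = 0.0
    want = int(np.argmin(np.sqrt((normed**2).sum(1))))
    assert best is cands[want]


def test_sparsity_penalty_promotes_sparsity():
    """hoyer_sparsity(H) non-decreasing in lambda on a seeded panel (<=5% slack)."""
    violations = 0
    total = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        V = r.uniform(0.0, 1.0, size=(12, 15))
        prev = None
        for lam in (0.0, 0.05, 0.2, 1.0):
            s = hoyer_sparsity(
                nmf_factorize(V, k=3, lambda_sparsity=lam, max_iter=300, seed=seed).H
            )
            if prev is not None:
                total += 1
                if s < prev - 1e-9:
                    violations += 1
            prev = s
    assert violations <= 0.05 * total


def test_clean_spectrogram_rank1_input():
    cfg = StftConfig(window_length=64, hop_length=16)
    rng = np.random.default_rng(3)
    mag = np.outer(rng.uniform(0.5, 1.0, cfg.n_bins), rng.uniform(0.5, 1.0, 40))
    phase = rng.uniform(-np.pi, np.pi, mag.shape)
    from voicegate import Spectrogram

    s_mod = Spectrogram(mag * np.exp(1j * phase), cfg, 8000, "modified")
    s_clean, best, cands = clean_spectrogram(
        s_mod, k_grid=(1, 2), lambda_grid=(0.0,), max_iter=800, tol=0.0, seed=0
    )
    assert best.objectives.f1_recon < 1e-4
    rel = np.linalg.norm(np.abs(s_clean.values) - mag) / np.linalg.norm(mag)
    assert rel < 1e-3
    # phase reuse
    np.testing.assert_allclose(
        np.angle(s_clean.values), np.angle(s_mod.values), atol=1e-6
    )


def test_clean_spectrogram_capacity_monotone():
    """Best-front reconstruction error does not increase as max rank grows."""
    pair = generate(SynthSpec(duration=0.6, sample_rate=8000, seed=4))
    cfg = StftConfig(window_length=256, hop_length=64)
    s = stft(pair.degraded, cfg)
    errs = []
    for kmax in (2, 4, 8):
        _, _, cands = clean_spectrogram(
            s, k_grid=tuple(range(1, kmax + 1)), lambda_grid=(0.0,),
            max_iter=120, seed=11,
        )
        errs.append(min(c.objectives.f1_recon for c in cands if c.on_front))
    assert errs[0] >= errs[1] >= errs[2]


def test_all_zero_spectrogram_short_circuits(caplog):
    cfg = StftConfig(window_length=32, hop_length=8)
    from voicegate import Spectrogram

    s = Spectrogram(np.zeros((cfg.n_bins, 10), dtype=complex), cfg, 8000, "modified")
    with caplog.at_level("WARNING"):
        s_clean, best, cands = clean_spectrogram(s)
    np.testing.assert_array_equal(s_clean.values, s.values)
    assert best.selected
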