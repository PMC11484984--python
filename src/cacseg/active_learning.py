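"""Active learning for weak coronary-region annotation.

Region annotation is the expensive part of building a segment-level calcium
scoring dataset, so the slices to annotate are chosen actively: Monte-Carlo
dropout ranks unlabeled slices by predictive uncertainty separately for the
main (calcium) and auxiliary (region) task, and a greedy batch is built from
the auxiliary candidates by maximizing the Fisher information correlation

    rho_F(X_M, X_B) = i_C / sqrt(i_F(main) * i_F(aux))

where the Fisher scores are per-slice gradients of the pseudo-label
log-likelihood at a designated parameter block theta_k (the bottleneck
convolution by default), i_F is the mean squared score norm of a sample set,
and i_C the average scalar product between main-task scores of X_M and
aux-task scores of X_B. By Cauchy-Schwarz |rho_F| <= 1. Samples are added one
at a time, each chosen to maximize rho_F(X_M, X_B ∪ {x}) — samples whose
region-task information aligns with where the calcium task is struggling.

The loop runs a fixed number of rounds (ten by default), fine-tuning between
rounds (with a fresh optimizer each time), reveals ground-truth region labels
for the selected slices in place of an annotator, and finally retrains from
scratch on all revealed labels to avoid warm-start overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .multitask import MultiTaskModel, MultiTaskConfig, SliceSample
from . import _nn

__all__ = [
    "ALState",
    "mc_dropout_uncertainty",
    "select_uncertain_subsets",
    "fisher_information_correlation",
    "select_batch",
    "run_al_loop",
]


@dataclass
class ALState:
    """Bookkeeping of one active-learning run (indices into the slice pool)."""

    X_U: list[int]
    X_L: list[int]
    X_M: list[int] = field(default_factory=list)
    X_A: list[int] = field(default_factory=list)
    X_B: list[int] = field(default_factory=list)
    round_index: int = 0
    history: list[dict] = field(default_factory=list)

    def check(self) -> None:
        if set(self.X_L) & set(self.X_U):
            raise AssertionError("labeled and unlabeled pools overlap")
        if not set(self.X_M) <= set(self.X_U) or not set(self.X_A) <= set(self.X_U):
            raise AssertionError("uncertain subsets must come from the unlabeled pool")
        if not set(self.X_B) <= set(self.X_A):
            raise AssertionError("selection batch must come from X_A")


def mc_dropout_uncertainty(
    model: MultiTaskModel,
    sample: SliceSample,
    task: str,
    T: int = 10,
    seed: int = 0,
) -> float:
    """Predictive entropy of the T-pass Monte-Carlo-dropout mean distribution.

    For the main task the entropy is averaged over candidate-mask pixels (the
    only pixels that can be calcium; 0.0 if the slice has no candidates), for
    the auxiliary task over the whole slice.
    """
    if T < 2:
        raise ValueError("Monte Carlo dropout needs at least 2 passes")
    if task not in ("main", "aux"):
        raise ValueError("task must be 'main' or 'aux'")
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(T):
        lm, la = model.net.forward(sample.channels[None],
                                   np.array([sample.z_frac]),
                                   train=False, dropout_rng=rng)
        p = _nn.softmax(lm if task == "main" else la, axis=1)[0]
        acc = p if acc is None else acc + p
    p = acc / T
    ent = -(p * np.log(np.clip(p, 1e-12, None))).sum(axis=0)  # (H, W)
    if task == "main":
        cand = sample.channels[5] > 0.5
        return float(ent[cand].mean()) if cand.any() else 0.0
    return float(ent.mean())


def select_uncertain_subsets(
    model: MultiTaskModel,
    pool: list[SliceSample],
    X_U: list[int],
    k_M: int,
    k_A: int,
    T: int = 10,
    seed: int = 0,
) -> tuple[list[int], list[int]]:
    """Top-k most uncertain unlabeled slices per task (ties by pool order)."""
    if not X_U:
        raise ValueError("unlabeled pool is empty")
    if max(k_M, k_A) > len(X_U):
        raise ValueError("requested subsets larger than the unlabeled pool")
    out = []
    for task, k in (("main", k_M), ("aux", k_A)):
        u = np.array([
            mc_dropout_uncertainty(model, pool[i], task, T=T, seed=seed + 31 * i)
            for i in X_U
        ])
        order = np.lexsort((np.arange(len(X_U)), -u))  # stable: ties keep order
        out.append([X_U[j] for j in order[:k]])
    return out[0], out[1]


def fisher_information_correlation(
    scores_main: np.ndarray, scores_aux: np.ndarray
) -> float:
    """rho_F between two Fisher-score sets (rows are per-sample score vectors).

    i_C is the average scalar product over all (main, aux) sample pairs; the
    normalizer is the square root of the product of the mean squared score
    norms, so |rho_F| <= 1 by Cauchy-Schwarz.
    """
    M = np.atleast_2d(np.asarray(scores_main, dtype=np.float64))
    A = np.atleast_2d(np.asarray(scores_aux, dtype=np.float64))
    if M.size == 0 or A.size == 0:
        raise ValueError("empty Fisher score set")
    i_f_main = float((M ** 2).sum(axis=1).mean())
    i_f_aux = float((A ** 2).sum(axis=1).mean())
    if i_f_main <= 0 or i_f_aux <= 0:
        raise ValueError("zero Fisher information: degenerate model")
    i_c = float(M.mean(axis=0) @ A.mean(axis=0))
    return i_c / np.sqrt(i_f_main * i_f_aux)


def select_batch(
    scores_main: np.ndarray,
    scores_aux: np.ndarray,
    candidates: list[int],
    batch_size: int,
) -> list[int]:
    """Greedy Fisher-correlation batch selection.

    ``scores_aux`` rows correspond to ``candidates``. Starting from an empty
    batch, repeatedly add the candidate x maximizing
    rho_F(X_M, X_B ∪ {x}); deterministic (ties keep candidate order).
    Returns the selected candidate ids in selection order.
    """
    if batch_size > len(candidates):
        raise ValueError("batch size exceeds the candidate pool")
    scores_aux = np.atleast_2d(np.asarray(scores_aux, dtype=np.float64))
    selected: list[int] = []
    chosen_rows: list[int] = []
    remaining = list(range(len(candidates)))
    for _ in range(batch_size):
        best_j, best_rho = None, -np.inf
        for j in remaining:
            rho = fisher_information_correlation(
                scores_main, scores_aux[chosen_rows + [j]])
            if rho > best_rho:
                best_j, best_rho = j, rho
        chosen_rows.append(best_j)
        remaining.remove(best_j)
        selected.append(candidates[best_j])
    return selected


def run_al_loop(
    pool: list[SliceSample],
    config: MultiTaskConfig | None = None,
    initial_labeled: int = 10,
    n_rounds: int = 10,
    budget: int = 5,
    k_uncertain: int = 15,
    T: int = 5,
    epochs_per_round: int = 2,
    final_epochs: int | None = None,
    seed: int = 0,
) -> tuple[MultiTaskModel, ALState]:
    """Full active-learning loop over a slice pool with hidden region labels.

    The pool must carry ground-truth ``aux_target`` for every slice (the
    simulated annotator reveals it on selection); ``has_region`` flags are
    managed by the loop. After the last round the model is retrained from a
    fresh initialization on all revealed labels.
    """
    cfg = config or MultiTaskConfig(seed=seed)
    if initial_labeled + n_rounds * budget > len(pool):
        raise ValueError("annotation budget exhausts the slice pool")
    rng = np.random.default_rng(seed)
    pool = [replace(s, has_region=False) for s in pool]

    init = sorted(rng.choice(len(pool), size=initial_labeled, replace=False).tolist())
    for i in init:
        pool[i].has_region = True
    state = ALState(X_U=[i for i in range(len(pool)) if i not in set(init)],
                    X_L=list(init))

    model = MultiTaskModel(cfg)
    model.fit(pool, epochs=epochs_per_round, fit_zero_cac=False)

    for rnd in range(1, n_rounds + 1):
        k = min(k_uncertain, len(state.X_U))
        X_M, X_A = select_uncertain_subsets(
            model, pool, state.X_U, k_M=k, k_A=k, T=T, seed=seed + 1000 * rnd)
        s_main = np.stack([model.fisher_score(pool[i].channels, pool[i].z_frac,
                                              "main") for i in X_M])
        s_aux = np.stack([model.fisher_score(pool[i].channels, pool[i].z_frac,
                                             "aux") for i in X_A])
        X_B = select_batch(s_main, s_aux, X_A, min(budget, len(X_A)))
        for i in X_B:  # simulated annotator: reveal ground-truth region labels
            pool[i].has_region = True
        state.X_M, state.X_A, state.X_B = X_M, X_A, X_B
        state.check()  # subsets are relative to the pre-reveal pools
        state.X_L = sorted(state.X_L + X_B)
        state.X_U = [i for i in state.X_U if i not in set(X_B)]
        state.round_index = rnd
        state.history.append({
            "round": rnd,
            "selected": list(X_B),
            "n_labeled": len(state.X_L),
            "rho_F": fisher_information_correlation(s_main, s_aux),
        })
        model.fit(pool, epochs=epochs_per_round, fit_zero_cac=False)

    # retrain from scratch on all revealed labels (avoid warm-start overfit)
    model = MultiTaskModel(cfg)
    model.fit(pool, epochs=final_epochs if final_epochs is not None
              else cfg.epochs)
    return model, state
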