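"""Pair-similarity sequence embedding and its iterative optimization.

A peptide window P is compared against the reference set of N positive
windows K_1..K_N through a substitution matrix M and per-position
weights W_j. Two views of the same comparison are used:

* the scalar average similarity
      S = (1/N) * sum_j ( sum_i M[P_j, K_ij] ) * W_j
* the 300-dimensional pair-similarity vector V_P with one entry per
  unordered character pair {a, b},
      S_ab = (1/N) * sum_j C_j(a, b) * M[a, b] * W_j
  where C_j(a, b) counts reference windows whose character at position j
  forms the pair {a, b} with P_j.

Since the pairs partition all (P_j, K_ij) character co-occurrences,
sum(V_P) == S exactly; this identity is a key internal consistency
check. W and M are tuned by greedy coordinate ascent (position-weight
determination and scoring-matrix optimization), scoring every candidate
step by the cross-validated AUC of an L2-penalized logistic regression
on the embedded vectors, with the inverse regularization strength C
raised by 0.1 after each full round.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler

from .alphabet import (
    ALPHABET,
    ALPHABET_SIZE,
    N_PAIRS,
    PAIR_INDEX,
    blosum62,
    encode_peptide,
)

__all__ = [
    "ScoringModel",
    "OptimizeConfig",
    "average_similarity",
    "embed",
    "embed_dataset",
    "fit_plr",
    "optimize_embedding",
    "save_scoring_model",
    "load_scoring_model",
]


@dataclass
class ScoringModel:
    """Position weights, substitution matrix, and the reference positives."""

    positives: list[str]
    weights: np.ndarray | None = None  # (L,), non-negative, initially all 1
    matrix: np.ndarray | None = None  # (24, 24) symmetric, initially BLOSUM62
    plr_c: float = 1.0
    window: int = 61

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.ones(self.window, dtype=float)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
        if self.matrix is None:
            self.matrix = blosum62()
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
        self.window = int(len(self.weights))
        if self.matrix.shape != (ALPHABET_SIZE, ALPHABET_SIZE):
            raise ValueError(f"matrix must be {ALPHABET_SIZE}x{ALPHABET_SIZE}")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        if len(self.positives) < 1:
            raise ValueError("reference positive set is empty")
        if self.plr_c <= 0:
            raise ValueError("plr_c must be positive")
        for pep in self.positives:
            if len(pep) != self.window:
                raise ValueError(
                    f"reference peptide length {len(pep)} != window {self.window}"
                )
        self._encoded = np.stack([encode_peptide(p) for p in self.positives])
        # counts[j, c]: how many reference positives carry character c at position j
        L = self.window
        counts = np.zeros((L, ALPHABET_SIZE), dtype=float)
        for j in range(L):
            counts[j] = np.bincount(self._encoded[:, j], minlength=ALPHABET_SIZE)
        self._counts = counts
        self._index = {}
        for i, pep in enumerate(self.positives):
            self._index.setdefault(pep, i)

    @property
    def n_reference(self) -> int:
        return len(self.positives)


def _check_window(peptide: str, model: ScoringModel) -> np.ndarray:
    if len(peptide) != model.window:
        raise ValueError(
            f"peptide length {len(peptide)} != model window {model.window}"
        )
    return encode_peptide(peptide)


def average_similarity(peptide: str, model: ScoringModel) -> float:
    """Average similarity S of a peptide against the reference positives."""
    enc = _check_window(peptide, model)
    per_pos = np.einsum("jc,jc->j", model._counts, model.matrix[enc, :])
    return float(per_pos @ model.weights / model.n_reference)


def _embed_encoded(
    enc: np.ndarray, model: ScoringModel, counts: np.ndarray, n_ref: int
) -> np.ndarray:
    # vals[j, c] = counts[j, c] * M[P_j, c] * W_j ; scatter into pair features
    vals = counts * model.matrix[enc, :] * model.weights[:, None]
    feats = PAIR_INDEX[enc, :]  # (L, 24) feature index of {P_j, c}
    return np.bincount(feats.ravel(), weights=vals.ravel(), minlength=N_PAIRS) / n_ref


def embed(peptide: str, model: ScoringModel) -> np.ndarray:
    """Embed one peptide into the 300-dimensional pair-similarity vector."""
    enc = _check_window(peptide, model)
    return _embed_encoded(enc, model, model._counts, model.n_reference)


def embed_dataset(
    peptides: Sequence[str], model: ScoringModel, leave_self_out: bool = True
) -> np.ndarray:
    """Embed many peptides; rows align with the input order.

    With ``leave_self_out`` (the default), a peptide that is itself a
    member of the reference positive set is scored against the other
    N - 1 positives, avoiding self-match inflation of its own features.
    """
    out = np.empty((len(peptides), N_PAIRS), dtype=float)
    n = model.n_reference
    for r, pep in enumerate(peptides):
        enc = _check_window(pep, model)
        if leave_self_out and pep in model._index and n > 1:
            counts = model._counts.copy()
            counts[np.arange(model.window), enc] -= 1.0
            out[r] = _embed_encoded(enc, model, counts, n - 1)
        else:
            out[r] = _embed_encoded(enc, model, model._counts, n)
    return out


@dataclass
class PLRFit:
    """A fitted ridge logistic scorer with its cross-validated AUC."""

    pipeline: Pipeline
    cv_auc: float
    fold_aucs: list[float]

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(X)


def _plr(C: float, seed: int) -> Pipeline:
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(C=C, max_iter=2000, random_state=seed),  # L2 ridge penalty
    )


def fit_plr(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    seed: int = 0,
    folds: int = 10,
) -> PLRFit:
    """Fit L2 logistic regression and report seeded stratified CV AUC.

    The headline AUC pools all held-out decision values across folds;
    per-fold AUCs are also returned. Raises on single-class input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("fit_plr requires both classes present")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(y), dtype=float)
    fold_aucs: list[float] = []
    for train, test in skf.split(X, y):
        est = _plr(C, seed).fit(X[train], y[train])
        d = est.decision_function(X[test])
        pooled[test] = d
        if np.unique(y[test]).size == 2:
            fold_aucs.append(float(roc_auc_score(y[test], d)))
    final = _plr(C, seed).fit(X, y)
    return PLRFit(final, float(roc_auc_score(y, pooled)), fold_aucs)


def fold_aware_cv_auc(
    peptides: Sequence[str],
    labels: Sequence[int],
    C: float = 1.0,
    seed: int = 0,
    folds: int = 10,
) -> float:
    """Pooled CV AUC with the reference positive set rebuilt per fold.

    Embedding features are defined relative to the positive reference
    set; when that set is fixed across folds, held-out positives share
    its sampling fluctuations and a classifier can exploit them even in
    the absence of real signal. Here each fold embeds both partitions
    against the training-fold positives only, giving an unbiased
    estimate (and ~0.5 on label-free data).
    """
    labels = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pooled = np.empty(len(labels), dtype=float)
    for train, test in skf.split(np.zeros(len(labels)), labels):
        ref = [peptides[i] for i in train if labels[i] == 1]
        model = ScoringModel(positives=ref)
        Xtr = embed_dataset([peptides[i] for i in train], model, leave_self_out=True)
        Xte = embed_dataset([peptides[i] for i in test], model, leave_self_out=False)
        est = _plr(C, seed).fit(Xtr, labels[train])
        pooled[test] = est.decision_function(Xte)
    return float(roc_auc_score(labels, pooled))


@dataclass
class OptimizeConfig:
    """Settings for the greedy PWD/SMO embedding optimization."""

    w_step: float = 0.1
    m_step: float = 1.0
    folds: int = 10
    seed: int = 0
    max_rounds: int = 50
    tol: float = 1e-6  # AUC ties below this count as no improvement
    c_init: float = 1.0
    c_increment: float = 0.1
    positions: Sequence[int] | None = None  # restrict PWD sweep (testing/scale)
    pairs: Sequence[tuple[str, str]] | None = None  # restrict SMO sweep
    leave_self_out: bool = True


@dataclass
class OptimizeResult:
    model: ScoringModel
    auc_trace: list[float] = field(default_factory=list)
    rounds: int = 0

    @property
    def initial_auc(self) -> float:
        return self.auc_trace[0]

    @property
    def final_auc(self) -> float:
        return self.auc_trace[-1]


def _cv_auc(
    peptides: Sequence[str],
    labels: np.ndarray,
    model: ScoringModel,
    cfg: OptimizeConfig,
) -> float:
    X = embed_dataset(peptides, model, leave_self_out=cfg.leave_self_out)
    return fit_plr(X, labels, C=model.plr_c, seed=cfg.seed, folds=cfg.folds).cv_auc


def optimize_embedding(
    peptides: Sequence[str],
    labels: Sequence[int],
    init: ScoringModel,
    cfg: OptimizeConfig | None = None,
) -> OptimizeResult:
    """Alternate PWD and SMO greedy sweeps to maximize CV AUC.

    Each sweep perturbs one coordinate at a time (W_j by +/- w_step with
    a floor at 0; symmetric matrix entries by +/- m_step), keeping the
    first perturbation that raises the seeded CV AUC by more than tol.
    After each PWD+SMO round, C is raised by 0.1. Terminates when a full
    round yields no accepted step, or at max_rounds. The AUC trace over
    accepted states is non-decreasing by construction, and fold splits
    are fixed by the seed so comparisons are paired.
    """
    cfg = cfg or OptimizeConfig()
    labels = np.asarray(labels, dtype=int)
    model = replace(init, weights=init.weights.copy(), matrix=init.matrix.copy(),
                    plr_c=cfg.c_init)
    best = _cv_auc(peptides, labels, model, cfg)
    trace = [best]
    positions = list(cfg.positions) if cfg.positions is not None else list(range(model.window))
    if cfg.pairs is not None:
        pair_ids = [(ALPHABET.index(a), ALPHABET.index(b)) for a, b in cfg.pairs]
    else:
        pair_ids = [(i, j) for i in range(ALPHABET_SIZE) for j in range(i, ALPHABET_SIZE)]

    rounds = 0
    for _ in range(cfg.max_rounds):
        improved = False
        # PWD: per-position weight perturbation
        for j in positions:
            for delta in (cfg.w_step, -cfg.w_step):
                w_new = max(0.0, model.weights[j] + delta)
                if w_new == model.weights[j]:
                    continue
                cand = replace(model, weights=model.weights.copy())
                cand.weights[j] = w_new
                auc = _cv_auc(peptides, labels, cand, cfg)
                if auc > best + cfg.tol:
                    model, best, improved = cand, auc, True
                    trace.append(best)
                    break
        # SMO: substitution-matrix entry perturbation (kept symmetric)
        for i, j in pair_ids:
            for delta in (cfg.m_step, -cfg.m_step):
                cand = replace(model, matrix=model.matrix.copy())
                cand.matrix[i, j] += delta
                cand.matrix[j, i] = cand.matrix[i, j]
                auc = _cv_auc(peptides, labels, cand, cfg)
                if auc > best + cfg.tol:
                    model, best, improved = cand, auc, True
                    trace.append(best)
                    break
        rounds += 1
        if not improved:
            break
        model = replace(model, plr_c=model.plr_c + cfg.c_increment)
    return OptimizeResult(model=model, auc_trace=trace, rounds=rounds)


def save_scoring_model(model: ScoringModel, path: str | Path) -> None:
    doc = {
        "alphabet": ALPHABET,
        "window": model.window,
        "weights": model.weights.tolist(),
        "matrix": model.matrix.tolist(),
        "plr_c": model.plr_c,
        "positives": model.positives,
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_scoring_model(path: str | Path) -> ScoringModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("alphabet") != ALPHABET:
        raise ValueError("scoring model uses an incompatible alphabet")
    return ScoringModel(
        positives=list(doc["positives"]),
        weights=np.asarray(doc["weights"], dtype=float),
        matrix=np.asarray(doc["matrix"], dtype=float),
        plr_c=float(doc["plr_c"]),
    )
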