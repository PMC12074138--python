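"""Online alternating-least-squares learner for streaming ECG features.

One round receives a labeled feature chunk X (d x n_t) and refines, by T
closed-form alternating updates, a projection W (d x r) to a latent space in
which samples cluster around per-individual prototypes.  The loss combines

* bidirectional regressions (weights alpha, beta): V ~ X^T W and X ~ G V^T,
  over both the current chunk and all past data;
* prototype learning (gamma, theta): prototypes R reproduce the pairwise
  same-individual matrix A through the Hadamard codes H, and representations V
  stay close to R;
* memory enhancement (eta): V stays consistent with the stored class means
  V_m through the membership matrix S;
* ridge regularization (delta) on W and G.

Past data never re-enter: their entire influence on W and G flows through the
cumulative sufficient statistics C1 = sum X X^T, C2 = sum X V, C3 = sum V^T V,
frozen at the end of each round.  Storage is O(d^2 + d r + r^2) regardless of
stream length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .codes import HadamardCodebook, assign_codes, build_hadamard, chunk_code_matrix
from .features import FeatureChunk
from .memory import MemoryBank, memory_matrix


@dataclass
class Hyperparams:
    """Trade-off weights and run controls.

    All weights default to 1 except delta = 0.01; latent dimension r = 128
    (tied to the 2^7 Hadamard order) and T = 6 alternating iterations per
    chunk.  Toggles switch whole modules off for ablation runs.
    """

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    theta: float = 1.0
    eta: float = 1.0
    delta: float = 0.01
    r: int = 128
    T: int = 6
    seed: int = 0
    bidirectional_regressions: bool = True
    prototype_learning: bool = True
    memory_enhancement: bool = True
    published_v_update: bool = False

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "theta", "eta", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.r < 1:
            raise ValueError("r must be >= 1")

    # Effective weights after applying the module toggles.
    @property
    def eff_alpha(self) -> float:
        return self.alpha if self.bidirectional_regressions else 0.0

    @property
    def eff_beta(self) -> float:
        return self.beta if self.bidirectional_regressions else 0.0

    @property
    def eff_gamma(self) -> float:
        return self.gamma if self.prototype_learning else 0.0

    @property
    def eff_theta(self) -> float:
        return self.theta if self.prototype_learning else 0.0

    @property
    def eff_eta(self) -> float:
        return self.eta if self.memory_enhancement else 0.0


@dataclass
class SufficientStats:
    """Cumulative cross-products of all absorbed rounds (frozen V's)."""

    C1: np.ndarray  # d x d, sum of X X^T
    C2: np.ndarray  # d x r, sum of X V
    C3: np.ndarray  # r x r, sum of V^T V
    rounds_absorbed: int = 0

    @classmethod
    def zeros(cls, d: int, r: int) -> "SufficientStats":
        return cls(C1=np.zeros((d, d)), C2=np.zeros((d, r)), C3=np.zeros((r, r)))

    def absorbed(self, X: np.ndarray, V: np.ndarray) -> "SufficientStats":
        """New stats with one round's (X, V) folded in (the streaming recurrences)."""
        return SufficientStats(
            C1=self.C1 + X @ X.T,
            C2=self.C2 + X @ V,
            C3=self.C3 + V.T @ V,
            rounds_absorbed=self.rounds_absorbed + 1,
        )


@dataclass
class ModelState:
    W: np.ndarray  # d x r projection
    G: np.ndarray  # d x r reconstruction
    stats: SufficientStats
    round: int = 0
    d: int = 0
    r: int = 0

    @classmethod
    def initial(cls, d: int, r: int) -> "ModelState":
        return cls(W=np.zeros((d, r)), G=np.zeros((d, r)), stats=SufficientStats.zeros(d, r), d=d, r=r)


@dataclass
class ChunkLatents:
    """Per-round working matrices (old-data matrices are never materialized)."""

    V: np.ndarray  # n_t x r latent representations
    R: np.ndarray  # n_t x r prototype rows
    H: np.ndarray  # n_t x r Hadamard rows
    A: np.ndarray  # n_t x n_t same-individual indicator
    S: np.ndarray  # c_old x n_t memory membership
    labels: list = field(default_factory=list)


def pairwise_label_matrix(labels) -> np.ndarray:
    """A[i, j] = 1 iff samples i and j share an individual; symmetric, unit diagonal."""
    labels = np.asarray(list(labels), dtype=object)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    return (labels[:, None] == labels[None, :]).astype(float)


def memory_similarity_matrix(labels, memory_ids) -> np.ndarray:
    """S[c, i] = 1 iff memory_ids[c] == labels[i]; columns of new individuals are zero."""
    memory_ids = list(memory_ids)
    if len(set(memory_ids)) != len(memory_ids):
        raise ValueError("memory_ids must be distinct")
    labels = list(labels)
    S = np.zeros((len(memory_ids), len(labels)))
    idx = {iid: c for c, iid in enumerate(memory_ids)}
    for i, lab in enumerate(labels):
        c = idx.get(lab)
        if c is not None:
            S[c, i] = 1.0
    return S


def _check_finite(name: str, M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError(f"non-finite values in {name}")
    return M


def _solve_spd(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve A X = B for symmetric positive-(semi)definite A via Cholesky.

    Falls back to a tiny diagonal jitter (1e-10 I), then to a generic solve,
    rather than ever forming an explicit inverse.
    """
    A = 0.5 * (A + A.T)
    try:
        c, low = scipy.linalg.cho_factor(A, check_finite=False)
        return scipy.linalg.cho_solve((c, low), B, check_finite=False)
    except scipy.linalg.LinAlgError:
        try:
            c, low = scipy.linalg.cho_factor(A + 1e-10 * np.eye(A.shape[0]), check_finite=False)
            return scipy.linalg.cho_solve((c, low), B, check_finite=False)
        except scipy.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"singular normal-equation bracket: {err}") from err


def update_W(stats_prev: SufficientStats, X_t, V_t, hyper: Hyperparams) -> np.ndarray:
    """Exact minimizer of the W sub-problem: W = (C1 + (delta/alpha) I)^-1 C2.

    C1, C2 are the cumulative statistics with the current chunk's contribution
    added from the latest V_t; past contributions stay frozen in stats_prev.
    """
    X_t = _check_finite("X_t", X_t)
    V_t = _check_finite("V_t", V_t)
    alpha = hyper.eff_alpha
    if alpha <= 0:
        raise ValueError("update_W requires alpha > 0 (bidirectional regressions enabled)")
    C1 = stats_prev.C1 + X_t @ X_t.T
    C2 = stats_prev.C2 + X_t @ V_t
    d = C1.shape[0]
    return _solve_spd(C1 + (hyper.delta / alpha) * np.eye(d), C2)


def update_G(stats_prev: SufficientStats, X_t, V_t, hyper: Hyperparams) -> np.ndarray:
    """Exact minimizer of the G sub-problem: G = C2 (C3 + (delta/beta) I)^-1."""
    X_t = _check_finite("X_t", X_t)
    V_t = _check_finite("V_t", V_t)
    beta = hyper.eff_beta
    if beta <= 0:
        raise ValueError("update_G requires beta > 0 (bidirectional regressions enabled)")
    C2 = stats_prev.C2 + X_t @ V_t
    C3 = stats_prev.C3 + V_t.T @ V_t
    r = C3.shape[0]
    return _solve_spd(C3 + (hyper.delta / beta) * np.eye(r), C2.T).T


def update_R(V_t, A_t, H_t, hyper: Hyperparams) -> np.ndarray:
    """Exact minimizer of the prototype sub-problem.

    R = (theta V + gamma A^T H)(theta I + gamma H^T H)^-1; with gamma = 0 this
    collapses to R = V.
    """
    V_t = _check_finite("V_t", V_t)
    A_t = _check_finite("A_t", A_t)
    H_t = _check_finite("H_t", H_t)
    theta, gamma = hyper.eff_theta, hyper.eff_gamma
    if theta + gamma <= 0:
        raise ValueError("update_R requires theta + gamma > 0")
    r = V_t.shape[1]
    bracket = theta * np.eye(r) + gamma * (H_t.T @ H_t)
    rhs = theta * V_t + gamma * (A_t.T @ H_t)
    if theta == 0:
        # no jitter here: a rank-deficient H^T H leaves the sub-problem
        # without a unique minimizer and must surface as an error
        try:
            c, low = scipy.linalg.cho_factor(0.5 * (bracket + bracket.T))
        except scipy.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "prototype bracket singular (theta = 0 with rank-deficient H^T H)"
            ) from err
        return scipy.linalg.cho_solve((c, low), rhs.T).T
    return _solve_spd(bracket, rhs.T).T


def update_V(X_t, W, G, R_t, S_t, V_mem, hyper: Hyperparams) -> np.ndarray:
    """Closed-form V update.

    Default mode solves the V sub-problem exactly:
        V ((alpha+theta) I + beta G^T G + eta V_m^T V_m)
            = alpha X^T W + beta X^T G + theta R + eta S^T V_m.
    ``published_v_update`` adds eta to the diagonal as in the published variant of the
    source formula; both modes coincide when the memory is empty (the eta term
    is skipped entirely at c_old = 0).
    """
    X_t = _check_finite("X_t", X_t)
    W = _check_finite("W", W)
    G = _check_finite("G", G)
    R_t = _check_finite("R_t", R_t)
    alpha, beta, theta, eta = hyper.eff_alpha, hyper.eff_beta, hyper.eff_theta, hyper.eff_eta
    r = W.shape[1]
    c_old = 0 if V_mem is None else np.asarray(V_mem).shape[0]
    use_eta = eta > 0 and c_old > 0

    num = np.zeros((X_t.shape[1], r))
    bracket = (alpha + theta) * np.eye(r)
    if alpha > 0:
        num += alpha * (X_t.T @ W)
    if beta > 0:
        num += beta * (X_t.T @ G)
        bracket += beta * (G.T @ G)
    if theta > 0:
        num += theta * R_t
    if use_eta:
        V_mem = _check_finite("V_mem", V_mem)
        S_t = _check_finite("S_t", S_t)
        num += eta * (S_t.T @ V_mem)
        bracket += eta * (V_mem.T @ V_mem)
        if hyper.published_v_update:
            bracket += eta * np.eye(r)
    return _solve_spd(bracket, num.T).T


def objective(
    X_t,
    W,
    G,
    latents: ChunkLatents,
    V_mem,
    hyper: Hyperparams,
    stats_prev: SufficientStats | None = None,
    include_past: bool = True,
    terms: bool = False,
):
    """Overall loss at the current iterate.

    Current-round part:
        alpha ||V - X^T W||^2 + beta ||X - G V^T||^2 + gamma ||A - H R^T||^2
        + theta ||R - V||^2 + eta ||S - V_m V^T||^2 + delta (||W||^2 + ||G||^2).

    With ``include_past`` the past-data regression residuals are added; they
    are exactly reconstructible from the frozen statistics:
        alpha: tr(C3) - 2 tr(W^T C2) + tr(W^T C1 W)
        beta : tr(C1) - 2 tr(G^T C2) + tr(G^T G C3).
    The eta term is skipped when the memory is empty.
    """
    X_t = np.asarray(X_t, dtype=float)
    V, R, H, A, S = latents.V, latents.R, latents.H, latents.A, latents.S
    alpha, beta, gamma, theta, eta = (
        hyper.eff_alpha, hyper.eff_beta, hyper.eff_gamma, hyper.eff_theta, hyper.eff_eta,
    )
    c_old = 0 if V_mem is None else np.asarray(V_mem).shape[0]

    out = {}
    out["alpha"] = alpha * np.sum((V - X_t.T @ W) ** 2) if alpha > 0 else 0.0
    out["beta"] = beta * np.sum((X_t - G @ V.T) ** 2) if beta > 0 else 0.0
    out["gamma"] = gamma * np.sum((A - H @ R.T) ** 2) if gamma > 0 else 0.0
    out["theta"] = theta * np.sum((R - V) ** 2) if theta > 0 else 0.0
    out["eta"] = (
        eta * np.sum((S - V_mem @ V.T) ** 2) if (eta > 0 and c_old > 0) else 0.0
    )
    out["delta"] = hyper.delta * (np.sum(W**2) + np.sum(G**2))
    if include_past and stats_prev is not None and stats_prev.rounds_absorbed > 0:
        C1, C2, C3 = stats_prev.C1, stats_prev.C2, stats_prev.C3
        if alpha > 0:
            out["alpha_past"] = alpha * (
                np.trace(C3) - 2 * np.sum(W * C2) + np.sum(W * (C1 @ W))
            )
        if beta > 0:
            out["beta_past"] = beta * (
                np.trace(C1) - 2 * np.sum(G * C2) + np.sum(G * (C3 @ G.T).T)
            )
    out["total"] = float(sum(out.values()))
    return out if terms else out["total"]


def train_chunk(
    state: ModelState,
    memory: MemoryBank,
    chunk: FeatureChunk,
    codebook: HadamardCodebook,
    hyper: Hyperparams,
    trace: list | None = None,
) -> tuple[ModelState, ChunkLatents]:
    """One round of online training (the four-step alternation).

    Builds A, H, S for the chunk, initializes V and R from seeded Gaussian
    noise (std 0.1), and runs T iterations of the W -> G -> R -> V closed-form
    updates.  Within the round, the chunk's contribution to C2/C3 is refreshed
    from the latest V at each update so every step is the exact minimizer of
    its sub-problem; C1's chunk part is fixed.  On exit the statistics are
    frozen with the converged V, W/G are refreshed from them, and the round
    counter advances.  Pass ``trace`` (a list) to collect per-step objective
    breakdowns.
    """
    X = np.asarray(chunk.X, dtype=float)
    d, n = X.shape
    if d != state.d:
        raise ValueError(f"chunk dimensionality {d} != model dimensionality {state.d}")
    labels = list(chunk.labels)
    r = hyper.r

    assign_codes(codebook, labels)
    A = pairwise_label_matrix(labels)
    H = chunk_code_matrix(codebook, labels, r=r)
    V_mem, memory_ids = memory_matrix(memory, r=r)
    if hyper.eff_eta > 0 and len(memory_ids) > 0:
        S = memory_similarity_matrix(labels, memory_ids)
    else:
        S = np.zeros((0, n))
        V_mem = np.zeros((0, r))

    rng = np.random.default_rng(np.uint32(hyper.seed) ^ np.uint32(state.round + 1))
    V = rng.normal(0.0, 0.1, size=(n, r))
    R = rng.normal(0.0, 0.1, size=(n, r))
    W = rng.normal(0.0, 0.1, size=(d, r))
    G = rng.normal(0.0, 0.1, size=(d, r))

    latents = ChunkLatents(V=V, R=R, H=H, A=A, S=S, labels=labels)

    def log(step: str, it: int):
        if trace is not None:
            entry = objective(X, W, G, latents, V_mem, hyper, state.stats, terms=True)
            entry.update(round=state.round + 1, iter=it, step=step)
            trace.append(entry)

    use_br = hyper.eff_alpha > 0 or hyper.eff_beta > 0
    use_pl = hyper.eff_gamma > 0 or hyper.eff_theta > 0
    for it in range(1, hyper.T + 1):
        if hyper.eff_alpha > 0:
            W = update_W(state.stats, X, latents.V, hyper)
            log("W", it)
        if hyper.eff_beta > 0:
            G = update_G(state.stats, X, latents.V, hyper)
            log("G", it)
        if use_pl:
            latents.R = update_R(latents.V, A, H, hyper)
            log("R", it)
        latents.V = update_V(X, W, G, latents.R, S, V_mem, hyper)
        log("V", it)

    stats = state.stats.absorbed(X, latents.V)
    if hyper.eff_alpha > 0:
        W = _solve_spd(stats.C1 + (hyper.delta / hyper.eff_alpha) * np.eye(d), stats.C2)
        log("W_final", hyper.T)
    elif not use_br:
        # Matching still needs a projection: fit the cumulative ridge map from
        # features to the frozen representations, outside the training loss.
        W = _solve_spd(stats.C1 + hyper.delta * np.eye(d), stats.C2)
    if hyper.eff_beta > 0:
        G = _solve_spd(stats.C3 + (hyper.delta / hyper.eff_beta) * np.eye(r), stats.C2.T).T
        log("G_final", hyper.T)

    new_state = ModelState(W=W, G=G, stats=stats, round=state.round + 1, d=d, r=r)
    return new_state, latents


def train_stream(
    chunks,
    hyper: Hyperparams,
    codebook: HadamardCodebook | None = None,
    trace: list | None = None,
    after_round=None,
):
    """Train over an ordered chunk sequence; returns (state, memory, codebook, per-round states).

    ``after_round(round_index, state, memory)`` is an optional callback (used
    e.g. for per-round evaluation curves).
    """
    from .memory import update_memory  # deferred to avoid import-cycle surprises

    if codebook is None:
        k = max(1, int(np.ceil(np.log2(max(hyper.r, 2)))))
        codebook = build_hadamard(k)
    state = None
    bank = MemoryBank()
    states = []
    for chunk in chunks:
        X = np.asarray(chunk.X, dtype=float)
        if state is None:
            state = ModelState.initial(X.shape[0], hyper.r)
        state, latents = train_chunk(state, bank, chunk, codebook, hyper, trace=trace)
        if hyper.memory_enhancement:
            bank = update_memory(bank, latents.V, chunk.labels)
        states.append(state)
        if after_round is not None:
            after_round(state.round, state, bank)
    return state, bank, codebook, states
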