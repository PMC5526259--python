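"""Bayesian epiallele inference at a single locus.

Model: each of the N observed reads y_i (binary over d CpGs, with missing
entries) is a noise-corrupted copy of one of Q latent binary epiallele
patterns x_q. Conditional on its generator w_i = q, each observed CpG call
independently disagrees with the pattern with probability epsilon (which
absorbs bisulfite-conversion failures, PCR and sequencing errors):

    p(y_i | x_q, eps) = prod_mu  eps^[y != x] (1 - eps)^[y == x]

with the product over observed positions only. Priors over X and w are
uniform, so MAP estimation is maximum likelihood:

  * w_i* = argmax_q p(y_i | x_q, eps)   — assign each read to the nearest
    pattern (fewest mismatches; ties broken by lowest pattern index);
  * x_qmu* = majority vote of the observed calls at site mu among reads
    attributed to q (exact ties, including no data, give 0);
  * eps* = alpha_0 / (alpha_0 + alpha_1), the overall mismatch fraction.

w is initialised by Ward-linkage hierarchical clustering of the reads
under a masked Hamming distance (for binary vectors the squared
Euclidean distance equals the Hamming count, so this is Ward clustering
of the reads themselves), then the w- and X-updates are alternated to
convergence (typically two or three iterations). The number of
epialleles Q is chosen by minimising AIC(Q) = -2 log-lik + 2 Q d,
counting the Qd pattern bits as free parameters. The log-likelihood here
is the joint density of the reads and their MAP attributions under the
uniform attribution prior, log p(Y, w | X, eps, Q) =
sum_i log p(y_i | x_{w_i}, eps) - N log Q. The -N log Q term matters:
without it a saturated model that gives every distinct corrupted read
pattern its own epiallele fits perfectly (eps -> 0) and beats any
parsimonious model whenever reads outnumber 2^d enough for duplicates,
which would select a dozen epialleles at an ordinary noisy locus.
Attribution uncertainty is captured by the responsibility matrix: the
leave-one-out marginal posterior of each w_i with all other parameters
held at their MAP values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .io import Locus


@dataclass(frozen=True)
class FitConfig:
    """Fitting knobs.

    q_max caps the AIC search (real loci rarely exceed ~13 epialleles);
    epsilon_floor keeps logarithms finite on perfect-fit loci;
    max_iterations bounds the coordinate updates (convergence is
    typically reached in two or three).
    """

    q_max: int = 20
    epsilon_floor: float = 1e-6
    max_iterations: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q_max < 1:
            raise ValueError("q_max must be >= 1")
        if not 0.0 < self.epsilon_floor < 0.5:
            raise ValueError("epsilon_floor must lie in (0, 1/2)")


@dataclass
class EpialleleModel:
    """A fitted epiallele model for one locus.

    X is the (Q, d) binary pattern matrix; w holds 0-based pattern
    indices, one per read; epsilon is the inferred noise probability.
    loglik is the joint log-density of the reads and their attributions,
    log p(Y, w | X, eps, Q), evaluated at max(epsilon, epsilon_floor);
    aic = -2 * loglik + 2 * Q * d.
    """

    Q: int
    X: np.ndarray
    w: np.ndarray
    epsilon: float
    loglik: float
    aic: float
    converged: bool = True
    loglik_path: list[float] = field(default_factory=list)
    aic_by_q: dict[int, float] = field(default_factory=dict)

    def pattern_strings(self) -> list[str]:
        return ["".join(str(int(b)) for b in row) for row in self.X]


@dataclass
class ResponsibilityMatrix:
    """(N, Q) matrix of p(w_i = q | everything else at MAP); rows sum to 1."""

    values: np.ndarray


# ---------------------------------------------------------------------------
# Elementary MAP updates


def emission_loglik(values: np.ndarray, mask: np.ndarray, pattern: np.ndarray,
                    epsilon: float) -> float:
    """Log-likelihood of one read under one pattern.

    Sums log(1 - epsilon) over observed matching sites and log(epsilon)
    over observed mismatching sites; masked positions contribute nothing
    (a fully masked read scores 0, the log of an empty product).
    """
    values = np.asarray(values)
    pattern = np.asarray(pattern)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != pattern.shape:
        raise ValueError("read and pattern lengths differ")
    mismatches = int(np.sum(mask & (values != pattern)))
    matches = int(mask.sum()) - mismatches
    if mismatches and epsilon <= 0.0:
        raise ValueError("epsilon must be positive when mismatches exist; "
                         "apply the epsilon floor first")
    out = matches * np.log1p(-epsilon)
    if mismatches:
        out += mismatches * np.log(epsilon)
    return float(out)


def _mismatch_matrix(values: np.ndarray, mask: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(N, Q) observed-mismatch counts between reads and patterns."""
    v1 = (values.astype(np.int64) * mask)          # observed & methylated
    v0 = ((1 - values).astype(np.int64) * mask)    # observed & unmethylated
    Xt = X.astype(np.int64).T
    return v1 @ (1 - Xt) + v0 @ Xt


def map_assign(values: np.ndarray, mask: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Attribute each read to its maximum-likelihood pattern.

    For epsilon < 1/2 the emission likelihood is monotone in the number
    of observed matches, so the argmax is the pattern with fewest
    mismatches; ties go to the lowest pattern index.
    """
    if X.shape[0] == 0:
        raise ValueError("pattern matrix is empty")
    return np.argmin(_mismatch_matrix(values, mask, X), axis=1)


def map_epialleles(values: np.ndarray, mask: np.ndarray, w: np.ndarray, Q: int,
                   prev_X: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote pattern update.

    For each pattern q and site mu, counts methylated (N_1) and
    unmethylated (N_0) observed calls among reads with w_i = q and sets
    the bit to 1 iff N_1 > N_0 (ties, including empty, give 0). Patterns
    with no attributed reads are left at their previous value and
    reported in the second return value.
    """
    d = values.shape[1]
    X = np.zeros((Q, d), dtype=np.uint8)
    empty = []
    v1 = values * mask
    v0 = (1 - values) * mask
    for q in range(Q):
        sel = w == q
        if not sel.any():
            empty.append(q)
            if prev_X is not None:
                X[q] = prev_X[q]
            continue
        n1 = v1[sel].sum(axis=0)
        n0 = v0[sel].sum(axis=0)
        X[q] = (n1 > n0).astype(np.uint8)
    return X, np.asarray(empty, dtype=np.intp)


def map_epsilon(values: np.ndarray, mask: np.ndarray, X: np.ndarray,
                w: np.ndarray) -> float:
    """Noise estimate: the fraction of observed calls that mismatch
    their attributed pattern, alpha_0 / (alpha_0 + alpha_1)."""
    total = int(mask.sum())
    if total == 0:
        raise ValueError("no observed entries at this locus")
    mismatches = int(np.sum(mask & (values != X[w])))
    return mismatches / total


def _profile_loglik(values: np.ndarray, mask: np.ndarray, X: np.ndarray,
                    w: np.ndarray, epsilon_floor: float) -> tuple[float, float]:
    """Log-likelihood at (X, w) with epsilon at its own MAP (floored)."""
    total = int(mask.sum())
    mismatches = int(np.sum(mask & (values != X[w])))
    eps = min(max(mismatches / total, epsilon_floor), 0.5)
    ll = (total - mismatches) * np.log1p(-eps) + mismatches * np.log(eps)
    return float(ll), mismatches / total


# ---------------------------------------------------------------------------
# Initialisation


def hamming_condensed(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Condensed pairwise masked-Hamming distances between reads.

    The distance is the proportion of mutually observed CpGs that
    differ; pairs with no shared observed position score 0.5 (maximal
    ignorance).
    """
    v1 = (values.astype(np.int64) * mask)
    v0 = ((1 - values).astype(np.int64) * mask)
    shared = mask.astype(np.int64) @ mask.astype(np.int64).T
    diff = v1 @ v0.T + v0 @ v1.T
    with np.errstate(invalid="ignore"):
        dist = np.where(shared > 0, diff / np.maximum(shared, 1), 0.5)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def read_linkage(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Ward-linkage dendrogram of the reads under masked Hamming distance.

    Distances enter as the square root of the Hamming proportion; for
    fully observed binary reads this is the Euclidean distance scaled by
    1/sqrt(d), making the linkage exactly Ward clustering of the read
    vectors. Ward separates clusters of near-identical patterns far more
    reliably than average linkage, which tends to merge pattern pairs one
    flip apart and strand the coordinate ascent in a local optimum.
    """
    return _scipy_linkage(np.sqrt(hamming_condensed(values, mask)), method="ward")


def init_assignment(values: np.ndarray, mask: np.ndarray, Q: int,
                    linkage: np.ndarray | None = None) -> np.ndarray:
    """Initial w: cut the read dendrogram into Q groups."""
    n = values.shape[0]
    if Q == 1 or n == 1:
        return np.zeros(n, dtype=np.intp)
    if linkage is None:
        linkage = read_linkage(values, mask)
    labels = fcluster(linkage, t=Q, criterion="maxclust")
    # relabel to 0..k-1 in order of first appearance for determinism
    _, first = np.unique(labels, return_index=True)
    order = {labels[i]: rank for rank, i in enumerate(sorted(first))}
    return np.asarray([order[l] for l in labels], dtype=np.intp)


# ---------------------------------------------------------------------------
# Fixed-Q fit and model selection


def _rescue_empty(values, mask, X, w, empty: np.ndarray,
                  epsilon_floor: float) -> tuple[np.ndarray, np.ndarray]:
    """Give each empty pattern the currently worst-fitting read.

    The read with the lowest best-emission log-likelihood under the
    current patterns and noise estimate is reassigned (ties broken by
    lowest read index); the caller then recomputes the patterns. A read
    is never taken from a cluster it is the sole member of.
    """
    if empty.size == 0:
        return X, w
    w = w.copy()
    mm = _mismatch_matrix(values, mask, X)
    total = max(int(mask.sum()), 1)
    eps = min(max(int(np.sum(mask & (values != X[w]))) / total, epsilon_floor), 0.5)
    obs = mask.sum(axis=1)
    best_ll = (obs - mm.min(axis=1)) * np.log1p(-eps) + mm.min(axis=1) * np.log(eps)
    taken: set[int] = set()
    for q in empty:
        for i in np.argsort(best_ll, kind="stable"):  # worst fit first
            if int(i) not in taken and np.sum(w == w[i]) > 1:
                w[int(i)] = q
                taken.add(int(i))
                break
    return X, w


def fit_fixed_q(locus: Locus, Q: int, config: FitConfig = FitConfig(),
                linkage: np.ndarray | None = None) -> EpialleleModel:
    """Fit the epiallele model with a fixed number of patterns Q.

    Alternates the majority-vote pattern update and the nearest-pattern
    attribution update from a hierarchical-clustering start until w is
    unchanged or ``max_iterations`` is reached; the joint likelihood is
    non-decreasing across iterations. Deterministic for a given input.
    """
    values, mask = locus.matrices()
    n = values.shape[0]
    if Q > n:
        raise ValueError(f"Q={Q} exceeds the number of reads N={n}")
    if Q > 2 ** locus.d:
        raise ValueError(f"Q={Q} exceeds the number of distinct patterns 2^d")

    w = init_assignment(values, mask, Q, linkage=linkage)
    X, _ = map_epialleles(values, mask, w, Q)
    log_prior_w = -n * np.log(Q)  # uniform attribution prior Q^-N
    path: list[float] = []
    converged = False
    for _ in range(config.max_iterations):
        X, _ = map_epialleles(values, mask, w, Q, prev_X=X)
        w_new = map_assign(values, mask, X)
        X, empty = map_epialleles(values, mask, w_new, Q, prev_X=X)
        if empty.size:
            X, w_new = _rescue_empty(values, mask, X, w_new, empty,
                                     config.epsilon_floor)
            X, _ = map_epialleles(values, mask, w_new, Q, prev_X=X)
        path.append(
            _profile_loglik(values, mask, X, w_new, config.epsilon_floor)[0]
            + log_prior_w
        )
        if np.array_equal(w_new, w):
            converged = True
            w = w_new
            break
        w = w_new

    cond_ll, eps_hat = _profile_loglik(values, mask, X, w, config.epsilon_floor)
    loglik = cond_ll + log_prior_w
    return EpialleleModel(
        Q=Q, X=X, w=w, epsilon=eps_hat, loglik=loglik,
        aic=aic(loglik, Q, locus.d), converged=converged, loglik_path=path,
    )


def aic(loglik: float, Q: int, d: int) -> float:
    """Akaike information criterion: -2 log-lik + 2 Q d."""
    return -2.0 * loglik + 2.0 * Q * d


def select_model(locus: Locus, config: FitConfig = FitConfig()) -> EpialleleModel:
    """Fit Q = 1 .. min(q_max, N, 2^d) and return the minimum-AIC model.

    Ties favour the smaller Q. The clustering dendrogram is computed
    once and re-cut for every Q.
    """
    values, mask = locus.matrices()
    n = values.shape[0]
    q_hi = min(config.q_max, n, 2 ** min(locus.d, 60))
    link = read_linkage(values, mask) if n > 1 else None
    best: EpialleleModel | None = None
    aic_by_q: dict[int, float] = {}
    for Q in range(1, q_hi + 1):
        model = fit_fixed_q(locus, Q, config, linkage=link)
        aic_by_q[Q] = model.aic
        if best is None or model.aic < best.aic:
            best = model
    assert best is not None
    best.aic_by_q = aic_by_q
    return best


# ---------------------------------------------------------------------------
# Marginalisation of w


def responsibilities(locus: Locus, model: EpialleleModel,
                     config: FitConfig = FitConfig()) -> ResponsibilityMatrix:
    """Leave-one-out marginal posterior of each read's attribution.

    With X and epsilon fixed at MAP and a uniform prior over patterns,
    row i is proportional to p(y_i | x_q, epsilon) over q, normalised to
    sum to one. Epsilon is floored so rows are defined on perfect-fit
    loci (where they harden toward one-hot vectors agreeing with w).
    """
    values, mask = locus.matrices()
    eps = min(max(model.epsilon, config.epsilon_floor), 0.5)
    mm = _mismatch_matrix(values, mask, model.X)
    obs = mask.sum(axis=1, keepdims=True)
    logp = (obs - mm) * np.log1p(-eps) + mm * np.log(eps)
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    p /= p.sum(axis=1, keepdims=True)
    return ResponsibilityMatrix(values=p)
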