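"""Group-level spatial ICA with stability analysis and back-reconstruction.

The decomposition follows the standard temporal-concatenation group ICA
recipe: each subject's (T x V) series is reduced by PCA to the smallest
dimension explaining at least 95% of its variance (capped), the reduced data
are stacked over subjects and reduced again to exactly ``n_components``
directions, and natural-gradient Infomax ICA unmixes the group matrix into
spatially independent maps.  Stability is assessed ICASSO-style: the
decomposition is re-run from random initializations, components are clustered
across runs by absolute spatial correlation, and each cluster receives a
quality index Iq (mean intra-cluster minus mean extra-cluster similarity);
the cluster centrotypes are the consensus group maps.  Subject-level maps and
time courses are recovered from the group maps by dual regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.extmath import randomized_svd

__all__ = [
    "PCAReduction",
    "ICASSOReport",
    "SubjectComponents",
    "two_stage_pca",
    "infomax_ica",
    "icasso_stability",
    "back_reconstruct",
    "select_components",
    "flag_noise_components",
    "amari_index",
    "GroupICA",
]


@dataclass
class PCAReduction:
    subject_dims: list                  # retained dimension per subject
    subject_bases: list                 # (T, k_i) left singular vectors
    subject_variance_retained: list     # fraction of variance kept
    group_basis: np.ndarray             # (sum k_i, n_group) directions
    group_singular_values: np.ndarray
    n_group_components: int
    variance_threshold: float


@dataclass
class ICASSOReport:
    n_runs: int
    cluster_assignments: np.ndarray     # (n_runs * K,) cluster id per run-component
    iq: np.ndarray                      # (K,) quality index per cluster
    centrotype_index: np.ndarray        # flat index of each cluster's centrotype
    similarity: np.ndarray              # (n_runs*K, n_runs*K) |corr| matrix
    intra_similarity: np.ndarray        # mean within-cluster similarity
    extra_similarity: np.ndarray        # mean similarity to other clusters
    degenerate: bool = False


@dataclass
class SubjectComponents:
    subject_maps: np.ndarray            # (K_kept, V)
    timecourses: np.ndarray             # (T, K_kept), zero mean per component
    kept_indices: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.kept_indices is None:
            self.kept_indices = np.arange(self.subject_maps.shape[0])


# ---------------------------------------------------------------------------
# PCA reduction

def two_stage_pca(subject_series, n_group_components=20,
                  variance_threshold=0.95, subject_max=30):
    """Two successive PCA reductions for temporal-concatenation group ICA.

    Stage 1 reduces each subject's centered (T x V) series along time to the
    smallest number of principal directions whose cumulative variance reaches
    ``variance_threshold`` (capped at ``subject_max``).  Stage 2 stacks the
    reduced subject data and keeps exactly ``n_group_components`` directions.

    Returns
    -------
    reduction : PCAReduction
    group_matrix : (n_group_components, V) ndarray
        The reduced group data handed to ICA.
    """
    if len(subject_series) < 2:
        raise ValueError("need at least 2 subjects")
    V = subject_series[0].shape[1]
    dims, bases, retained, reduced = [], [], [], []
    for X in subject_series:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != V:
            raise ValueError("all subjects must share the voxel dimension")
        Xc = X - X.mean(axis=0, keepdims=True)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = s ** 2
        frac = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(frac, variance_threshold) + 1)
        k = min(k, subject_max, len(s))
        dims.append(k)
        bases.append(U[:, :k])
        retained.append(float(frac[k - 1]))
        reduced.append(s[:k, None] * Vt[:k])          # (k, V)

    Z = np.vstack(reduced)
    if n_group_components > min(Z.shape):
        raise ValueError(
            f"requested {n_group_components} group components but stacked "
            f"subject data has rank at most {min(Z.shape)}")
    U2, s2, Vt2 = randomized_svd(Z, n_components=n_group_components,
                                 n_oversamples=10, n_iter=7, random_state=0)
    if s2[-1] <= 1e-10 * max(s2[0], 1.0):
        raise ValueError("stacked subject data is rank deficient for the "
                         "requested group dimension")
    group_matrix = s2[:, None] * Vt2                  # (n_group, V)
    reduction = PCAReduction(
        subject_dims=dims, subject_bases=bases,
        subject_variance_retained=retained, group_basis=U2,
        group_singular_values=s2, n_group_components=n_group_components,
        variance_threshold=variance_threshold)
    return reduction, group_matrix


# ---------------------------------------------------------------------------
# Infomax ICA

def _whiten(X, n_components):
    """Center rows and sphere to identity covariance via eigen-decomposition."""
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    cov = Xc @ Xc.T / Xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-12 * max(evals[0], 1.0):
        raise ValueError("data rank below requested component count")
    K = (evecs / np.sqrt(evals)).T                    # (n_comp, n_ch)
    return K @ Xc, K, mean


def _random_orthogonal(n, rng):
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def infomax_ica(reduced_data, n_components=None, seed=0, learning_rate=3e-3,
                max_iter=500, tol=1e-7, block=128, anneal_deg=60.0,
                anneal_step=0.9):
    """Natural-gradient Infomax ICA with a logistic nonlinearity.

    The update for each data block U = W X + b is
    ``W += lr * (I + (1 - 2 g(U)) U^T / block) W`` with ``g`` the logistic
    sigmoid — the maximum-likelihood natural gradient for super-Gaussian
    sources.  The learning rate is annealed when successive weight updates
    oscillate (angle > ``anneal_deg``); convergence is declared when the
    per-pass weight change drops below ``tol``.

    Returns
    -------
    unmixing : (n_components, n_channels) ndarray
        Total unmixing (including whitening): sources = unmixing @ centered data.
    sources : (n_components, n_samples) ndarray
        Unit-variance sources, sign fixed so each row's largest-magnitude
        sample is positive.
    info : dict with keys ``converged``, ``n_iter``, ``final_change``.
    """
    X = np.asarray(reduced_data, dtype=float)
    n_ch, N = X.shape
    if n_components is None:
        n_components = n_ch
    Xw, K, _ = _whiten(X, n_components)
    rng = np.random.default_rng(seed)
    W = _random_orthogonal(n_components, rng)
    bias = np.zeros((n_components, 1))
    lr = float(learning_rate)
    block = int(min(block, N))
    I = np.eye(n_components)

    old_delta = None
    converged = False
    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        W_prev = W.copy()
        perm = rng.permutation(N)
        for t0 in range(0, N - block + 1, block):
            xb = Xw[:, perm[t0:t0 + block]]
            u = W @ xb + bias
            y = 1.0 / (1.0 + np.exp(-np.clip(u, -50, 50)))
            g = 1.0 - 2.0 * y
            W = W + lr * (I + (g @ u.T) / block) @ W
            bias = bias + lr * g.mean(axis=1, keepdims=True)
            if not np.isfinite(W).all() or np.abs(W).max() > 1e8:
                # blow-up: restart colder
                lr *= 0.5
                W = _random_orthogonal(n_components, rng)
                bias = np.zeros((n_components, 1))
                break
        delta = W - W_prev
        prev_change, change = change, float(np.linalg.norm(delta))
        if old_delta is not None:
            denom = change * np.linalg.norm(old_delta)
            if denom > 0:
                cosang = np.clip((delta * old_delta).sum() / denom, -1, 1)
                if np.degrees(np.arccos(cosang)) > anneal_deg:
                    lr *= anneal_step
            # stochastic plateau: once the update is small the solution is
            # locked in; decay the rate steadily so the tolerance is reached
            if change < 1e-3 or (change < 1e-2 and change >= prev_change):
                lr *= anneal_step
        old_delta = delta
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"Infomax did not converge in {max_iter} iterations "
                      f"(final weight change {change:.2e})", RuntimeWarning)

    sources = W @ Xw
    sd = sources.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    sources /= sd
    unmixing = (W / sd) @ K
    # sign convention: largest-|value| sample of each source positive
    signs = np.sign(sources[np.arange(n_components),
                            np.abs(sources).argmax(axis=1)])
    signs[signs == 0] = 1.0
    sources *= signs[:, None]
    unmixing *= signs[:, None]
    return unmixing, sources, {"converged": converged, "n_iter": it,
                               "final_change": change}


def amari_index(W, A):
    """Permutation/scale-invariant unmixing error in [0, 1]; 0 is perfect.

    For P = W A the index averages, over rows and columns of |P|, how far the
    mass is from being concentrated on a single entry.
    """
    P = np.abs(np.asarray(W) @ np.asarray(A))
    K = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * K * (K - 1)))


# ---------------------------------------------------------------------------
# ICASSO stability

def icasso_stability(reduced_data, n_components=None, n_runs=10, seed=0,
                     force_identical=False, **ica_kwargs):
    """Re-run Infomax from random initializations and cluster the components.

    Pairwise similarity between run components is the absolute Pearson
    correlation of their spatial maps; average-linkage agglomerative
    clustering partitions the ``n_runs * K`` maps into K clusters; each
    cluster's quality index is Iq = mean intra-cluster similarity - mean
    extra-cluster similarity, and its centrotype (the member with the highest
    total intra-cluster similarity) serves as the consensus map.

    ``force_identical`` reuses the same initialization seed for every run
    (a degenerate setting useful for validating that identical runs give
    Iq = 1 up to the cross-component similarity floor).

    Returns
    -------
    report : ICASSOReport
    consensus_maps : (K, V) ndarray, clusters ordered by descending Iq.
    """
    X = np.asarray(reduced_data, dtype=float)
    if n_components is None:
        n_components = X.shape[0]
    if n_runs < 2:
        raise ValueError("ICASSO needs at least 2 runs")
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_runs)]
    if force_identical:
        run_seeds = [run_seeds[0]] * n_runs

    all_sources = []
    for rs in run_seeds:
        _, S, _ = infomax_ica(X, n_components, seed=rs, **ica_kwargs)
        all_sources.append(S)
    M = np.vstack(all_sources)                         # (n_runs*K, V)
    sim = np.abs(np.corrcoef(M))
    np.clip(sim, 0.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)

    dist = 1.0 - sim
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Zl = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Zl, t=n_components, criterion="maxclust") - 1

    n_items = M.shape[0]
    iq = np.full(n_components, np.nan)
    intra = np.full(n_components, np.nan)
    extra = np.full(n_components, np.nan)
    centro = np.full(n_components, -1, dtype=int)
    degenerate = False
    for c in range(n_components):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            degenerate = True
            continue
        outside = np.flatnonzero(labels != c)
        block = sim[np.ix_(members, members)]
        if members.size > 1:
            intra_c = (block.sum() - members.size) / (members.size * (members.size - 1))
        else:
            intra_c = 1.0
        extra_c = sim[np.ix_(members, outside)].mean() if outside.size else 0.0
        intra[c], extra[c] = intra_c, extra_c
        iq[c] = intra_c - extra_c
        centro[c] = members[block.sum(axis=1).argmax()]
    if degenerate:
        warnings.warn("ICASSO clustering produced an empty cluster "
                      "(unstable decomposition)", RuntimeWarning)

    order = np.argsort(-np.where(np.isnan(iq), -np.inf, iq))
    valid = [c for c in order if centro[c] >= 0]
    consensus = M[[centro[c] for c in valid]]
    report = ICASSOReport(
        n_runs=n_runs, cluster_assignments=labels, iq=iq[order],
        centrotype_index=centro[order], similarity=sim,
        intra_similarity=intra[order], extra_similarity=extra[order],
        degenerate=degenerate)
    return report, consensus


# ---------------------------------------------------------------------------
# Back-reconstruction (dual regression) and component selection

def back_reconstruct(group_maps, subject_series):
    """Dual regression of one subject's series onto the group maps.

    Stage 1 regresses every time point's voxel vector on the group maps
    (with intercept) giving the subject time courses; stage 2 regresses every
    voxel's series on those time courses (with intercept) giving the subject
    maps.
    """
    G = np.asarray(group_maps, dtype=float)
    X = np.asarray(subject_series, dtype=float)
    K, V = G.shape
    if X.shape[1] != V:
        raise ValueError("voxel dimension mismatch with group maps")
    if np.linalg.matrix_rank(G) < K:
        raise ValueError("group maps are collinear (rank deficient)")
    D1 = np.column_stack([np.ones(V), G.T])            # (V, K+1)
    tc, *_ = np.linalg.lstsq(D1, X.T, rcond=None)      # (K+1, T)
    tc = tc[1:].T                                      # (T, K)
    tc = tc - tc.mean(axis=0, keepdims=True)
    D2 = np.column_stack([np.ones(X.shape[0]), tc])    # (T, K+1)
    beta, *_ = np.linalg.lstsq(D2, X, rcond=None)      # (K+1, V)
    maps = beta[1:]
    return SubjectComponents(subject_maps=maps, timecourses=tc,
                             kept_indices=np.arange(K))


def flag_noise_components(timecourses, tr, freq_cutoff=0.1, power_fraction=0.5):
    """Spectral heuristic: flag components dominated by high frequencies.

    A component is flagged as noise when the fraction of its time-course
    power above ``freq_cutoff`` (Hz) exceeds ``power_fraction``.
    """
    tc = np.asarray(timecourses, dtype=float)
    T = tc.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr)
    spec = np.abs(np.fft.rfft(tc - tc.mean(axis=0), axis=0)) ** 2
    total = spec.sum(axis=0)
    total[total == 0] = 1.0
    high = spec[freqs > freq_cutoff].sum(axis=0)
    return (high / total) > power_fraction


def select_components(components, keep_list=None, tr=None, heuristic=False,
                      freq_cutoff=0.1, power_fraction=0.5):
    """Restrict a SubjectComponents to a kept subset.

    Either an explicit ``keep_list`` of component indices (the default,
    mirroring a manual noise-component review) or, with ``heuristic=True``,
    an automatic spectral criterion dropping high-frequency components.
    """
    if keep_list is not None:
        keep = np.asarray(keep_list, dtype=int)
    elif heuristic:
        if tr is None:
            raise ValueError("heuristic selection needs the TR")
        noisy = flag_noise_components(components.timecourses, tr,
                                      freq_cutoff, power_fraction)
        keep = np.flatnonzero(~noisy)
    else:
        keep = np.arange(components.subject_maps.shape[0])
    if keep.size == 0:
        raise ValueError("component selection kept nothing")
    if keep.min() < 0 or keep.max() >= components.subject_maps.shape[0]:
        raise ValueError("keep_list index out of range")
    return SubjectComponents(
        subject_maps=components.subject_maps[keep],
        timecourses=components.timecourses[:, keep],
        kept_indices=components.kept_indices[keep])


# ---------------------------------------------------------------------------
# Estimator

class GroupICA(BaseEstimator, TransformerMixin):
    """Group spatial ICA estimator (fit on training subjects, transform any).

    ``fit`` runs the two-stage PCA reduction, an ICASSO-stabilized Infomax
    decomposition and stores the consensus group maps; ``transform`` dual-
    regresses each subject's series onto those fixed maps, so test subjects
    never influence the group model (the cross-validation contract).

    Parameters
    ----------
    n_components : int, default 20
        Group PCA / ICA dimension.
    variance_threshold : float, default 0.95
        Subject-stage retained-variance target.
    subject_pca_max : int, default 30
        Cap on the subject-stage dimension.
    icasso_runs : int, default 10
        Number of Infomax restarts clustered for stability; 1 disables
        ICASSO and uses a single run.
    keep_list : sequence of int or None
        Components retained after decomposition (noise removal); None keeps
        all.
    random_state : int or None
        Seed for ICA initializations.

    Attributes
    ----------
    group_maps_ : (K_kept, V) consensus spatial maps (unit variance rows)
    mixing_ : pseudo-inverse mixing of the reduced data
    icasso_ : ICASSOReport or None
    pca_ : PCAReduction
    """

    def __init__(self, n_components=20, variance_threshold=0.95,
                 subject_pca_max=30, icasso_runs=10, keep_list=None,
                 learning_rate=3e-3, max_iter=500, tol=1e-7,
                 random_state=None):
        self.n_components = n_components
        self.variance_threshold = variance_threshold
        self.subject_pca_max = subject_pca_max
        self.icasso_runs = icasso_runs
        self.keep_list = keep_list
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        seed = 0 if self.random_state is None else int(self.random_state)
        self.pca_, G = two_stage_pca(
            X, n_group_components=self.n_components,
            variance_threshold=self.variance_threshold,
            subject_max=self.subject_pca_max)
        ica_kwargs = dict(learning_rate=self.learning_rate,
                          max_iter=self.max_iter, tol=self.tol)
        if self.icasso_runs and self.icasso_runs > 1:
            self.icasso_, maps = icasso_stability(
                G, self.n_components, n_runs=self.icasso_runs, seed=seed,
                **ica_kwargs)
        else:
            self.icasso_ = None
            _, maps, self.convergence_info_ = infomax_ica(
                G, self.n_components, seed=seed, **ica_kwargs)
        if self.keep_list is not None:
            maps = maps[np.asarray(self.keep_list, dtype=int)]
        self.group_maps_ = maps
        self.mixing_ = np.linalg.pinv(maps @ np.linalg.pinv(G))
        self.n_features_in_ = X[0].shape[1]
        return self

    def transform(self, X):
        """Back-reconstruct each subject against the fitted group maps."""
        if not hasattr(self, "group_maps_"):
            raise RuntimeError("GroupICA is not fitted")
        return [back_reconstruct(self.group_maps_, s) for s in X]
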