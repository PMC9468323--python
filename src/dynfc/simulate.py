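"""Synthetic multi-subject BOLD-like cohorts with known ground truth.

The generator emulates the data model the pipeline assumes: K latent spatial
networks (Gaussian blobs on a voxel grid) mixed into voxel data by their
component time courses, whose pairwise covariance switches between discrete
hidden states over time (a Markov chain), plus additive Gaussian noise at a
configurable SNR.  A group effect is planted by shifting the correlation of
designated component pairs in designated states for one group, so every
downstream stage (ICA recovery, windowed connectivity, classification) can be
validated against known truth.

Realism is deliberately limited to second-order temporal statistics: no
hemodynamic convolution, scanner artifacts or motion are simulated, because
the pipeline only consumes windowed correlations of the component signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GroundTruthCohort",
    "make_spatial_maps",
    "make_state_covariances",
    "sample_state_sequence",
    "sample_balanced_state_sequence",
    "sample_component_timecourses",
    "mix_to_voxels",
    "make_cohort",
]


@dataclass
class GroundTruthCohort:
    """Everything needed to score the pipeline against the generating model.

    Attributes
    ----------
    spatial_maps : (K, V) ndarray
        Non-negative component loadings, each row peaking at a distinct site.
    voxel_series : list of (T, V) ndarray
        Per-subject noisy voxel data, ``timecourses @ spatial_maps + noise``.
    timecourses : list of (T, K) ndarray
        The generating component signals per subject.
    state_sequences : list of (T,) int ndarray
        Hidden state id active at each time point, per subject.
    state_covariances : dict group -> (n_states, K, K) ndarray
        Unit-diagonal positive-definite correlation matrices per state; groups
        differ only on ``effect_pairs`` in the affected states.
    group_labels : (n_subjects,) ndarray of str
    effect_pairs : list of (p, q) component index pairs carrying the effect
    delta : per-state correlation shifts applied to group "B"
    snr : signal-sd / noise-sd ratio
    seed : master seed
    """

    spatial_maps: np.ndarray
    voxel_series: list
    timecourses: list
    state_sequences: list
    state_covariances: dict
    group_labels: np.ndarray
    subject_ids: list
    effect_pairs: list
    delta: np.ndarray
    snr: float
    seed: int
    grid_shape: tuple = field(default=(15, 15, 10))


def make_spatial_maps(n_components, grid_shape, blob_sigma=1.5, seed=0,
                      max_pairwise_r=0.3, max_tries=200):
    """Place ``n_components`` Gaussian blobs at distinct grid sites.

    Each map is row-normalized to unit maximum and non-negative.  Centers are
    re-drawn (rejection sampling) until every pair of maps has spatial
    Pearson correlation below ``max_pairwise_r``.

    Parameters
    ----------
    grid_shape : tuple of int
        Voxel grid dimensions; flattened to V = prod(grid_shape) columns.
    blob_sigma : float
        Gaussian width in voxel units.

    Returns
    -------
    (n_components, V) ndarray
    """
    if n_components < 2:
        raise ValueError("need at least 2 components")
    grid_shape = tuple(int(g) for g in grid_shape)
    V = int(np.prod(grid_shape))
    if V < 4 * n_components:
        raise ValueError(
            f"grid volume {V} too small for {n_components} distinct blobs")
    rng = np.random.default_rng(seed)
    coords = np.stack(np.meshgrid(*[np.arange(g) for g in grid_shape],
                                  indexing="ij"), axis=-1).reshape(-1, len(grid_shape))
    for _ in range(max_tries):
        # best-candidate placement: grow the center set by always taking the
        # candidate farthest from the existing centers
        centers = [np.array([rng.uniform(0, g - 1) for g in grid_shape])]
        for _k in range(1, n_components):
            cand = np.stack([rng.uniform(0, g - 1, size=64)
                             for g in grid_shape], axis=1)
            dmin = np.min(np.linalg.norm(
                cand[:, None] - np.asarray(centers)[None], axis=-1), axis=1)
            centers.append(cand[dmin.argmax()])
        centers = np.asarray(centers)
        d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 2.0 * blob_sigma:
            continue
        sq = ((coords[None, :, :] - centers[:, None, :]) ** 2).sum(-1)
        maps = np.exp(-sq / (2.0 * blob_sigma ** 2))
        maps /= maps.max(axis=1, keepdims=True)
        r = np.corrcoef(maps)
        np.fill_diagonal(r, 0.0)
        if np.abs(r).max() < max_pairwise_r:
            return maps
    raise ValueError("could not place distinct blob centers; grid too small "
                     "for the requested component count / sigma")


def sample_state_sequence(n_states, T, mean_dwell, seed=0):
    """Markov chain over ``n_states`` with mean dwell time ``mean_dwell``.

    Stay probability is ``1 - 1/mean_dwell``; leaving transitions are uniform
    over the other states.  Initial state uniform.
    """
    if n_states < 1 or T < 1 or mean_dwell < 1:
        raise ValueError("n_states, T and mean_dwell must all be >= 1")
    rng = np.random.default_rng(seed)
    if n_states == 1:
        return np.zeros(T, dtype=np.int64)
    p_stay = 1.0 - 1.0 / mean_dwell
    seq = np.empty(T, dtype=np.int64)
    seq[0] = rng.integers(n_states)
    u = rng.random(T - 1)
    jumps = rng.integers(1, n_states, size=T - 1)
    for t in range(1, T):
        if u[t - 1] < p_stay:
            seq[t] = seq[t - 1]
        else:
            # uniform over the other states via a cyclic offset
            seq[t] = (seq[t - 1] + jumps[t - 1]) % n_states
    return seq


def sample_balanced_state_sequence(T, n_blocks_per_state=2, seed=0):
    """Two-state sequence with exactly T/2 time points per state.

    Each state's total time is split into ``n_blocks_per_state`` contiguous
    blocks with random boundaries, and blocks alternate between states from
    a random initial state.  Unlike the Markov chain, state occupancy carries
    no subject information, so whole-course statistics cannot proxy for the
    state-dependent structure — the construction used to isolate purely
    dynamic group effects.
    """
    if T < 4 * n_blocks_per_state:
        raise ValueError("T too short for the requested block count")
    rng = np.random.default_rng(seed)
    halves = []
    for _ in range(2):
        cuts = np.sort(rng.choice(np.arange(1, T // 2),
                                  n_blocks_per_state - 1, replace=False))
        halves.append(np.diff(np.r_[0, cuts, T // 2]))
    seq = []
    s = int(rng.integers(2))
    idx = [0, 0]
    for _ in range(2 * n_blocks_per_state):
        seq.extend([s] * int(halves[s][idx[s]]))
        idx[s] += 1
        s = 1 - s
    seq = np.asarray(seq[:T], dtype=np.int64)
    if len(seq) < T:   # odd T: pad with the final state
        seq = np.r_[seq, np.full(T - len(seq), seq[-1], dtype=np.int64)]
    return seq


def sample_component_timecourses(states, covariances, seed=0):
    """Draw a (T, K) signal: x_t ~ N(0, cov[state_t]).

    ``covariances`` is an (n_states, K, K) array (or sequence) of
    positive-definite matrices.
    """
    states = np.asarray(states)
    covariances = np.asarray(covariances, dtype=float)
    if covariances.ndim != 3:
        raise ValueError("covariances must be (n_states, K, K)")
    if states.max() >= covariances.shape[0]:
        raise ValueError("state id without a covariance matrix")
    chols = []
    for c in covariances:
        try:
            chols.append(np.linalg.cholesky(c))
        except np.linalg.LinAlgError as e:
            raise ValueError("state covariance not positive-definite") from e
    rng = np.random.default_rng(seed)
    T, K = len(states), covariances.shape[1]
    z = rng.standard_normal((T, K))
    out = np.empty((T, K))
    for s, L in enumerate(chols):
        m = states == s
        out[m] = z[m] @ L.T
    return out


def mix_to_voxels(maps, timecourses, snr, seed=0):
    """Project component signals onto voxels and add Gaussian noise.

    Noise sd is set so that sd(signal over all voxels) / sd(noise) == snr.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    maps = np.asarray(maps, dtype=float)
    timecourses = np.asarray(timecourses, dtype=float)
    signal = timecourses @ maps
    sd = signal.std()
    noise_sd = (sd / snr) if sd > 0 else 1.0
    rng = np.random.default_rng(seed)
    return signal + noise_sd * rng.standard_normal(signal.shape)


def make_state_covariances(n_components, n_states, background_r=0.5, seed=0,
                           exclude=()):
    """Distinct unit-diagonal correlation structure per hidden state.

    Each state correlates a different disjoint set of component pairs at
    ``background_r`` so that the states are distinguishable from windowed
    connectivity alone.  Positive-definiteness is guaranteed by keeping the
    correlated pairs disjoint (block-diagonal 2x2 blocks).  Components in
    ``exclude`` are left uncorrelated, which reserves them for planted group
    effects without risking indefiniteness.
    """
    rng = np.random.default_rng(seed)
    covs = np.tile(np.eye(n_components), (n_states, 1, 1))
    excl = set(exclude)
    pairs = [(p, q) for p in range(n_components)
             for q in range(p + 1, n_components)
             if p not in excl and q not in excl]
    if not pairs:
        return covs
    for s in range(n_states):
        used = set()
        chosen = []
        order = rng.permutation(len(pairs))
        for idx in order:
            p, q = pairs[idx]
            if p in used or q in used:
                continue
            chosen.append((p, q))
            used.update((p, q))
            if len(chosen) >= max(1, n_components // 4):
                break
        for p, q in chosen:
            covs[s, p, q] = covs[s, q, p] = background_r
    return covs


def _apply_effect(covs, effect_pairs, delta):
    """Shift designated pair correlations per state; validates feasibility."""
    covs = covs.copy()
    for s in range(covs.shape[0]):
        d = delta[s]
        if d == 0:
            continue
        for p, q in effect_pairs:
            r = covs[s, p, q] + d
            if not (-1.0 < r < 1.0):
                raise ValueError(
                    f"delta {d} pushes pair ({p},{q}) correlation to {r}, "
                    "outside (-1, 1)")
            covs[s, p, q] = covs[s, q, p] = r
        # verify PD after the shift
        if np.linalg.eigvalsh(covs[s]).min() <= 1e-10:
            raise ValueError("effect delta makes a state covariance "
                             "non-positive-definite")
    return covs


def make_cohort(n_per_group=(40, 40), n_components=15, T=130, n_states=2,
                grid_shape=(15, 15, 10), mean_dwell=40,
                effect_pairs=None,
                delta=0.0, effect_states=None, snr=2.0, background_r=0.5,
                blob_sigma=1.5, seed=0, group_names=("A", "B")):
    """Generate a two-group cohort with a planted connectivity difference.

    Group ``B``'s state covariances have the ``effect_pairs`` correlations
    shifted by ``delta`` relative to group ``A``; spatial maps, state dynamics
    and noise level are shared.  ``delta`` may be a scalar — applied in every
    state by default, or only in the states listed in ``effect_states`` — or
    a length-``n_states`` sequence of per-state shifts (then
    ``effect_states`` is ignored), which allows state-dependent constructions
    such as opposite signs whose whole-course correlation averages out.

    The default effect emulates a distributed disconnection: several disjoint
    component pairs shifted together, the way a disorder alters a set of
    network couplings rather than a single edge (disjointness also keeps the
    shifted correlation matrices positive-definite for any |delta| < 1 at
    zero baseline).  Components carrying the effect get no background
    correlation, so with delta = 0 the two groups are exchangeable.

    Defaults mirror an ADNI-like scale: K=15 networks, T=130 time points,
    2 hidden states with dwell ~40 TR, a 15x15x10 voxel grid and snr 2.
    """
    if len(n_per_group) < 2:
        raise ValueError("need at least two groups")
    if effect_pairs is None:
        # distributed default: up to three disjoint pairs that fit K
        effect_pairs = tuple((p, p + 1) for p in (0, 2, 4)
                             if p + 1 < n_components)
    for p, q in effect_pairs:
        if not (0 <= p < n_components and 0 <= q < n_components and p != q):
            raise ValueError(f"effect pair ({p},{q}) invalid for "
                             f"K={n_components}")
    if np.ndim(delta) == 0:
        states = range(n_states) if effect_states is None else effect_states
        dvec = np.zeros(n_states)
        for s in states:
            dvec[s] = float(delta)
    else:
        dvec = np.asarray(delta, dtype=float)
        if dvec.shape != (n_states,):
            raise ValueError("per-state delta must have length n_states")

    rng = np.random.default_rng(seed)
    maps = make_spatial_maps(n_components, grid_shape, blob_sigma,
                             seed=rng.integers(2 ** 31))
    effect_components = sorted({c for pq in effect_pairs for c in pq})
    base = make_state_covariances(n_components, n_states, background_r,
                                  seed=rng.integers(2 ** 31),
                                  exclude=effect_components)
    cov_by_group = {
        group_names[0]: base,
        group_names[1]: _apply_effect(base, list(effect_pairs), dvec),
    }

    voxel_series, timecourses, state_sequences = [], [], []
    labels, subject_ids = [], []
    for g, n in zip(group_names, n_per_group):
        covs = cov_by_group[g]
        for i in range(n):
            sid = f"sub-{g}{i:03d}"
            states = sample_state_sequence(n_states, T, mean_dwell,
                                           seed=rng.integers(2 ** 31))
            tc = sample_component_timecourses(states, covs,
                                              seed=rng.integers(2 ** 31))
            vox = mix_to_voxels(maps, tc, snr, seed=rng.integers(2 ** 31))
            voxel_series.append(vox)
            timecourses.append(tc)
            state_sequences.append(states)
            labels.append(g)
            subject_ids.append(sid)

    return GroundTruthCohort(
        spatial_maps=maps,
        voxel_series=voxel_series,
        timecourses=timecourses,
        state_sequences=state_sequences,
        state_covariances=cov_by_group,
        group_labels=np.asarray(labels),
        subject_ids=subject_ids,
        effect_pairs=list(effect_pairs),
        delta=dvec,
        snr=float(snr),
        seed=int(seed),
        grid_shape=tuple(grid_shape),
    )
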