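"""Bayesian ball-and-stick fiber model and probabilistic streamline tracking.

The per-voxel signal model is the two-stick ball-and-stick form

    μ(g, b) = S0 [ (1 − f₁ − f₂) e^{−b d} + Σᵢ fᵢ e^{−b d (g·vᵢ)²} ]

with a Gamma prior on the diffusivity d, a uniform-on-the-sphere prior on
each stick orientation, automatic-relevance (1/f) shrinkage priors on the
stick fractions over the simplex f > 0, f₁ + f₂ ≤ 1, a flat prior on S0 and
a Jeffreys prior on the noise variance.  The posterior is sampled with Metropolis-within-Gibbs: Gaussian
random-walk proposals per parameter block (adapted during burn-in), and a
conjugate inverse-gamma Gibbs step for the noise variance.  All voxels are
updated simultaneously as vectorized chains.  A second stick is retained
for tracking only where its posterior mean fraction exceeds a support
threshold.

Tracking draws one posterior sample per step at the current voxel
(nearest-voxel lookup), picks among the supported stick orientations with
probability proportional to f, sign-aligns with the previous direction and
advances by the step length.  Streamlines terminate on target entry
(success), grid/termination-mask exit, curvature violation (cosine between
successive directions below the threshold — the FSL convention, 0.2 ≈ 78.5°
per step), loop detection on a half-resolution grid, or the step cap.
Propagation is bidirectional: two half-tracts per sample.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dwi import DWIVolume

__all__ = [
    "BallStickOptions",
    "FiberModel",
    "TrackingParams",
    "TractographyResult",
    "fit_ball_and_stick",
    "track",
    "angle_between_deg",
    "mean_orientation",
]


# --------------------------------------------------------------------------
# model containers


@dataclass
class BallStickOptions:
    """MCMC settings for the ball-and-stick fit.

    ``burn_in`` iterations are discarded (proposal scales adapt during this
    phase), then ``n_samples`` posterior samples are retained every ``thin``
    iterations.  ``f_support_threshold`` is the posterior-mean fraction a
    stick needs to count toward the voxel's fiber support.
    """

    burn_in: int = 400
    n_samples: int = 60
    thin: int = 2
    adapt_every: int = 25
    target_acceptance: float = 0.35
    f_support_threshold: float = 0.05
    ard: bool = True               # 1/f relevance shrinkage on stick fractions
    d_prior_shape: float = 2.0
    d_prior_mean: float = 1.5e-3   # mm²/s
    noise_floor_rel: float = 1e-3  # sd floor as a fraction of S0

    def __post_init__(self):
        if self.n_samples < 50:
            raise ValueError("at least 50 posterior samples per voxel are required")


@dataclass
class FiberModel:
    """Per-voxel posterior sample set driving probabilistic tracking."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    voxel_indices: np.ndarray    # (V, 3) int
    orientations: np.ndarray     # (V, K, 2, 3) unit vectors
    fractions: np.ndarray        # (V, K, 2)
    diffusivity: np.ndarray      # (V, K)
    support: np.ndarray          # (V,) int8 in {0, 1, 2}
    acceptance: np.ndarray | None = None
    flagged: np.ndarray | None = None
    vox_map: np.ndarray = field(init=False)

    def __post_init__(self):
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.int64)
        vm = np.full(self.shape, -1, dtype=np.int64)
        vm[tuple(self.voxel_indices.T)] = np.arange(self.voxel_indices.shape[0])
        self.vox_map = vm
        if self.flagged is None:
            self.flagged = np.zeros(self.voxel_indices.shape[0], dtype=bool)

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices.shape[0]

    @property
    def n_samples(self) -> int:
        return self.orientations.shape[1]

    @property
    def coverage(self) -> np.ndarray:
        return self.vox_map >= 0

    @classmethod
    def from_orientation_field(
        cls,
        orientations: np.ndarray,
        fractions: np.ndarray,
        voxel_size=(2.0, 2.0, 2.0),
        diffusivity: float = 1.2e-3,
    ) -> "FiberModel":
        """Deterministic single-sample model from a known orientation field
        (the phantom's ground truth) — the tracking oracle used in tests."""
        fractions = np.asarray(fractions, dtype=float)
        orientations = np.asarray(orientations, dtype=float)
        shape = fractions.shape[:3]
        vox = np.argwhere(fractions.sum(axis=-1) > 0)
        fr = fractions[tuple(vox.T)][:, None, :]          # (V, 1, 2)
        ori = orientations[tuple(vox.T)][:, None, :, :]   # (V, 1, 2, 3)
        support = (fractions[tuple(vox.T)] > 0).sum(axis=-1).astype(np.int8)
        return cls(
            shape=shape,
            voxel_size=tuple(float(v) for v in np.asarray(voxel_size).reshape(3)),
            voxel_indices=vox,
            orientations=ori,
            fractions=fr,
            diffusivity=np.full((vox.shape[0], 1), diffusivity),
            support=support,
        )


def angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Axial angle (degrees, in [0, 90]) between two orientation axes."""
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    return float(np.degrees(np.arccos(np.clip(abs(np.dot(u, v)), 0.0, 1.0))))


def mean_orientation(samples: np.ndarray) -> np.ndarray:
    """Posterior mean axis of orientation samples (K, 3), computed as the
    principal eigenvector of the mean dyadic tensor — immune to the ±v sign
    ambiguity of axial data."""
    s = np.asarray(samples, dtype=float)
    dyad = np.einsum("ki,kj->ij", s, s) / s.shape[0]
    w, v = np.linalg.eigh(dyad)
    return v[:, -1]


# --------------------------------------------------------------------------
# MCMC fit


def _sph_to_vec(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def _vec_to_sph(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.arccos(np.clip(v[..., 2], -1.0, 1.0))
    phi = np.arctan2(v[..., 1], v[..., 0])
    return theta, phi


def _wrap_theta_phi(theta, phi):
    theta = np.mod(theta, 2 * np.pi)
    over = theta > np.pi
    theta = np.where(over, 2 * np.pi - theta, theta)
    phi = np.where(over, phi + np.pi, phi)
    return theta, np.mod(phi, 2 * np.pi)


class _State:
    """Vectorized chain state for V voxels."""

    __slots__ = ("th1", "ph1", "th2", "ph2", "f1", "f2", "d", "s0", "sigma2", "ss")

    def __init__(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)


def _model_mu(th1, ph1, th2, ph2, f1, f2, d, s0, bvals, bvecs):
    v1 = _sph_to_vec(th1, ph1)
    v2 = _sph_to_vec(th2, ph2)
    bd = d[:, None] * bvals[None, :]
    e_ball = np.exp(-bd)
    dot1 = v1 @ bvecs.T
    dot2 = v2 @ bvecs.T
    e1 = np.exp(-bd * dot1**2)
    e2 = np.exp(-bd * dot2**2)
    att = (1.0 - f1 - f2)[:, None] * e_ball + f1[:, None] * e1 + f2[:, None] * e2
    return s0[:, None] * att


def _init_state(y, bvals, bvecs, b0_index, opts):
    """Initialize chains from a quick unweighted log-linear tensor fit."""
    V, N = y.shape
    s0 = np.maximum(y[:, b0_index], 1e-6)
    floor = np.maximum(np.finfo(float).eps * s0[:, None], 1e-300)
    ylog = np.log(np.maximum(y, floor))
    g = bvecs
    X = np.column_stack(
        [
            np.ones(N),
            -bvals * g[:, 0] ** 2,
            -bvals * g[:, 1] ** 2,
            -bvals * g[:, 2] ** 2,
            -2 * bvals * g[:, 0] * g[:, 1],
            -2 * bvals * g[:, 0] * g[:, 2],
            -2 * bvals * g[:, 1] * g[:, 2],
        ]
    )
    beta, *_ = np.linalg.lstsq(X, ylog.T, rcond=None)
    beta = beta.T
    D = np.empty((V, 3, 3))
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]
    evals, evecs = np.linalg.eigh(D)
    md = np.clip(evals.mean(axis=1), 1e-4, 5e-3)
    lam = evals[:, ::-1]
    mean = lam.mean(axis=1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=1))
    den = np.sqrt(np.sum(lam**2, axis=1))
    fa = np.sqrt(1.5) * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    v1 = evecs[:, :, 2]  # principal
    v2 = evecs[:, :, 1]  # orthogonal by construction
    th1, ph1 = _vec_to_sph(v1)
    th2, ph2 = _vec_to_sph(v2)
    f1 = np.clip(fa, 0.05, 0.85)
    f2 = np.full(V, 0.05)
    d = md
    mu = _model_mu(th1, ph1, th2, ph2, f1, f2, d, s0, bvals, bvecs)
    ss = np.sum((y - mu) ** 2, axis=1)
    floor_var = (opts.noise_floor_rel * s0) ** 2
    sigma2 = np.maximum(ss / max(N - 1, 1), floor_var)
    return _State(
        th1=th1, ph1=ph1, th2=th2, ph2=ph2, f1=f1, f2=f2, d=d, s0=s0,
        sigma2=sigma2, ss=ss,
    ), floor_var


def fit_ball_and_stick(
    dwi: DWIVolume,
    mask: np.ndarray | None = None,
    options: BallStickOptions | None = None,
    seed: int = 0,
) -> FiberModel:
    """Sample the ball-and-stick posterior in every voxel of ``mask``
    (default: the brain mask) and return the retained sample set.

    Voxels whose post-burn-in acceptance rate falls outside [0.05, 0.95]
    are flagged and a summary warning is issued.
    """
    opts = options or BallStickOptions()
    if mask is None:
        mask = dwi.brain_mask
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.spatial_shape:
        raise ValueError("fit mask shape mismatch")
    if not np.any(dwi.gradients.b0_mask):
        raise ValueError("ball-and-stick fit needs at least one b0 volume")

    vox = np.argwhere(mask)
    y = dwi.signal[mask]
    V, N = y.shape
    bvals = dwi.gradients.bvals
    bvecs = dwi.gradients.bvecs
    rng = np.random.default_rng(seed)

    state, floor_var = _init_state(y, bvals, bvecs, dwi.b0_index, opts)

    k_shape = opts.d_prior_shape
    d_scale = opts.d_prior_mean / k_shape

    scales = {
        "ori1": np.full(V, 0.15),
        "ori2": np.full(V, 0.25),
        "f1": np.full(V, 0.05),
        "f2": np.full(V, 0.05),
        "d": np.full(V, 1e-4),
        "s0": 0.02 * state.s0.copy(),
    }
    scale_bounds = {
        "ori1": (1e-3, 1.5), "ori2": (1e-3, 1.5),
        "f1": (1e-3, 0.3), "f2": (1e-3, 0.3),
        "d": (1e-6, 1e-3), "s0": None,
    }
    blocks = ("ori1", "ori2", "f1", "f2", "d", "s0")

    def mu_of(st):
        return _model_mu(
            st.th1, st.ph1, st.th2, st.ph2, st.f1, st.f2, st.d, st.s0, bvals, bvecs
        )

    def propose(block):
        """Return (candidate params dict, validity mask, extra log-prior)."""
        sc = scales[block]
        if block in ("ori1", "ori2"):
            th = state.th1 if block == "ori1" else state.th2
            ph = state.ph1 if block == "ori1" else state.ph2
            th_n = th + sc * rng.standard_normal(V)
            ph_n = ph + sc * rng.standard_normal(V)
            th_n, ph_n = _wrap_theta_phi(th_n, ph_n)
            # uniform-on-sphere prior: density ∝ sin θ
            logp = np.log(np.maximum(np.sin(th_n), 1e-12)) - np.log(
                np.maximum(np.sin(th), 1e-12)
            )
            key = ("th1", "ph1") if block == "ori1" else ("th2", "ph2")
            return {key[0]: th_n, key[1]: ph_n}, np.ones(V, bool), logp
        if block in ("f1", "f2"):
            f_old = state.f1 if block == "f1" else state.f2
            other = state.f2 if block == "f1" else state.f1
            f_n = f_old + sc * rng.standard_normal(V)
            valid = (f_n >= 1e-6) & (f_n + other <= 1.0)
            if opts.ard:
                # automatic relevance determination: p(f) ∝ 1/f shrinks
                # fractions the data cannot support toward zero
                safe = np.where(valid, f_n, f_old)
                logp = -(np.log(safe) - np.log(np.maximum(f_old, 1e-12)))
            else:
                logp = np.zeros(V)
            return {block: f_n}, valid, logp
        if block == "d":
            d_n = state.d + sc * rng.standard_normal(V)
            valid = (d_n > 0) & (d_n < 0.02)
            safe = np.where(valid, d_n, state.d)
            logp = (k_shape - 1.0) * (np.log(safe) - np.log(state.d)) - (
                safe - state.d
            ) / d_scale
            return {"d": d_n}, valid, logp
        s0_n = state.s0 + sc * rng.standard_normal(V)
        valid = s0_n > 0
        return {"s0": s0_n}, valid, np.zeros(V)

    n_iter = opts.burn_in + opts.n_samples * opts.thin
    K = opts.n_samples
    samp_ori = np.zeros((V, K, 2, 3), dtype=np.float32)
    samp_f = np.zeros((V, K, 2), dtype=np.float32)
    samp_d = np.zeros((V, K), dtype=np.float32)

    acc_window = {b: np.zeros(V) for b in blocks}
    acc_post = np.zeros(V)
    n_post_updates = 0
    k_out = 0

    for it in range(n_iter):
        for block in blocks:
            cand, valid, logp = propose(block)
            trial = _State(
                **{
                    k: cand.get(k, getattr(state, k))
                    for k in ("th1", "ph1", "th2", "ph2", "f1", "f2", "d", "s0")
                },
                sigma2=state.sigma2,
                ss=state.ss,
            )
            mu_new = mu_of(trial)
            ss_new = np.sum((y - mu_new) ** 2, axis=1)
            log_r = (state.ss - ss_new) / (2.0 * state.sigma2) + logp
            accept = valid & (np.log(rng.random(V)) < log_r)
            for k, v in cand.items():
                cur = getattr(state, k)
                setattr(state, k, np.where(accept, v, cur))
            state.ss = np.where(accept, ss_new, state.ss)
            acc_window[block] += accept
            if it >= opts.burn_in:
                acc_post += accept
        # conjugate inverse-gamma Gibbs step for the noise variance
        state.sigma2 = np.maximum(
            (state.ss / 2.0) / rng.gamma(N / 2.0, 1.0, size=V), floor_var
        )
        if it >= opts.burn_in:
            n_post_updates += len(blocks)

        if it < opts.burn_in and (it + 1) % opts.adapt_every == 0:
            for block in blocks:
                rate = acc_window[block] / opts.adapt_every
                scales[block] = scales[block] * np.exp(rate - opts.target_acceptance)
                bounds = scale_bounds[block]
                if bounds is not None:
                    scales[block] = np.clip(scales[block], *bounds)
                else:
                    scales[block] = np.clip(
                        scales[block], 1e-4 * state.s0, 0.5 * state.s0
                    )
                acc_window[block][:] = 0.0
        elif (it + 1) % opts.adapt_every == 0:
            for block in blocks:
                acc_window[block][:] = 0.0

        if it >= opts.burn_in and (it - opts.burn_in) % opts.thin == 0 and k_out < K:
            samp_ori[:, k_out, 0] = _sph_to_vec(state.th1, state.ph1)
            samp_ori[:, k_out, 1] = _sph_to_vec(state.th2, state.ph2)
            samp_f[:, k_out, 0] = state.f1
            samp_f[:, k_out, 1] = state.f2
            samp_d[:, k_out] = state.d
            k_out += 1

    acceptance = acc_post / max(n_post_updates, 1)
    flagged = (acceptance < 0.05) | (acceptance > 0.95)
    if np.any(flagged):
        warnings.warn(
            f"{int(flagged.sum())}/{V} voxels have MCMC acceptance outside "
            "[0.05, 0.95] after adaptation"
        )

    # order sticks by posterior mean fraction, then threshold for support
    mean_f = samp_f.mean(axis=1)  # (V, 2)
    swap = mean_f[:, 1] > mean_f[:, 0]
    if np.any(swap):
        samp_f[swap] = samp_f[swap][:, :, ::-1]
        samp_ori[swap] = samp_ori[swap][:, :, ::-1]
        mean_f = samp_f.mean(axis=1)
    support = (mean_f >= opts.f_support_threshold).sum(axis=1).astype(np.int8)

    return FiberModel(
        shape=dwi.spatial_shape,
        voxel_size=dwi.voxel_size,
        voxel_indices=vox,
        orientations=samp_ori,
        fractions=samp_f,
        diffusivity=samp_d,
        support=support,
        acceptance=acceptance,
        flagged=flagged,
    )


# --------------------------------------------------------------------------
# tracking


@dataclass(frozen=True)
class TrackingParams:
    """Probabilistic tracking settings.

    ``curvature`` is the minimum cosine between successive step directions
    (FSL convention: 0.2 allows bends up to ≈78.5° per step).
    """

    samples: int = 5000
    step_mm: float = 0.5
    curvature: float = 0.2
    loopcheck: bool = True
    max_steps: int = 2000

    def __post_init__(self):
        if self.samples < 1:
            raise ValueError("samples per seed voxel must be ≥ 1")
        if self.step_mm <= 0:
            raise ValueError("step length must be > 0")
        if not -1.0 <= self.curvature <= 1.0:
            raise ValueError("curvature threshold must be in [-1, 1]")


@dataclass
class TractographyResult:
    """Per-seed-voxel success counts and the visitation map of successful
    streamlines for one (seed mask, classification target) pair."""

    seed_mask: np.ndarray
    target_mask: np.ndarray
    success_counts: np.ndarray   # (x, y, z) uint32, nonzero only on seeds
    visitation: np.ndarray       # (x, y, z) uint32
    samples_per_voxel: int
    params: TrackingParams

    @property
    def n_seed_voxels(self) -> int:
        return int(self.seed_mask.sum())

    @property
    def seed_counts(self) -> np.ndarray:
        """Success counts of the seed voxels as a flat vector."""
        return self.success_counts[self.seed_mask]


_CHUNK = 2048
_RAND_BLOCK = 64


def track(
    model: FiberModel,
    seed_mask: np.ndarray,
    target_mask: np.ndarray,
    params: TrackingParams | None = None,
    termination_mask: np.ndarray | None = None,
    seed: int = 0,
) -> TractographyResult:
    """Probabilistic tractography from every voxel of ``seed_mask`` toward
    the classification target.

    Each seed voxel launches ``params.samples`` streamlines from its centre,
    propagated in both directions.  A sample succeeds when either half-tract
    enters the target mask; an unreachable target is not an error (counts
    stay 0).
    """
    params = params or TrackingParams()
    seed_mask = np.asarray(seed_mask, dtype=bool)
    target_mask = np.asarray(target_mask, dtype=bool)
    shape = model.shape
    if seed_mask.shape != shape or target_mask.shape != shape:
        raise ValueError("masks must live on the model grid")
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if np.any(seed_mask & target_mask):
        raise ValueError("seed and target masks must be disjoint")
    if termination_mask is None:
        termination_mask = model.coverage
    termination_mask = np.asarray(termination_mask, dtype=bool) | target_mask

    vs = np.asarray(model.voxel_size, dtype=float)
    shape_arr = np.asarray(shape)
    seed_vox = np.argwhere(seed_mask)
    n_seeds = seed_vox.shape[0]
    samples = params.samples
    n_slots = n_seeds * samples
    slot_seed = np.repeat(np.arange(n_seeds), samples)
    K = model.n_samples

    coarse_shape = tuple((shape_arr + 1) // 2)
    n_cells = int(np.prod(coarse_shape))

    success = np.zeros(n_slots, dtype=bool)
    visitation = np.zeros(shape, dtype=np.int64)

    n_chunks = (n_slots + _CHUNK - 1) // _CHUNK
    seeds = np.random.SeedSequence(seed).spawn(n_chunks)

    for ci in range(n_chunks):
        lo, hi = ci * _CHUNK, min((ci + 1) * _CHUNK, n_slots)
        n = hi - lo
        rng = np.random.default_rng(seeds[ci])
        sidx = seed_vox[slot_seed[lo:hi]]                    # (n, 3)
        rows0 = model.vox_map[tuple(sidx.T)]
        k0 = rng.integers(0, K, size=n)
        u0 = rng.random(n)
        alive0 = (rows0 >= 0) & (model.support[np.maximum(rows0, 0)] > 0)
        v0 = np.zeros((n, 3))
        if np.any(alive0):
            r = rows0[alive0]
            fr = model.fractions[r, k0[alive0]]              # (m, 2)
            two = model.support[r] == 2
            tot = fr.sum(axis=1)
            p2 = np.where(two & (tot > 0), fr[:, 1] / np.where(tot > 0, tot, 1.0), 0.0)
            stick = (u0[alive0] < p2).astype(int)
            v0[alive0] = model.orientations[r, k0[alive0], stick]
        pos = np.repeat(((sidx + 0.5) * vs)[:, None, :], 2, axis=1)   # (n, 2, 3)
        dirs = np.stack([v0, -v0], axis=1)                            # (n, 2, 3)
        active = np.repeat(alive0[:, None], 2, axis=1)
        succ = np.zeros(n, dtype=bool)
        visits_slot: list[np.ndarray] = []
        visits_vox: list[np.ndarray] = []
        loop_store = (
            np.zeros((n, 2, n_cells, 3), dtype=np.int8) if params.loopcheck else None
        )

        ks = us = None
        for step in range(params.max_steps):
            if not active.any():
                break
            if step % _RAND_BLOCK == 0:
                ks = rng.integers(0, K, size=(n, 2, _RAND_BLOCK))
                us = rng.random((n, 2, _RAND_BLOCK))
            sl, hf = np.nonzero(active)
            p = pos[sl, hf]
            vox = np.floor(p / vs[None, :]).astype(np.int64)
            inside = np.all((vox >= 0) & (vox < shape_arr[None, :]), axis=1)
            active[sl[~inside], hf[~inside]] = False
            sl, hf, vox = sl[inside], hf[inside], vox[inside]
            flat = np.ravel_multi_index(tuple(vox.T), shape)

            hit = target_mask.flat[flat]
            if np.any(hit):
                succ[sl[hit]] = True
                visits_slot.append(sl[hit])
                visits_vox.append(flat[hit])
                active[sl[hit], hf[hit]] = False
                keep = ~hit
                sl, hf, vox, flat = sl[keep], hf[keep], vox[keep], flat[keep]

            ok_term = termination_mask.flat[flat]
            rows = model.vox_map.flat[flat]
            ok_model = (rows >= 0) & (model.support[np.maximum(rows, 0)] > 0)
            dead = ~(ok_term & ok_model)
            if np.any(dead):
                active[sl[dead], hf[dead]] = False
                keep = ~dead
                sl, hf, vox, flat, rows = (
                    sl[keep], hf[keep], vox[keep], flat[keep], rows[keep]
                )
            if sl.size == 0:
                continue
            visits_slot.append(sl)
            visits_vox.append(flat)

            k = ks[sl, hf, step % _RAND_BLOCK]
            u = us[sl, hf, step % _RAND_BLOCK]
            fr = model.fractions[rows, k]                     # (m, 2)
            two = model.support[rows] == 2
            tot = fr.sum(axis=1)
            p2 = np.where(two & (tot > 0), fr[:, 1] / np.where(tot > 0, tot, 1.0), 0.0)
            stick = (u < p2).astype(int)
            v = model.orientations[rows, k, stick].astype(float)

            prev = dirs[sl, hf]
            dt = np.sum(v * prev, axis=1)
            v = np.where(dt[:, None] < 0, -v, v)
            cos = np.abs(dt)
            kill = cos < params.curvature

            if params.loopcheck:
                cell = np.ravel_multi_index(tuple((vox // 2).T), coarse_shape)
                stored = loop_store[sl, hf, cell]             # (m, 3) int8
                seen = np.any(stored != 0, axis=1)
                rev = np.sum(stored.astype(float) * v, axis=1) < 0
                kill |= seen & rev
                new = ~seen & ~kill
                if np.any(new):
                    loop_store[sl[new], hf[new], cell[new]] = np.clip(
                        np.round(v[new] * 127), -127, 127
                    ).astype(np.int8)

            if np.any(kill):
                active[sl[kill], hf[kill]] = False
            move = ~kill
            if np.any(move):
                slm, hfm = sl[move], hf[move]
                dirs[slm, hfm] = v[move]
                pos[slm, hfm] = pos[slm, hfm] + params.step_mm * v[move]

        success[lo:hi] = succ
        if np.any(succ) and visits_slot:
            all_sl = np.concatenate(visits_slot)
            all_vox = np.concatenate(visits_vox)
            good = succ[all_sl]
            if np.any(good):
                pair = all_sl[good].astype(np.int64) * visitation.size + all_vox[good]
                uniq = np.unique(pair)
                vox_ids = (uniq % visitation.size).astype(np.int64)
                np.add.at(visitation.reshape(-1), vox_ids, 1)

    counts = np.zeros(shape, dtype=np.uint32)
    per_seed = np.bincount(slot_seed[success], minlength=n_seeds)
    counts[tuple(seed_vox.T)] = per_seed
    return TractographyResult(
        seed_mask=seed_mask,
        target_mask=target_mask,
        success_counts=counts,
        visitation=visitation.astype(np.uint32),
        samples_per_voxel=samples,
        params=params,
    )
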