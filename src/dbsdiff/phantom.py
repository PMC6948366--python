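"""Synthetic two-session DWI phantom generator.

Emulates the acquisition contrast of a pre-operative (high-SNR, anesthetized)
versus post-operative (low-SNR, moving, electrode signal-dropout) diffusion
study on a small voxel grid with known fiber geometry.  Every downstream
stage of the pipeline — motion correction, tensor scalars, quality metrics,
ROI statistics, Bayesian tractography — is testable against the ground truth
this module records.

Signal model (ball-and-stick, single shell):

    S(g, b) = S0 [ (1 − Σ f_i) e^{−b d}  +  Σ_i f_i e^{−b d (g·v_i)²} ]

with at most two sticks per voxel, isotropic tissue attenuation
``e^{−b d_tissue}`` in gray matter / CSF, and Rician measurement noise
``|S + ε₁ + i ε₂|`` with ε ~ N(0, σ²) — the physically correct noise family
for magnitude MR images.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dwi import DWIVolume
from .gradients import GradientTable, make_scheme
from .rigid import RigidTransform, apply_rigid, grid_center_mm, resample_moved

# tissue class codes
AIR, GM, WM, CSF = 0, 1, 2, 3

_CENTERLINE_STEP = 0.25  # voxels; densification step along bundle centerlines


@dataclass(frozen=True)
class Bundle:
    """A fiber bundle: centerline waypoints (voxel coords), tube radius
    (voxels) and stick volume fraction f."""

    waypoints: np.ndarray
    radius: float = 1.5
    f: float = 0.7

    def __post_init__(self):
        wp = np.asarray(self.waypoints, dtype=float)
        if wp.ndim != 2 or wp.shape[1] != 3 or wp.shape[0] < 2:
            raise ValueError("waypoints must be an (M ≥ 2, 3) array")
        if self.radius <= 0:
            raise ValueError("bundle radius must be > 0")
        if not 0 < self.f <= 1:
            raise ValueError("stick fraction f must be in (0, 1]")
        object.__setattr__(self, "waypoints", wp)


@dataclass(frozen=True)
class ArtifactSpec:
    """Spherical signal-dropout region (electrode/wire susceptibility)."""

    center: np.ndarray
    radius: float
    attenuation: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError("artifact attenuation factor must be in [0, 1]")
        if self.radius <= 0:
            raise ValueError("artifact radius must be > 0")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))


@dataclass
class PhantomSpec:
    """Full description of a synthetic subject.

    ``tissue_labels`` and ``roi_labels`` may be supplied explicitly or left
    None, in which case a default ellipsoidal brain (GM everywhere, WM on
    bundles, air outside) is built and no ROIs are defined.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    bundles: list[Bundle] = field(default_factory=list)
    tissue_labels: np.ndarray | None = None
    roi_labels: np.ndarray | None = None
    roi_defs: dict[str, int] = field(default_factory=dict)
    seed_rois: list[str] = field(default_factory=list)
    target_rois: list[str] = field(default_factory=list)
    artifact: ArtifactSpec | None = None
    csf_center: tuple[float, float, float] | None = None  # default-tissue CSF blob
    csf_radius: float = 1.5
    sigma_pre: float = 5.0
    sigma_post: float = 40.0
    s0: float = 1000.0
    d_wm: float = 1.2e-3   # mm²/s, stick & ball diffusivity in white matter
    d_gm: float = 0.9e-3   # mm²/s, isotropic gray matter
    d_csf: float = 3.0e-3  # mm²/s, isotropic CSF
    # relative proton-density/T2 weights per tissue: give the b0 image the
    # tissue contrast real T2-weighted b0 volumes have (needed for image
    # registration to be well-posed)
    s0_gm: float = 1.0
    s0_wm: float = 0.9
    s0_csf: float = 1.6

    def validate(self) -> None:
        if self.sigma_pre < 0 or self.sigma_post < 0:
            raise ValueError("noise sigma must be ≥ 0")
        if self.s0 <= 0:
            raise ValueError("S0 must be > 0")
        for name in self.seed_rois + self.target_rois:
            if name not in self.roi_defs:
                raise ValueError(f"ROI '{name}' missing from label dictionary")


@dataclass
class Phantom:
    """Rasterized phantom: per-voxel fiber orientations, tissue classes,
    ROI labels and artifact mask, all on the same grid."""

    spec: PhantomSpec
    orientations: np.ndarray   # (x, y, z, 2, 3) unit vectors, zero where absent
    fractions: np.ndarray      # (x, y, z, 2) stick fractions
    n_fibers: np.ndarray       # (x, y, z) int, 0..2
    tissue: np.ndarray         # (x, y, z) int tissue class
    roi_labels: np.ndarray     # (x, y, z) int, 0 = background
    artifact_mask: np.ndarray  # (x, y, z) bool

    @property
    def shape(self):
        return self.tissue.shape

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue != AIR

    def tissue_mask(self, klass: int) -> np.ndarray:
        return self.tissue == klass

    def masks(self) -> dict[str, np.ndarray]:
        return {
            "brain": self.brain_mask,
            "gm": self.tissue_mask(GM),
            "wm": self.tissue_mask(WM),
            "air": self.tissue_mask(AIR),
            "csf": self.tissue_mask(CSF),
            "artifact": self.artifact_mask,
        }

    def roi_mask(self, label: int) -> np.ndarray:
        return self.roi_labels == label


def _densify(waypoints: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at ~0.25-voxel arc-length steps and return points
    with unit tangents (centered finite differences)."""
    seg = np.linalg.norm(np.diff(waypoints, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("bundle centerline has zero length")
    knots = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, total, max(int(np.ceil(total / _CENTERLINE_STEP)) + 1, 2))
    pts = np.column_stack([np.interp(s, knots, waypoints[:, i]) for i in range(3)])
    tang = np.gradient(pts, s, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return pts, tang


def _rasterize_bundle(bundle: Bundle, shape) -> tuple[np.ndarray, np.ndarray]:
    """Return (inside mask, per-voxel unit tangent) for one bundle tube."""
    pts, tang = _densify(bundle.waypoints)
    shape = np.asarray(shape)
    r = bundle.radius
    lo = pts.min(axis=0) - r
    hi = pts.max(axis=0) + r
    if np.any(lo < -0.5) or np.any(hi > shape - 0.5):
        raise ValueError(
            f"bundle tube leaves the grid (extent {lo.round(2)}..{hi.round(2)} "
            f"vs shape {tuple(shape)})"
        )
    dist = np.full(tuple(shape), np.inf)
    nearest = np.full(tuple(shape), -1, dtype=np.int64)
    reach = int(np.ceil(r))
    off = np.arange(-reach, reach + 1)
    ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    for i, p in enumerate(pts):
        base = np.round(p).astype(int)
        vox = base[None, :] + offsets
        ok = np.all((vox >= 0) & (vox < shape[None, :]), axis=1)
        vox = vox[ok]
        d = np.linalg.norm(vox - p[None, :], axis=1)
        close = d <= r
        vox, d = vox[close], d[close]
        idx = (vox[:, 0], vox[:, 1], vox[:, 2])
        better = d < dist[idx]
        bi = tuple(a[better] for a in idx)
        dist[bi] = d[better]
        nearest[bi] = i
    inside = np.isfinite(dist) & (dist <= r)
    orient = np.zeros(tuple(shape) + (3,))
    orient[inside] = tang[nearest[inside]]
    return inside, orient


_BRAIN_SEMI_FRACTIONS = (0.46, 0.42, 0.37)  # anisotropic, so rotations are identifiable


def default_tissue(
    shape,
    bundle_mask: np.ndarray | None = None,
    csf_center=None,
    csf_radius: float = 1.5,
) -> np.ndarray:
    """Ellipsoidal brain inscribed in the grid: GM inside, WM on bundles,
    air outside, with an optional CSF blob (ventricle stand-in)."""
    shape = np.asarray(shape)
    center = (shape - 1) / 2.0
    semi = np.asarray(_BRAIN_SEMI_FRACTIONS) * shape
    coords = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    rho = np.sum(((coords - center) / semi) ** 2, axis=-1)
    tissue = np.full(tuple(shape), AIR, dtype=np.int8)
    tissue[rho <= 1.0] = GM
    if csf_center is not None:
        tissue[ball_mask(shape, csf_center, csf_radius) & (tissue == GM)] = CSF
    if bundle_mask is not None:
        tissue[bundle_mask] = WM
    return tissue


def ball_mask(shape, center, radius) -> np.ndarray:
    shape = np.asarray(shape)
    center = np.asarray(center, dtype=float)
    coords = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1)
    return np.linalg.norm(coords - center, axis=-1) <= radius


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a :class:`PhantomSpec` into orientation/tissue/ROI volumes.

    Raises if a bundle tube leaves the grid, more than two bundles overlap in
    a voxel, or configured seed/target ROI masks overlap each other.
    """
    spec.validate()
    shape = tuple(spec.shape)
    orientations = np.zeros(shape + (2, 3))
    fractions = np.zeros(shape + (2,))
    n_fibers = np.zeros(shape, dtype=np.int8)
    bundle_any = np.zeros(shape, dtype=bool)
    for bundle in spec.bundles:
        inside, orient = _rasterize_bundle(bundle, shape)
        if np.any(n_fibers[inside] >= 2):
            raise ValueError("more than two bundles overlap in at least one voxel")
        slot = n_fibers[inside]
        idx = np.argwhere(inside)
        orientations[idx[:, 0], idx[:, 1], idx[:, 2], slot] = orient[inside]
        fractions[idx[:, 0], idx[:, 1], idx[:, 2], slot] = bundle.f
        n_fibers[inside] += 1
        bundle_any |= inside

    tissue = spec.tissue_labels
    if tissue is None:
        tissue = default_tissue(shape, bundle_any, spec.csf_center, spec.csf_radius)
    else:
        tissue = np.asarray(tissue)
        if tissue.shape != shape:
            raise ValueError("tissue label volume shape mismatch")

    roi_labels = spec.roi_labels
    if roi_labels is None:
        roi_labels = np.zeros(shape, dtype=np.int16)
    else:
        roi_labels = np.asarray(roi_labels)
        if roi_labels.shape != shape:
            raise ValueError("ROI label volume shape mismatch")

    for s_name in spec.seed_rois:
        for t_name in spec.target_rois:
            s_lab, t_lab = spec.roi_defs[s_name], spec.roi_defs[t_name]
            if s_lab == t_lab:
                raise ValueError(
                    f"seed ROI '{s_name}' and target ROI '{t_name}' share label {s_lab}"
                )

    artifact_mask = np.zeros(shape, dtype=bool)
    if spec.artifact is not None:
        artifact_mask = ball_mask(shape, spec.artifact.center, spec.artifact.radius)

    return Phantom(
        spec=spec,
        orientations=orientations,
        fractions=fractions,
        n_fibers=n_fibers,
        tissue=tissue,
        roi_labels=roi_labels,
        artifact_mask=artifact_mask,
    )


def noiseless_signal(phantom: Phantom, gradients: GradientTable) -> np.ndarray:
    """Closed-form ball-and-stick signal for every voxel and volume."""
    spec = phantom.spec
    b = gradients.bvals
    g = gradients.bvecs
    shape = phantom.shape
    signal = np.zeros(shape + (len(gradients),))

    for klass, d, w in (
        (GM, spec.d_gm, spec.s0_gm),
        (CSF, spec.d_csf, spec.s0_csf),
        (WM, spec.d_wm, spec.s0_wm),  # isotropic WM voxels without sticks
    ):
        m = phantom.tissue == klass
        if klass == WM:
            m = m & (phantom.n_fibers == 0)
        signal[m] = w * spec.s0 * np.exp(-b * d)[None, :]

    fib = np.argwhere(phantom.n_fibers > 0)
    if fib.size:
        fr = phantom.fractions[fib[:, 0], fib[:, 1], fib[:, 2]]        # (V, 2)
        fsum = fr.sum(axis=1)
        if np.any(fsum > 1.0 + 1e-9):
            raise ValueError("stick fractions sum above 1 in at least one voxel")
        v = phantom.orientations[fib[:, 0], fib[:, 1], fib[:, 2]]      # (V, 2, 3)
        dot = np.einsum("nk,vfk->vfn", g, v)                            # (V, 2, N)
        stick = np.exp(-b[None, None, :] * spec.d_wm * dot**2)
        ball = np.exp(-b * spec.d_wm)[None, :]
        att = (1.0 - fsum)[:, None] * ball + np.einsum("vf,vfn->vn", fr, stick)
        signal[fib[:, 0], fib[:, 1], fib[:, 2]] = spec.s0_wm * spec.s0 * att
    return signal


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + complex Gaussian noise of parameter sigma)."""
    if sigma == 0:
        return signal.copy()
    re = signal + rng.normal(0.0, sigma, size=signal.shape)
    im = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(re, im)


def simulate_dwi(
    phantom: Phantom,
    gradients: GradientTable | None = None,
    sigma: float = 0.0,
    seed: int = 0,
    session: str = "pre",
    dropout_mask: np.ndarray | None = None,
    dropout_attenuation: float = 1.0,
) -> DWIVolume:
    """Simulate one session's DWI from the phantom.

    The noiseless signal obeys the ball-and-stick closed form exactly; the
    same seed always yields an identical volume.  ``dropout_mask`` models a
    susceptibility artifact at acquisition: the *clean* signal inside the
    mask is multiplied by ``dropout_attenuation`` before Rician noise is
    added, so the local SNR genuinely collapses (thermal noise is unchanged
    by signal loss).  Compare :func:`apply_artifact`, which masks an
    already-reconstructed magnitude image.
    """
    if sigma < 0:
        raise ValueError("sigma must be ≥ 0")
    if gradients is None:
        gradients = make_scheme()
    clean = noiseless_signal(phantom, gradients)
    if dropout_mask is not None:
        if not 0.0 <= dropout_attenuation <= 1.0:
            raise ValueError("dropout attenuation must be in [0, 1]")
        dropout_mask = np.asarray(dropout_mask, dtype=bool)
        if dropout_mask.shape != phantom.shape:
            raise ValueError("dropout mask shape mismatch")
        clean = clean.copy()
        clean[dropout_mask] *= dropout_attenuation
    rng = np.random.default_rng(seed)
    noisy = add_rician_noise(clean, sigma, rng)
    masks = {k: v for k, v in phantom.masks().items() if k != "artifact"}
    meta = {
        "sigma": float(sigma),
        "noise_seed": int(seed),
        "labels": phantom.roi_labels,
        "s0": phantom.spec.s0,
    }
    return DWIVolume(
        signal=noisy,
        gradients=gradients,
        voxel_size=phantom.spec.voxel_size,
        session=session,
        masks=masks,
        meta=meta,
    )


def apply_artifact(dwi: DWIVolume, artifact_mask: np.ndarray, attenuation: float) -> DWIVolume:
    """Multiply the signal inside the artifact mask by ``attenuation``.

    Applied to the final (already noisy) signal, matching the appearance of
    susceptibility dropout in magnitude images; voxels outside the mask are
    bit-identical to the input.
    """
    if not 0.0 <= attenuation <= 1.0:
        raise ValueError("attenuation factor must be in [0, 1]")
    artifact_mask = np.asarray(artifact_mask, dtype=bool)
    if artifact_mask.shape != dwi.spatial_shape:
        raise ValueError("artifact mask shape mismatch")
    signal = dwi.signal.copy()
    signal[artifact_mask] *= attenuation
    return dwi.copy_with(
        signal=signal,
        meta_update={"artifact_attenuation": float(attenuation)},
    )


def apply_motion(dwi: DWIVolume, transforms: list[RigidTransform]) -> DWIVolume:
    """Resample each volume under its rigid head-motion transform.

    One transform per volume; the b0 reference transform must be identity.
    Raises if any transform moves more than 25% of brain voxels outside the
    grid.  Ground-truth transforms are recorded in ``meta['true_motion']``
    for recovery testing.
    """
    if len(transforms) != dwi.n_volumes:
        raise ValueError(f"need {dwi.n_volumes} transforms, got {len(transforms)}")
    if not transforms[dwi.b0_index].is_identity:
        raise ValueError("the b0 reference volume transform must be identity")

    vs = np.asarray(dwi.voxel_size)
    center = grid_center_mm(dwi.spatial_shape, vs)
    brain = dwi.masks.get("brain")
    if brain is not None and brain.any():
        pts = np.argwhere(brain) * vs[None, :]
        n_brain = pts.shape[0]
        upper = (np.asarray(dwi.spatial_shape) - 0.5) * vs
        for i, tr in enumerate(transforms):
            if tr.is_identity:
                continue
            moved = apply_rigid(pts, tr, center)
            outside = np.any((moved < -0.5 * vs) | (moved > upper), axis=1)
            if outside.sum() > 0.25 * n_brain:
                raise ValueError(
                    f"transform for volume {i} moves >25% of brain voxels outside the grid"
                )

    signal = np.empty_like(dwi.signal)
    for v, tr in enumerate(transforms):
        if tr.is_identity:
            signal[..., v] = dwi.signal[..., v]
        else:
            signal[..., v] = np.maximum(
                resample_moved(dwi.signal[..., v], tr, vs), 0.0
            )
    true_motion = [
        {"translation_mm": t.translation.tolist(), "rotation_deg": t.rotation_deg.tolist()}
        for t in transforms
    ]
    return dwi.copy_with(signal=signal, meta_update={"true_motion": true_motion})


def build_study_phantom(
    artifact_attenuation: float = 0.1,
    with_artifact: bool = True,
    sigma_pre: float = 5.0,
    sigma_post: float = 40.0,
) -> Phantom:
    """The default 24³ study phantom with three tracts and twelve ROIs.

    Three bundles stand in for the three pathways the pipeline compares:
    ``ns`` (straight, along x), ``drt`` (along y, bisected by the artifact
    sphere in the post session) and ``hd`` (along y at a different depth).
    The tracts do not cross each other: with stick choice proportional to f
    at every step, a crossing acts as a strong stochastic attrition zone,
    which would confound the artifact dose-response the phantom is built to
    exhibit (crossing-fiber geometry is still available through custom
    :class:`PhantomSpec` bundles).  Seed/target ROI balls sit at the bundle
    ends; six distractor gray-matter ROIs (one overlapping the artifact)
    populate the cohort statistics.
    """
    bundles = [
        Bundle(waypoints=[(4, 8, 12), (19, 8, 12)], radius=1.6, f=0.45),
        Bundle(waypoints=[(12, 4, 8), (12, 19, 8)], radius=1.6, f=0.45),
        Bundle(waypoints=[(12, 4, 16), (12, 19, 16)], radius=1.6, f=0.45),
    ]
    shape = (24, 24, 24)
    roi_defs = {
        "ns_seed": 1, "ns_target": 2,
        "drt_seed": 3, "drt_target": 4,
        "hd_seed": 5, "hd_target": 6,
        "periartifact": 7, "parietal_l": 8, "parietal_r": 9,
        "occipital": 10, "vertex": 11, "temporal": 12,
    }
    roi_centers = {
        "ns_seed": (4.5, 8, 12), "ns_target": (18.5, 8, 12),
        "drt_seed": (12, 4.5, 8), "drt_target": (12, 18.5, 8),
        "hd_seed": (12, 4.5, 16), "hd_target": (12, 18.5, 16),
        "periartifact": (15, 12, 8), "parietal_l": (6, 16, 16),
        "parietal_r": (18, 16, 16), "occipital": (6, 16, 6),
        "vertex": (12, 12, 12), "temporal": (17, 6, 8),
    }
    labels = np.zeros(shape, dtype=np.int16)
    for name, center in roi_centers.items():
        m = ball_mask(shape, center, 2.0)
        if np.any(labels[m] != 0):
            clash = sorted(set(labels[m][labels[m] != 0].tolist()))
            raise ValueError(f"ROI '{name}' overlaps labels {clash}")
        labels[m] = roi_defs[name]
    artifact = (
        ArtifactSpec(center=(12, 11.5, 8), radius=3.0, attenuation=artifact_attenuation)
        if with_artifact
        else None
    )
    spec = PhantomSpec(
        shape=shape,
        bundles=bundles,
        roi_labels=labels,
        roi_defs=roi_defs,
        seed_rois=["ns_seed", "drt_seed", "hd_seed"],
        target_rois=["ns_target", "drt_target", "hd_target"],
        artifact=artifact,
        csf_center=(7.0, 11.5, 10.0),
        sigma_pre=sigma_pre,
        sigma_post=sigma_post,
    )
    return make_phantom(spec)
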