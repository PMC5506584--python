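"""Two-group synthetic resting-state cohorts with controllable group effects.

The generator emulates the kind of data the classification pipeline consumes:
per-subject 4-D voxel time series on a mirror-symmetric grid with an integer
atlas label volume, six motion-parameter traces, and WM/CSF nuisance
ensembles.  Each ROI carries one latent band-limited (0.01-0.1 Hz) signal;
voxel series are loading * latent + white noise.  Group effects are injected
into the +1 group only, each targeting exactly one downstream feature type:

* ``ALFF``   — scales the latent-signal amplitude of a ROI.
* ``ReHo``   — shrinks within-ROI voxel noise, raising local synchrony.
* ``VMHC``   — raises the latent coupling between a ROI and its mirror twin.
* ``TC``     — injects a shared latent into both ROIs of a pair.
* ``GC``     — adds a one-lag dependence of the pair's second ROI on the first.
* seed names — raise coupling between a seed network's latent and a target ROI.

Homotopy is mirror symmetry along the first grid axis (the stand-in for the
inter-hemispheric x-flip).  Motion traces are smooth random walks plus
Bernoulli step excursions whose frame-to-frame Euclidean norm exceeds the
0.35 censoring threshold, so the censoring rule has work to do.  WM/CSF
ensembles share a few low-frequency confound signals that are also mixed
weakly into the voxel data, making nuisance regression testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "SubjectData",
    "generate_cohort",
    "mirror_index",
    "build_atlas",
    "homotopic_partner",
    "default_seed_map",
    "SEED_NETWORK_NAMES",
]

#: Canonical seed-network names (analogues of the five large-scale networks
#: commonly probed with bilateral spherical seeds).
SEED_NETWORK_NAMES = ("DMN", "ECN", "SN", "LN", "StrN")

#: Fraction of a ROI latent shared with its homotopic twin in the absence of
#: any VMHC effect.
_BASE_HOMOTOPIC_SHARE = 0.3

#: Amplitude with which the shared confound signals leak into brain voxels.
_CONFOUND_LEAK = 0.15


class ConfigurationError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class EffectSpec:
    """One group-level effect, applied to group +1 subjects only.

    Parameters
    ----------
    feature_type:
        Tag of the feature the effect targets: ``ALFF``, ``ReHo``, ``VMHC``,
        ``FCS``, ``TC``, ``GC`` or a seed-network name.
    target:
        A single ROI label for local/seed effects, an (i, j) ROI pair for
        ``TC`` and an ordered (source, sink) pair for ``GC``.
    effect_size:
        Magnitude of the manipulation; multiplicative for ALFF/ReHo,
        a mixing/coupling increment for the connectivity effects.
    """

    feature_type: str
    target: int | tuple[int, int]
    effect_size: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect_size):
            raise ConfigurationError("effect_size must be finite")
        pairwise = self.feature_type in ("TC", "GC")
        if pairwise and not isinstance(self.target, tuple):
            raise ConfigurationError(
                f"{self.feature_type} effect requires an ROI pair target")
        if not pairwise and isinstance(self.target, tuple):
            raise ConfigurationError(
                f"{self.feature_type} effect requires a single ROI target")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a balanced two-group synthetic cohort."""

    n_per_group: int = 20
    grid_shape: tuple[int, int, int] = (8, 12, 8)
    n_rois: int = 12
    n_timepoints: int = 120
    tr_seconds: float = 2.0
    effects: tuple[EffectSpec, ...] = ()
    noise_sd: float = 1.0
    motion_spike_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] % 2 != 0:
            raise ConfigurationError("first grid axis must be even")
        if self.n_rois % 2 != 0:
            raise ConfigurationError(
                "n_rois must be even (homotopic pairing is an involution)")
        if self.n_per_group < 1 or self.n_timepoints < 8:
            raise ConfigurationError("cohort too small")
        object.__setattr__(self, "effects", tuple(self.effects))
        atlas = build_atlas(self.grid_shape, self.n_rois)
        for eff in self.effects:
            rois = eff.target if isinstance(eff.target, tuple) else (eff.target,)
            for r in rois:
                if not (1 <= r <= self.n_rois):
                    raise ConfigurationError(
                        f"effect targets nonexistent ROI {r}")
        del atlas


@dataclass
class SubjectData:
    """One subject's raw data as produced by the generator."""

    subject_id: str
    label: int  # y in {-1, +1}
    voxels: np.ndarray  # X x Y x Z x T
    atlas: np.ndarray  # X x Y x Z integer labels, 0 = non-brain
    motion: np.ndarray  # 6 x T
    wm_ensemble: np.ndarray  # k_w x T
    csf_ensemble: np.ndarray  # k_c x T


def mirror_index(
    voxel_coord: Sequence[int], grid_shape: Sequence[int]
) -> tuple[int, ...]:
    """Reflect a voxel coordinate across the mid-plane of the first axis.

    ``x -> X - 1 - x``; an involution.  Other axes are untouched.
    """
    coord = tuple(int(c) for c in voxel_coord)
    for c, n in zip(coord, grid_shape):
        if not (0 <= c < n):
            raise IndexError(f"coordinate {coord} outside grid {tuple(grid_shape)}")
    return (grid_shape[0] - 1 - coord[0],) + coord[1:]


def homotopic_partner(roi: int, n_rois: int) -> int:
    """Label of the mirror twin of ``roi`` (labels 1..n_rois)."""
    half = n_rois // 2
    return roi + half if roi <= half else roi - half


def build_atlas(grid_shape: tuple[int, int, int], n_rois: int) -> np.ndarray:
    """Lay out ``n_rois`` mirror-paired 3x3x3 ROI blocks on the grid.

    ROIs 1..R/2 are placed in the x < X/2 half on a stride-4 lattice
    (leaving non-brain gaps); ROIs R/2+1..R are their x-mirrored twins.
    Every ROI has 27 voxels, so a full 26-neighbourhood exists.
    """
    X, Y, Z = grid_shape
    half = n_rois // 2
    origins = [
        (x0, y0, z0)
        for x0 in range(0, X // 2 - 2, 4)
        for y0 in range(0, Y - 2, 4)
        for z0 in range(0, Z - 2, 4)
    ]
    if len(origins) < half:
        raise ConfigurationError(
            f"grid {grid_shape} too small for {n_rois} ROIs "
            f"({len(origins)} block sites per hemisphere)")
    atlas = np.zeros(grid_shape, dtype=np.int32)
    for k, (x0, y0, z0) in enumerate(origins[:half], start=1):
        atlas[x0:x0 + 3, y0:y0 + 3, z0:z0 + 3] = k
        atlas[X - x0 - 3:X - x0, y0:y0 + 3, z0:z0 + 3] = k + half
    return atlas


def default_seed_map(n_rois: int) -> dict[str, tuple[int, int]]:
    """Assign each seed-network name a bilateral (homotopic) ROI pair.

    Networks are mapped to homotopic pairs in order, cycling if the atlas
    has fewer pairs than networks.
    """
    half = n_rois // 2
    return {
        name: ((i % half) + 1, (i % half) + 1 + half)
        for i, name in enumerate(SEED_NETWORK_NAMES)
    }


def _bandlimited(
    rng: np.random.Generator, n: int, t: int, tr: float,
    band: tuple[float, float] = (0.01, 0.1),
) -> np.ndarray:
    """n unit-variance signals with spectral support restricted to ``band``."""
    freqs = np.fft.rfftfreq(t, tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():  # degenerate short series: keep lowest non-DC bin
        keep = np.zeros_like(freqs, dtype=bool)
        keep[1] = True
    coef = np.zeros((n, freqs.size), dtype=complex)
    nk = int(keep.sum())
    coef[:, keep] = rng.standard_normal((n, nk)) + 1j * rng.standard_normal((n, nk))
    sig = np.fft.irfft(coef, n=t, axis=1)
    sig -= sig.mean(axis=1, keepdims=True)
    sd = sig.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return sig / sd


def _restandardize(u: np.ndarray) -> np.ndarray:
    u = u - u.mean()
    sd = u.std()
    return u / sd if sd > 0 else u


def _subject_latents(
    rng: np.random.Generator, spec: CohortSpec, in_effect_group: bool,
    seed_map: dict[str, tuple[int, int]],
) -> np.ndarray:
    """Per-ROI latent signals (R x T) with all group effects applied."""
    R, T, tr = spec.n_rois, spec.n_timepoints, spec.tr_seconds
    half = R // 2

    pair_latents = _bandlimited(rng, half, T, tr)
    own = _bandlimited(rng, R, T, tr)

    share = np.full(half, _BASE_HOMOTOPIC_SHARE)
    if in_effect_group:
        for eff in spec.effects:
            if eff.feature_type == "VMHC":
                p = (eff.target - 1) % half
                share[p] = float(np.clip(share[p] + eff.effect_size, 0.0, 0.99))

    u = np.empty((R, T))
    for r in range(R):
        p = r % half
        u[r] = np.sqrt(share[p]) * pair_latents[p] + np.sqrt(1 - share[p]) * own[r]

    # Connectivity effects mix extra structure into the latents (group +1 only).
    if in_effect_group:
        for eff in spec.effects:
            e = eff.effect_size
            if eff.feature_type == "TC":
                i, j = eff.target
                shared = _bandlimited(rng, 1, T, tr)[0]
                u[i - 1] = (u[i - 1] + e * shared) / np.sqrt(1 + e * e)
                u[j - 1] = (u[j - 1] + e * shared) / np.sqrt(1 + e * e)
            elif eff.feature_type == "GC":
                i, j = eff.target
                lagged = np.concatenate(([u[i - 1, 0]], u[i - 1, :-1]))
                u[j - 1] = _restandardize(u[j - 1] + e * lagged)
            elif eff.feature_type in seed_map:
                p = (seed_map[eff.feature_type][0] - 1) % half
                t_roi = eff.target - 1
                u[t_roi] = (u[t_roi] + e * pair_latents[p]) / np.sqrt(1 + e * e)
    return u


def _motion_trace(
    rng: np.random.Generator, t: int, spike_rate: float
) -> np.ndarray:
    """Six smooth random-walk parameters plus sparse step excursions."""
    steps = rng.normal(0.0, 0.02, size=(6, t))
    steps[:, 0] = 0.0
    motion = np.cumsum(steps, axis=1)
    spikes = rng.random(t) < spike_rate
    spikes[0] = False
    for frame in np.nonzero(spikes)[0]:
        param = rng.integers(0, 6)
        motion[param, frame:] += rng.choice([-1.0, 1.0]) * 0.5
    return motion


def generate_cohort(spec: CohortSpec) -> list[SubjectData]:
    """Generate a balanced cohort of ``2 * n_per_group`` subjects.

    Deterministic given ``spec.seed``.  Subjects 0..n-1 carry label -1
    (control analogue), subjects n..2n-1 label +1 (the effect group).
    """
    rng = np.random.default_rng(spec.seed)
    atlas = build_atlas(spec.grid_shape, spec.n_rois)
    seed_map = default_seed_map(spec.n_rois)
    X, Y, Z = spec.grid_shape
    T, tr, R = spec.n_timepoints, spec.tr_seconds, spec.n_rois
    n_vox = X * Y * Z
    flat_atlas = atlas.reshape(-1)

    amp = np.ones(R)
    voxel_noise_sd = np.full(R, spec.noise_sd)
    for eff in spec.effects:
        if eff.feature_type == "ALFF":
            amp[eff.target - 1] *= 1.0 + eff.effect_size
        elif eff.feature_type == "ReHo":
            voxel_noise_sd[eff.target - 1] /= 1.0 + eff.effect_size

    subjects: list[SubjectData] = []
    for idx in range(2 * spec.n_per_group):
        label = -1 if idx < spec.n_per_group else +1
        in_effect_group = label == +1

        latents = _subject_latents(rng, spec, in_effect_group, seed_map)
        confounds = _bandlimited(rng, 2, T, tr, band=(0.0, 0.03))

        vox = rng.normal(0.0, spec.noise_sd, size=(n_vox, T))
        for r in range(1, R + 1):
            rows = flat_atlas == r
            nr = int(rows.sum())
            a = amp[r - 1] if in_effect_group else 1.0
            sd = voxel_noise_sd[r - 1] if in_effect_group else spec.noise_sd
            loadings = rng.uniform(0.8, 1.2, size=nr)
            vox[rows] = (
                a * loadings[:, None] * latents[r - 1]
                + rng.normal(0.0, sd, size=(nr, T))
            )
        vox[flat_atlas > 0] += _CONFOUND_LEAK * confounds.sum(axis=0)

        wm = (
            rng.uniform(0.5, 1.0, size=(5, 1)) * confounds[0]
            + rng.uniform(-0.5, 0.5, size=(5, 1)) * confounds[1]
            + rng.normal(0.0, 0.3, size=(5, T))
        )
        csf = (
            rng.uniform(0.5, 1.0, size=(5, 1)) * confounds[1]
            + rng.uniform(-0.5, 0.5, size=(5, 1)) * confounds[0]
            + rng.normal(0.0, 0.3, size=(5, T))
        )
        subjects.append(
            SubjectData(
                subject_id=f"sub{idx:03d}",
                label=label,
                voxels=vox.reshape(X, Y, Z, T),
                atlas=atlas,
                motion=_motion_trace(rng, T, spec.motion_spike_rate),
                wm_ensemble=wm,
                csf_ensemble=csf,
            )
        )
    return subjects
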