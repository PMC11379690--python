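"""Window augmentations for the two pretext tasks.

Four transforms drive the multi-task (MTL) pretext: signal reversal,
segment permutation (10-sample segments), time warping, and per-axis random
scaling. Each is applied independently with probability ``p_apply`` in a
fixed order (reverse -> permute -> warp -> scale), and the 4-bit flag vector
records which were applied; the model's job is to recover those bits.

The SimCLR pretext instead draws two independent 3-D rotations of the same
window (uniform axis on the sphere, uniform angle), emulating arbitrary
sensor orientation on the wrist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import WINDOW_SAMPLES


@dataclass
class AugmentationFlags:
    reversed: int = 0
    permuted: int = 0
    time_warped: int = 0
    axis_scaled: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.reversed, self.permuted, self.time_warped,
                         self.axis_scaled], dtype=np.float32)


@dataclass
class AugmentationPolicy:
    p_apply: float = 0.5
    segment_len: int = 10
    warp_knots: int = 4
    warp_strength: float = 0.2
    scale_low: float = 0.5
    scale_high: float = 2.0
    rotation_angle_range: tuple[float, float] = (0.0, 2.0 * np.pi)

    def __post_init__(self):
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must be in [0, 1]")
        if self.scale_low <= 0 or self.scale_low > self.scale_high:
            raise ValueError("need 0 < scale_low <= scale_high")
        if WINDOW_SAMPLES % self.segment_len != 0:
            raise ValueError(f"segment_len must divide {WINDOW_SAMPLES}")
        if not 0.0 <= self.warp_strength < 1.0:
            raise ValueError("warp_strength must be in [0, 1)")


def _check_window(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w)
    if w.dtype != np.float64:  # float32 by default, float64 preserved
        w = w.astype(np.float32)
    if w.shape != (3, WINDOW_SAMPLES):
        raise ValueError(f"expected a (3, {WINDOW_SAMPLES}) window")
    return w


def reverse(w: np.ndarray) -> np.ndarray:
    return _check_window(w)[:, ::-1].copy()


def permute_segments(w: np.ndarray, policy: AugmentationPolicy,
                     rng: np.random.Generator) -> np.ndarray:
    """Shuffle fixed-length segments; the same permutation on all three axes."""
    w = _check_window(w)
    seg = policy.segment_len
    n_seg = WINDOW_SAMPLES // seg
    perm = rng.permutation(n_seg)
    return w.reshape(3, n_seg, seg)[:, perm].reshape(3, WINDOW_SAMPLES)


def _warp_time_map(policy: AugmentationPolicy, rng: np.random.Generator,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Strictly increasing piecewise-linear map of [0,1] onto itself.

    Interval lengths between ``warp_knots`` interior knots are perturbed
    multiplicatively by at most ``warp_strength`` and renormalized, so the
    endpoints stay fixed and monotonicity is guaranteed.
    """
    k = policy.warp_knots
    anchors = np.linspace(0.0, 1.0, k + 2)
    intervals = np.diff(anchors)
    factors = 1.0 + policy.warp_strength * rng.uniform(-1.0, 1.0, size=k + 1)
    warped = intervals * factors
    warped /= warped.sum()
    return anchors, np.concatenate([[0.0], np.cumsum(warped)])


def time_warp(w: np.ndarray, policy: AugmentationPolicy,
              rng: np.random.Generator) -> np.ndarray:
    w = _check_window(w)
    anchors, warped = _warp_time_map(policy, rng)
    t_out = np.linspace(0.0, 1.0, WINDOW_SAMPLES)
    # source position for each output sample: inverse of the (monotone) map
    t_src = np.interp(t_out, warped, anchors)
    idx = t_src * (WINDOW_SAMPLES - 1)
    return np.stack([np.interp(idx, np.arange(WINDOW_SAMPLES), w[a])
                     for a in range(3)]).astype(w.dtype)


def axis_scale(w: np.ndarray, policy: AugmentationPolicy,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    w = _check_window(w)
    factors = rng.uniform(policy.scale_low, policy.scale_high, size=3)
    return (w * factors[:, None].astype(w.dtype), factors.astype(w.dtype))


def apply_mtl(w: np.ndarray, policy: AugmentationPolicy,
              rng: np.random.Generator) -> tuple[np.ndarray, AugmentationFlags]:
    """Apply each augmentation with probability ``p_apply``, in fixed order.

    Flags record *application*, not visible change (e.g. reversing a
    palindromic window still sets the bit).
    """
    w = _check_window(w)
    apply = rng.uniform(size=4) < policy.p_apply
    flags = AugmentationFlags(*(int(b) for b in apply))
    if flags.reversed:
        w = reverse(w)
    if flags.permuted:
        w = permute_segments(w, policy, rng)
    if flags.time_warped:
        w = time_warp(w, policy, rng)
    if flags.axis_scaled:
        w, _ = axis_scale(w, policy, rng)
    return w, flags


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def random_rotation(w: np.ndarray, policy: AugmentationPolicy,
                    rng: np.random.Generator) -> np.ndarray:
    """One random 3-D rotation applied to every sample of the window."""
    w = _check_window(w)
    vec = rng.normal(size=3)
    while np.linalg.norm(vec) < 1e-12:  # pragma: no cover - measure zero
        vec = rng.normal(size=3)
    angle = rng.uniform(*policy.rotation_angle_range)
    R = rotation_matrix(vec, angle)
    return (R.astype(w.dtype) @ w).astype(w.dtype)


def simclr_views(w: np.ndarray, policy: AugmentationPolicy,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two independent rotated views of the same window (positives)."""
    return (random_rotation(w, policy, rng), random_rotation(w, policy, rng))
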