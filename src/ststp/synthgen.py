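"""Synthetic labelled subjects: rendered clips plus ground-truth landmarks.

Each subject is a deliberately cartoonish talking head on a textured
(trackable) background: elliptical eyes whose contour collapses vertically
during blink frames, eyebrow arcs that bob with a per-subject amplitude,
an optional hand blob with 21 joint markers (palm centre dropped from the
landmark stream), and a global random-walk body translation.  The landmark
stream is the exact render geometry, so every downstream detector can be
scored against ground truth.

Class structure mirrors a two-class (LIE / TRUTH) interview corpus in which
blink rate is the strongest involuntary cue, followed by body motion and
eyebrow activity, with hand motion weakest; the per-cue effect deltas below
encode that ordering.  ``effect = 0`` makes the two classes statistically
identical; ``effect = 1`` applies the full documented deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .io_formats import (LandmarkStream, VideoClip, N_HAND_JOINTS)

LABELS = ("TRUTH", "LIE")

#: per-cue LIE-minus-TRUTH deltas at effect = 1, ordered strongest to
#: weakest: blink (blinks/min), body (px/frame), eyebrow (px), hand (px)
EFFECT_DELTAS = {
    "blink_rate": 18.0,
    "body_motion_amplitude": 0.8,
    "eyebrow_amplitude": 0.5,
    "hand_motion_amplitude": 0.2,
}

#: TRUTH-class cue means and between-subject standard deviations
TRUTH_CUE_MEANS = {
    "blink_rate": 20.0,
    "body_motion_amplitude": 0.8,
    "eyebrow_amplitude": 0.5,
    "hand_motion_amplitude": 0.3,
}
CUE_SDS = {
    "blink_rate": 5.0,
    "body_motion_amplitude": 0.25,
    "eyebrow_amplitude": 0.2,
    "hand_motion_amplitude": 0.1,
}

#: females express every cue slightly more strongly in this simulator
FEMALE_CUE_FACTOR = 1.1


class ConfigurationError(ValueError):
    pass


@dataclass
class ScenarioConfig:
    """Generation parameters for a single synthetic subject."""

    label: str = "TRUTH"
    blink_rate: float = 20.0          # blinks / minute
    blink_duration: int = 3           # frames per closure
    eyebrow_amplitude: float = 0.5    # px, brow bob amplitude
    hand_motion_amplitude: float = 0.3  # px / frame, hand jiggle
    body_motion_amplitude: float = 0.8  # px / frame, global translation
    has_hands: bool = True
    n_hands: int = 1
    n_frames: int = 200
    fps: float = 25.0
    frame_size: tuple[int, int] = (64, 64)
    noise_sd: float = 2.0             # pixel-intensity units
    gender: str = "F"
    seed: int = 0

    def validate(self) -> None:
        if self.label not in LABELS:
            raise ConfigurationError(f"label must be in {LABELS}")
        if min(self.blink_rate, self.eyebrow_amplitude,
               self.hand_motion_amplitude, self.body_motion_amplitude) < 0:
            raise ConfigurationError("rates and amplitudes must be >= 0")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if min(self.frame_size) < 32:
            raise ConfigurationError(
                f"frame_size {self.frame_size} too small to place a face "
                "(need at least 32 px each way)")
        if self.has_hands and self.n_hands not in (1, 2):
            raise ConfigurationError("n_hands must be 1 or 2 when hands present")


@dataclass
class SyntheticSubject:
    """A rendered clip, its exact landmark stream, and the ground truth."""

    clip: VideoClip
    landmarks: LandmarkStream
    truth: dict
    label: str
    gender: str = "F"
    config: ScenarioConfig | None = None


# ---------------------------------------------------------------------------
# drawing primitives (float image, intensity 0..255, dark marks subtract)
# ---------------------------------------------------------------------------

def _grids(shape):
    return np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")


def _draw_ellipse(img, rr, cc, cy, cx, ry, rx, value):
    # rr, cc retained in the signature for clarity; drawing is clipped to
    # the primitive's bounding box for speed
    if ry <= 0 or rx <= 0:
        return
    h, w = img.shape
    r0 = max(int(np.floor(cy - ry)), 0)
    r1 = min(int(np.ceil(cy + ry)) + 1, h)
    c0 = max(int(np.floor(cx - rx)), 0)
    c1 = min(int(np.ceil(cx + rx)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    sub_r = np.arange(r0, r1)[:, None]
    sub_c = np.arange(c0, c1)[None, :]
    mask = ((sub_r - cy) / ry) ** 2 + ((sub_c - cx) / rx) ** 2 <= 1.0
    img[r0:r1, c0:c1][mask] = value


def _draw_disc(img, rr, cc, cy, cx, radius, value):
    if radius <= 1.2:
        _stamp(img, cy, cx, value)
    else:
        _draw_ellipse(img, rr, cc, cy, cx, radius, radius, value)


def _stamp(img, cy, cx, value):
    """Cheap ~2x2 px mark for sub-pixel-radius primitives."""
    h, w = img.shape
    r0 = min(max(int(round(cy - 0.5)), 0), h - 1)
    c0 = min(max(int(round(cx - 0.5)), 0), w - 1)
    img[r0:r0 + 2, c0:c0 + 2] = value


def _draw_polyline(img, rr, cc, points, value, thickness=0.9):
    pts = np.asarray(points, dtype=float)
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        n = max(int(np.hypot(*seg)) + 1, 2)
        ts = np.arange(n + 1) / n
        for t in ts:
            p = a + seg * t
            _draw_disc(img, rr, cc, p[0], p[1], thickness, value)


#: relative joint layout of one synthetic hand (unit scale, row/col);
#: the palm centre (extracted 21st point) is the origin and is dropped
_HAND_TEMPLATE = None


def _hand_template() -> np.ndarray:
    global _HAND_TEMPLATE
    if _HAND_TEMPLATE is None:
        rng = np.random.default_rng(1234)  # fixed anatomical template
        joints = [np.array([1.0, 0.0])]    # wrist below palm centre
        finger_cols = np.linspace(-0.9, 0.9, 5)
        finger_len = (3, 4, 4, 4, 4)       # thumb has one fewer joint
        for col, n in zip(finger_cols, finger_len):
            for k in range(1, n + 1):
                joints.append(np.array([-0.35 * k, col * (1 + 0.08 * k)]))
        tpl = np.stack(joints)
        tpl += rng.normal(0, 0.02, tpl.shape)  # break exact symmetry
        _HAND_TEMPLATE = tpl
    return _HAND_TEMPLATE


# ---------------------------------------------------------------------------
# subject generation
# ---------------------------------------------------------------------------

def generate_subject(config: ScenarioConfig) -> SyntheticSubject:
    """Render one subject deterministically from its config and seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    H, W = config.frame_size
    T = config.n_frames

    # --- temporal ground truth -------------------------------------------
    p_blink = config.blink_rate / (60.0 * config.fps)
    starts = rng.random(T) < p_blink
    closed = np.zeros(T, dtype=bool)
    for t in np.flatnonzero(starts):
        closed[t:t + config.blink_duration] = True
    blink_events = _runs(closed)

    # mean-reverting (OU) posture sway: per-frame innovations have the
    # documented amplitude, while reversion keeps the face in frame
    body = _ou_walk(rng, T, config.body_motion_amplitude, reversion=0.15)
    body_disp = np.diff(body, axis=0)

    brow_bob = config.eyebrow_amplitude * _smooth_noise(rng, T, 8)

    hand_walk = _ou_walk(rng, T, config.hand_motion_amplitude, reversion=0.2)

    # --- static geometry --------------------------------------------------
    s = min(H, W)
    eye_a = 0.080 * s                       # eye half-width
    eye_b_open = 0.6 * eye_a                # open half-height
    eye_y, eye_xl, eye_xr = 0.38 * H, 0.34 * W, 0.66 * W
    brow_y = eye_y - 0.14 * s
    brow_xs = np.linspace(0.30 * W, 0.70 * W, 3)
    hand_centres = [np.array([0.82 * H, 0.30 * W]),
                    np.array([0.82 * H, 0.70 * W])][: config.n_hands]
    hand_scale = 0.045 * s
    tpl = _hand_template() * hand_scale

    # textured background, larger than the frame so translation never wraps
    pad = int(np.ceil(np.abs(body).max())) + 2
    bg = ndimage.gaussian_filter(
        rng.normal(size=(H + 2 * pad, W + 2 * pad)), 1.2)
    bg = 120 + 55 * bg / max(np.abs(bg).max(), 1e-9)

    rr, cc = _grids((H, W))
    frames = np.empty((T, H, W, 3), dtype=np.uint8)
    left_eye = np.zeros((T, 6, 2))
    right_eye = np.zeros((T, 6, 2))
    brows = np.zeros((T, 3, 2))
    hands = np.zeros((T, 2, N_HAND_JOINTS, 2))

    # shift the background for every frame in one interpolation call
    all_rows = rr[None, :, :] + pad - body[:, 0, None, None]
    all_cols = cc[None, :, :] + pad - body[:, 1, None, None]
    shifted_bg = ndimage.map_coordinates(
        bg, [all_rows.ravel(), all_cols.ravel()], order=1,
        mode="nearest").reshape(T, H, W)

    for t in range(T):
        dy, dx = body[t]
        img = shifted_bg[t]

        # face disc
        _draw_ellipse(img, rr, cc, 0.45 * H + dy, 0.50 * W + dx,
                      0.34 * H, 0.30 * W, 180.0)

        b_t = eye_b_open * (0.08 if closed[t] else 1.0)
        for side, ex in (("L", eye_xl), ("R", eye_xr)):
            cy, cx = eye_y + dy, ex + dx
            _draw_ellipse(img, rr, cc, cy, cx, max(b_t, 0.8), eye_a, 235.0)
            if not closed[t]:
                _draw_disc(img, rr, cc, cy, cx, 0.45 * eye_a, 30.0)  # iris
            lm = _eye_landmarks(cy, cx, eye_a, b_t)
            if side == "L":
                left_eye[t] = lm
            else:
                right_eye[t] = lm

        bob = brow_bob[t]
        brow_pts = np.stack([
            np.full(3, brow_y) + dy - bob - np.array([0.0, 0.02 * s, 0.0]),
            brow_xs + dx,
        ], axis=1)
        _draw_polyline(img, rr, cc, brow_pts, 60.0)
        brows[t] = brow_pts

        if config.has_hands:
            jiggle = rng.normal(0, 0.15, size=(N_HAND_JOINTS, 2))
            for h, centre in enumerate(hand_centres):
                c = centre + body[t] + hand_walk[t]
                joints = c + tpl + jiggle
                _draw_disc(img, rr, cc, c[0] - 0.5 * hand_scale, c[1],
                           2.2 * hand_scale, 200.0)  # palm blob
                for j in joints:
                    _draw_disc(img, rr, cc, j[0], j[1], 0.8, 45.0)
                hands[t, h] = joints

        img += rng.normal(0, config.noise_sd, size=img.shape)
        frames[t] = np.clip(img, 0, 255).astype(np.uint8)[..., None]

    clip = VideoClip(frames=frames, fps=config.fps,
                     clip_id=f"{config.label.lower()}_{config.seed}")
    stream = LandmarkStream(
        left_eye=left_eye, right_eye=right_eye, brows=brows, hands=hands,
        has_eyes=True, has_hands=config.has_hands, clip_id=clip.clip_id)
    truth = {
        "blink_events": blink_events,
        "blink_count": len(blink_events),
        "closed": closed,
        "body_displacements": body_disp,
        "hand_walk": hand_walk,
    }
    return SyntheticSubject(clip=clip, landmarks=stream, truth=truth,
                            label=config.label, gender=config.gender,
                            config=config)


def _eye_landmarks(cy, cx, a, b):
    """Six contour points l1..l6 of an eye ellipse, (row, col) order
    converted to (x, y) = (col, row) pixel coordinates."""
    h = 0.8660254037844386 * b  # sin(60 deg) height at half-width
    pts_rc = np.array([
        [cy, cx - a],          # l1 outer corner
        [cy - h, cx - a / 2],  # l2 upper lid
        [cy - h, cx + a / 2],  # l3 upper lid
        [cy, cx + a],          # l4 inner corner
        [cy + h, cx + a / 2],  # l5 lower lid
        [cy + h, cx - a / 2],  # l6 lower lid
    ])
    return pts_rc[:, ::-1]  # (x, y)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) spans of True runs."""
    out = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(mask) - 1))
    return out


def _ou_walk(rng, n, amplitude, reversion):
    """2-D mean-reverting random walk starting at the origin."""
    steps = rng.normal(0.0, amplitude, size=(n - 1, 2))
    walk = np.zeros((n, 2))
    for t in range(1, n):
        walk[t] = (1 - reversion) * walk[t - 1] + steps[t - 1]
    return walk


def _smooth_noise(rng, n, scale):
    x = rng.normal(size=n)
    x = ndimage.gaussian_filter1d(x, scale, mode="nearest")
    sd = x.std()
    return x / sd if sd > 0 else x


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def sample_config(label: str, effect: float, rng: np.random.Generator,
                  base: ScenarioConfig | None = None,
                  cue_deltas: dict | None = None) -> ScenarioConfig:
    """Draw one subject's cue parameters for its class at a given effect.

    ``cue_deltas`` overrides the documented per-cue class deltas (e.g. a
    blink-only contrast for ablation studies); unnamed cues get delta 0.
    """
    base = base or ScenarioConfig()
    deltas = EFFECT_DELTAS if cue_deltas is None else cue_deltas
    shift = 1.0 if label == "LIE" else 0.0
    gender = "F" if rng.random() < 0.5 else "M"
    gfac = FEMALE_CUE_FACTOR if gender == "F" else 1.0
    cues = {}
    for cue, mean in TRUTH_CUE_MEANS.items():
        loc = (mean + shift * effect * deltas.get(cue, 0.0)) * gfac
        cues[cue] = max(float(rng.normal(loc, CUE_SDS[cue])), 0.0)
    has_hands = rng.random() < 0.8
    n_hands = int(rng.integers(1, 3)) if has_hands else 1
    return replace(
        base, label=label, gender=gender, has_hands=has_hands,
        n_hands=n_hands, seed=int(rng.integers(0, 2**31 - 1)), **cues)


def generate_cohort(n_per_class: int, effect: float, seed: int = 0,
                    base: ScenarioConfig | None = None,
                    cue_deltas: dict | None = None,
                    configs_only: bool = False):
    """Generate a balanced labelled cohort of synthetic subjects.

    ``effect`` in [0, 1] scales the documented per-cue class deltas;
    ``effect = 0`` makes LIE and TRUTH parameter distributions identical.
    Each subject is independently seeded from the master seed.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    if not 0.0 <= effect <= 1.0:
        raise ConfigurationError("effect must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    configs = []
    for label in ("TRUTH", "LIE"):
        for _ in range(n_per_class):
            configs.append(sample_config(label, effect, rng, base, cue_deltas))
    if configs_only:
        return configs
    return [generate_subject(c) for c in configs]
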