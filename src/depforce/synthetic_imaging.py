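"""Synthetic bead time-lapse stacks with known ground-truth rupture times.

Renders beads as flat-topped smooth disks arranged on electrode centerlines
(matching the chip layout: 40 um electrodes on a 50 um centerline pitch).
Each bead holds its pre-rupture gray level until its true rupture frame, then
switches to the post-rupture level; Gaussian read noise is added on top.
Optical realism (defocus PSF, illumination gradients, shot noise) is
deliberately out of scope -- only the intensity-change event matters to the
detection pipeline, and the ground truth written alongside each stack is
sufficient to score every downstream stage without external data.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from depforce.event_detection import ROI, assign_rupture_force, detect_rupture, trace_from_stack
from depforce.ramp_control import RampSchedule
from depforce.rupture_model import BellParameters, sample_rupture_forces

__all__ = [
    "SceneSpec",
    "ImageStack",
    "render_stack",
    "make_benchmark_set",
    "score_benchmark",
    "write_stack",
    "centerline_positions",
]


@dataclass
class SceneSpec:
    """Everything needed to render a deterministic synthetic stack."""

    image_size: tuple = (256, 256)        # (height, width) px
    pixel_pitch: float = 1.0              # um per px
    bead_positions: list = field(default_factory=list)  # [(cx, cy)] px
    bead_radius_px: float = 7.5
    pre_level: float = 100.0
    post_level: float = 160.0
    background: float = 30.0
    noise_sd: float = 5.0                 # gray levels
    capture_rate: float = 100.0           # frames/s
    n_frames: int = 100
    true_rupture_frames: list | None = None  # frame index or None per bead
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        top = 2 ** self.bit_depth - 1
        for lv in (self.pre_level, self.post_level, self.background):
            if not 0 <= lv <= top:
                raise ValueError(f"gray level {lv} outside [0, {top}]")
        h, w = self.image_size
        for (cx, cy) in self.bead_positions:
            if not (0 <= cx < w and 0 <= cy < h):
                raise ValueError(f"bead position ({cx}, {cy}) outside the frame")

    @property
    def rois(self) -> list:
        return [ROI(cx, cy, self.bead_radius_px) for (cx, cy) in self.bead_positions]


@dataclass
class ImageStack:
    """Rendered grayscale stack plus the spec that generated it."""

    frames: np.ndarray       # (T, H, W)
    bit_depth: int
    metadata: SceneSpec

    def __post_init__(self) -> None:
        if self.frames.shape[0] != self.metadata.n_frames:
            raise ValueError("frame count does not match the spec")


def centerline_positions(n_beads: int, image_size=(256, 256),
                         pixel_pitch: float = 1.0, centerline_pitch_um: float = 50.0,
                         margin_px: float = 12.0) -> list:
    """Bead positions along vertical electrode centerlines.

    Centerlines run every ``centerline_pitch_um`` (the chip's electrode
    pitch); beads are spread evenly down each line, skipping a margin so ROIs
    stay inside the frame.
    """
    h, w = image_size
    pitch_px = centerline_pitch_um / pixel_pitch
    xs = np.arange(pitch_px / 2, w - margin_px, pitch_px)
    if xs.size == 0:
        raise ValueError("image too narrow for one centerline")
    per_line = math.ceil(n_beads / xs.size)
    ys = np.linspace(margin_px, h - margin_px, per_line)
    positions = [(float(x), float(y)) for x in xs for y in ys]
    return positions[:n_beads]


def render_stack(spec: SceneSpec) -> ImageStack:
    """Render the stack described by *spec*; bit-identical for a given seed."""
    h, w = spec.image_size
    t = spec.n_frames
    rupt = spec.true_rupture_frames
    if rupt is None:
        rupt = [None] * len(spec.bead_positions)
    if len(rupt) != len(spec.bead_positions):
        raise ValueError("true_rupture_frames must match bead_positions")

    yy, xx = np.mgrid[:h, :w].astype(float)
    overlap = np.zeros((h, w))
    weights = []
    r0, edge = spec.bead_radius_px, 1.0
    for (cx, cy) in spec.bead_positions:
        d = np.hypot(xx - cx, yy - cy)
        wgt = np.clip((r0 + edge / 2 - d) / edge, 0.0, 1.0)  # flat top, 1 px soft edge
        weights.append(wgt)
        overlap += wgt > 0
    if np.any(overlap > 1):
        warnings.warn("overlapping beads in the scene; rendering anyway",
                      RuntimeWarning, stacklevel=2)

    base = np.full((h, w), spec.background, dtype=np.float32)
    for wgt in weights:
        base += (spec.pre_level - spec.background) * wgt.astype(np.float32)

    frames = np.empty((t, h, w), dtype=np.float32)
    current = base.copy()
    by_frame = {}
    for b, rf in enumerate(rupt):
        if rf is not None:
            by_frame.setdefault(int(rf), []).append(b)
    for f in range(t):
        for b in by_frame.get(f, ()):
            current += (spec.post_level - spec.pre_level) * weights[b].astype(np.float32)
        frames[f] = current

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape).astype(np.float32)

    top = 2 ** spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16
    out = np.clip(np.rint(frames), 0, top).astype(dtype)
    return ImageStack(frames=out, bit_depth=spec.bit_depth, metadata=spec)


def make_benchmark_set(schedule: RampSchedule, params: BellParameters,
                       n_beads: int = 100, noise_sd: float = 5.0, seed=0,
                       frames_per_step: int = 2, image_size=(512, 512),
                       post_roll: int = 10):
    """End-to-end benchmark: rupture times -> rendered stack -> truth table.

    Samples per-bead rupture times from the Bell model under the schedule,
    renders a stack at a capture rate synchronized to the staircase
    (``frames_per_step`` frames per voltage update), and returns
    ``(ImageStack, truth DataFrame, capture_rate)``.  A rupture at time t
    first appears in frame ``ceil(t * fps)`` (the first frame whose start
    time is at or after t); censored beads never change level.
    """
    fps = frames_per_step * schedule.n_steps / schedule.duration
    n_frames = int(math.ceil(schedule.duration * fps)) + post_roll
    ss = np.random.SeedSequence(seed if isinstance(seed, (int, np.integer)) else 0)
    s_rupture, s_render = ss.spawn(2)
    samples = sample_rupture_forces(schedule, params, n_beads, s_rupture)

    true_frames = []
    for t_r, cens in zip(samples.rupture_times, samples.censored):
        true_frames.append(None if cens else int(math.ceil(t_r * fps)))

    positions = centerline_positions(n_beads, image_size=image_size)
    spec = SceneSpec(
        image_size=image_size, bead_positions=positions,
        noise_sd=noise_sd, capture_rate=fps, n_frames=n_frames,
        true_rupture_frames=true_frames,
        seed=int(s_render.generate_state(1)[0] % (2 ** 31)),
    )
    stack = render_stack(spec)

    truth = pd.DataFrame({
        "bead": np.arange(n_beads),
        "true_time_s": samples.rupture_times,
        "true_frame": [f if f is not None else -1 for f in true_frames],
        "true_force_pN": samples.rupture_forces,
        "censored": samples.censored.astype(int),
    })
    return stack, truth, fps


def score_benchmark(stack: ImageStack, truth: pd.DataFrame,
                    schedule: RampSchedule, capture_rate: float,
                    **detect_kwargs) -> pd.DataFrame:
    """Run detection + force assignment on a benchmark stack and score it.

    Returns the truth table with detected frame/force columns and a
    ``recovered`` flag: censored beads count as recovered when no event is
    detected; ruptured beads when the assigned force is within one force step
    of the true force.
    """
    traces = trace_from_stack(stack, stack.metadata.rois, capture_rate)
    step = schedule.force_step
    rows = []
    for trace, (_, row) in zip(traces, truth.iterrows()):
        ev = detect_rupture(trace, **detect_kwargs)
        ev = assign_rupture_force(ev, schedule, capture_rate)
        if row["censored"]:
            recovered = ev.rupture_frame is None or ev.censored
        else:
            recovered = (ev.rupture_frame is not None
                         and abs(ev.force - row["true_force_pN"]) <= step + 1e-9)
        rows.append({
            **row, "detected_frame": ev.rupture_frame if ev.rupture_frame is not None else -1,
            "detected_force_pN": ev.force, "detected_censored": int(ev.censored),
            "recovered": bool(recovered),
        })
    return pd.DataFrame(rows)


def write_stack(stack: ImageStack, path, truth: pd.DataFrame | None = None,
                truth_path=None, sidecar_path=None) -> None:
    """Write a multi-page TIFF plus optional truth CSV and JSON spec sidecar."""
    import tifffile

    tifffile.imwrite(path, stack.frames)
    if truth is not None and truth_path is not None:
        truth.to_csv(truth_path, index=False)
    if sidecar_path is not None:
        spec = asdict(stack.metadata)
        spec["true_rupture_frames"] = [
            f if f is not None else -1 for f in (spec["true_rupture_frames"] or [])
        ]
        with open(sidecar_path, "w") as fh:
            json.dump(spec, fh, indent=1)
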