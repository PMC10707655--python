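"""Synthetic surgical-scene generator.

Renders small RGB frames that emulate an endoscopic view during
robot-assisted surgery at desk scale: a tissue-toned textured background,
bright elongated instrument shapes (binary segmentation targets), and
dark-red blood-accumulation blobs whose rendered area defines the per-frame
class label.  Temporal scenarios model the clinically observed pattern in
which brief, low-confidence "oozing" precursor bursts precede a sustained
bleeding phase.

Everything is deterministic given the scenario's seed: per-frame RNG streams
are spawned from ``(rng_seed, frame_index)`` so a frame can be re-rendered
in isolation and bit-identically.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "SceneScenario",
    "FrameSample",
    "DatasetManifest",
    "render_frame",
    "generate_sequence",
    "generate_training_dataset",
    "write_dataset",
    "read_manifest",
]

#: fraction of frame pixels a blood blob must cover for the frame to be
#: labelled "blood accumulation" (class 1).
MIN_BLOOD_AREA_FRACTION = 0.01


@dataclass(frozen=True)
class SceneScenario:
    """Parameters of one synthetic temporal scene.

    ``precursor_onset_s``/``bleed_onset_s`` delimit the oozing-precursor
    window and the sustained bleeding phase; either may be ``None`` for
    blood-free or precursor-free scenes.  ``blob_growth_rate`` is the area
    growth of the sustained blood pool in pixels^2 per second.
    """

    duration_s: float = 10.0
    fps: float = 25.0
    precursor_onset_s: float | None = None
    bleed_onset_s: float | None = None
    n_tools: int = 2
    blob_growth_rate: float = 30.0
    frame_size: int = 64
    background_texture_seed: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if (
            self.precursor_onset_s is not None
            and self.bleed_onset_s is not None
            and not self.precursor_onset_s < self.bleed_onset_s
        ):
            raise ValueError("precursor_onset_s must precede bleed_onset_s")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class FrameSample:
    """One rendered frame: image, instrument mask and blood class label."""

    image: np.ndarray  # H x W x 3 float in [0, 1]
    tool_mask: np.ndarray  # H x W uint8 in {0, 1}
    blood_label: int  # 0 = no blood accumulation, 1 = blood accumulation
    timestamp_s: float
    frame_index: int

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.tool_mask.shape:
            raise ValueError("image and tool_mask spatial dims differ")
        if self.blood_label not in (0, 1):
            raise ValueError("blood_label must be 0 or 1")


@dataclass
class DatasetManifest:
    """On-disk index of a rendered dataset (JSON round-trippable)."""

    fps: float
    frames: list[dict] = field(default_factory=list)
    precursor_onset_s: float | None = None
    bleed_onset_s: float | None = None
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------


def _pixel_grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:size, 0:size]
    return yy.astype(np.float64), xx.astype(np.float64)


def _background(scenario: SceneScenario) -> np.ndarray:
    """Tissue-toned background with low-frequency texture, fixed per scene."""
    rng = np.random.default_rng(
        np.random.SeedSequence([scenario.background_texture_seed, 0x7155])
    )
    s = scenario.frame_size
    base = np.array([0.72, 0.45, 0.42])  # pinkish tissue tone
    coarse = rng.normal(0.0, 1.0, (s // 8 + 2, s // 8 + 2))
    # bilinear upsample of coarse noise -> smooth mottling
    yy, xx = _pixel_grid(s)
    fy, fx = yy / 8.0, xx / 8.0
    y0, x0 = fy.astype(int), fx.astype(int)
    wy, wx = fy - y0, fx - x0
    tex = (
        coarse[y0, x0] * (1 - wy) * (1 - wx)
        + coarse[y0 + 1, x0] * wy * (1 - wx)
        + coarse[y0, x0 + 1] * (1 - wy) * wx
        + coarse[y0 + 1, x0 + 1] * wy * wx
    )
    img = base[None, None, :] + 0.06 * tex[:, :, None]
    img += np.array([0.02, -0.01, -0.01])[None, None, :] * rng.standard_normal((s, s, 1))
    return np.clip(img, 0.0, 1.0)


def _tool_mask(scenario: SceneScenario, t: float) -> np.ndarray:
    """Rotated bright capsules standing in for instrument shafts.

    Tools translate slowly with time so sequences are not static; geometry
    is a deterministic function of (scenario seed, t).
    """
    s = scenario.frame_size
    rng = np.random.default_rng(np.random.SeedSequence([scenario.rng_seed, 0x7001]))
    yy, xx = _pixel_grid(s)
    mask = np.zeros((s, s), dtype=bool)
    for _ in range(scenario.n_tools):
        cx0, cy0 = rng.uniform(0.15 * s, 0.85 * s, 2)
        angle = rng.uniform(0, np.pi)
        vx, vy = rng.uniform(-1.5, 1.5, 2)  # px / s drift
        half_len = rng.uniform(0.25 * s, 0.45 * s)
        half_w = rng.uniform(1.2, 2.2)
        cx = np.clip(cx0 + vx * t, 0.1 * s, 0.9 * s)
        cy = np.clip(cy0 + vy * t, 0.1 * s, 0.9 * s)
        ca, sa = np.cos(angle), np.sin(angle)
        u = (xx - cx) * ca + (yy - cy) * sa  # along shaft
        v = -(xx - cx) * sa + (yy - cy) * ca  # across shaft
        # capsule: rectangle with semicircular caps
        du = np.maximum(np.abs(u) - half_len, 0.0)
        mask |= du**2 + v**2 <= half_w**2
    return mask


def _blood_area_target(scenario: SceneScenario, t: float) -> float:
    """Blood-blob area (px^2) the scenario prescribes at time t.

    Precursor window: 2-frame bursts every ~300 ms, mostly sub-threshold
    with every 4th burst briefly supra-threshold.  Sustained phase: area
    starts at the label threshold and grows at ``blob_growth_rate``.
    """
    s2 = scenario.frame_size**2
    min_area = MIN_BLOOD_AREA_FRACTION * s2
    if scenario.bleed_onset_s is not None and t >= scenario.bleed_onset_s:
        area = min_area * 1.5 + scenario.blob_growth_rate * (t - scenario.bleed_onset_s)
        return min(area, 0.25 * s2)
    if scenario.precursor_onset_s is not None and t >= scenario.precursor_onset_s:
        burst_period = 0.3
        burst_len_frames = 2
        dt_in = t - scenario.precursor_onset_s
        burst_idx = int(dt_in // burst_period)
        phase = dt_in - burst_idx * burst_period
        if phase < burst_len_frames / scenario.fps:
            if burst_idx % 4 == 3:  # occasional supra-threshold burst
                return min_area * 1.6
            return min_area * 0.55
    return 0.0


def _blood_mask(scenario: SceneScenario, t: float, tool_mask: np.ndarray) -> np.ndarray:
    """Union-of-ellipses blood pool with the prescribed area, avoiding tools."""
    area = _blood_area_target(scenario, t)
    s = scenario.frame_size
    if area <= 0:
        return np.zeros((s, s), dtype=bool)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.rng_seed, 0x7b1d]))
    cy, cx = rng.uniform(0.3 * s, 0.7 * s, 2)
    aspect = rng.uniform(0.6, 1.0)
    angle = rng.uniform(0, np.pi)
    yy, xx = _pixel_grid(s)
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    # main ellipse sized for the target area plus two satellite blobs
    a = np.sqrt(area / (np.pi * aspect)) * 0.92
    b = a * aspect
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    for k in range(2):
        off = rng.uniform(-1.2, 1.2, 2) * (a + 1)
        r = max(1.0, 0.28 * a)
        mask |= ((xx - cx - off[0]) ** 2 + (yy - cy - off[1]) ** 2) <= r**2
    return mask & ~tool_mask


def render_frame(
    scenario: SceneScenario, t: float, rng_state: np.random.Generator | None = None
) -> FrameSample:
    """Render the frame at time ``t`` of a scenario.

    Deterministic given ``(scenario, t)``; the per-frame pixel-noise stream
    is derived from the scenario seed and the frame index.  The blood label
    is recomputed from the actually rendered blob area, so it can never
    disagree with the pixels.
    """
    if not 0 <= t <= scenario.duration_s:
        raise ValueError(f"t={t} outside [0, {scenario.duration_s}]")
    frame_index = int(round(t * scenario.fps))
    if rng_state is None:
        rng_state = np.random.default_rng(
            np.random.SeedSequence([scenario.rng_seed, 0xF8A3, frame_index])
        )
    img = _background(scenario).copy()
    tools = _tool_mask(scenario, t)
    blood = _blood_mask(scenario, t, tools)

    # dark-red pool: red channel dominant, green/blue suppressed
    red = rng_state.uniform(0.5, 0.8)
    img[blood] = np.array([red, 0.12, 0.10])
    # instruments: bright, low-saturation metal
    img[tools] = np.array([0.88, 0.88, 0.92])
    img += rng_state.normal(0.0, 0.02, img.shape)  # sensor noise
    img = np.clip(img, 0.0, 1.0)

    min_area = MIN_BLOOD_AREA_FRACTION * scenario.frame_size**2
    label = int(blood.sum() >= min_area)
    return FrameSample(
        image=img.astype(np.float32),
        tool_mask=tools.astype(np.uint8),
        blood_label=label,
        timestamp_s=t,
        frame_index=frame_index,
    )


def generate_sequence(
    scenario: SceneScenario,
) -> tuple[list[FrameSample], dict[str, float | None]]:
    """Render all frames of a scenario plus its ground-truth onsets."""
    samples = [
        render_frame(scenario, i / scenario.fps) for i in range(scenario.n_frames)
    ]
    onsets = {
        "precursor_onset_s": scenario.precursor_onset_s,
        "bleed_onset_s": scenario.bleed_onset_s,
    }
    return samples, onsets


def generate_training_dataset(
    n_frames: int,
    seed: int,
    frame_size: int = 64,
) -> list[FrameSample]:
    """Balanced still-frame dataset for training the multi-task network.

    Half the frames come from blood-free scenes, half from scenes well past
    their sustained-bleeding onset; scene geometry varies per frame via the
    seed so the network cannot memorise a single layout.
    """
    if n_frames % 2:
        raise ValueError("n_frames must be even for a balanced dataset")
    samples: list[FrameSample] = []
    for i in range(n_frames):
        with_blood = i % 2 == 1
        scn = SceneScenario(
            duration_s=10.0,
            fps=25.0,
            bleed_onset_s=2.0 if with_blood else None,
            blob_growth_rate=30.0,
            frame_size=frame_size,
            background_texture_seed=seed * 100003 + i,
            rng_seed=seed * 7919 + i,
        )
        # sample a time in the sustained phase (or anywhere, for class 0)
        t_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x11, i]))
        t = t_rng.uniform(3.0, 10.0) if with_blood else t_rng.uniform(0.0, 10.0)
        samples.append(render_frame(scn, min(t, scn.duration_s)))
    return samples


def generate_precursor_confidence_trace(
    rng_seed: int,
    fps: float = 25.0,
    duration_s: float = 14.0,
    plateau_onset_s: float = 10.0,
    precursor_lead_s: float = 6.0,
    burst_period_s: float = 0.3,
    burst_len_frames: int = 2,
    burst_conf: tuple[float, float] = (0.5, 0.7),
    plateau_conf: tuple[float, float] = (0.97, 1.0),
    baseline_conf: tuple[float, float] = (0.0, 0.1),
) -> tuple[np.ndarray, float]:
    """Synthetic per-frame bleeding-confidence trace with oozing precursors.

    Uniform baseline noise; short bursts of moderate confidence every
    ``burst_period_s`` starting ``precursor_lead_s`` before the sustained
    plateau; near-certain confidence from ``plateau_onset_s`` onward.
    Returns ``(values, plateau_onset_s)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0x7A4C]))
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    p = rng.uniform(*baseline_conf, n)
    bt = plateau_onset_s - precursor_lead_s
    while bt < plateau_onset_s:
        i = int(round(bt * fps))
        if 0 <= i < n:
            p[i : i + burst_len_frames] = rng.uniform(*burst_conf)
        bt += burst_period_s
    plateau = t >= plateau_onset_s
    p[plateau] = rng.uniform(*plateau_conf, int(plateau.sum()))
    return np.clip(p, 0.0, 1.0), plateau_onset_s


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _save_png(path: Path, arr: np.ndarray) -> None:
    Image.fromarray(arr).save(path)


def write_dataset(
    samples: Sequence[FrameSample],
    manifest_path: str | Path,
    image_dir: str | Path,
    fps: float = 25.0,
    precursor_onset_s: float | None = None,
    bleed_onset_s: float | None = None,
    seed: int = 0,
) -> DatasetManifest:
    """Write frames/masks as 8-bit PNG plus a JSON manifest; returns the manifest.

    Frame paths are stored relative to the manifest file, so identically
    seeded datasets are byte-identical wherever they are written.
    """
    image_dir = Path(image_dir)
    image_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(manifest_path)
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    manifest = DatasetManifest(
        fps=fps,
        precursor_onset_s=precursor_onset_s,
        bleed_onset_s=bleed_onset_s,
        seed=seed,
    )
    for i, s in enumerate(samples):
        img_path = image_dir / f"frame_{i:06d}.png"
        mask_path = image_dir / f"mask_{i:06d}.png"
        _save_png(img_path, (np.clip(s.image, 0, 1) * 255).round().astype(np.uint8))
        _save_png(mask_path, (s.tool_mask * 255).astype(np.uint8))
        manifest.frames.append(
            {
                "path": os.path.relpath(img_path, manifest_path.parent),
                "mask_path": os.path.relpath(mask_path, manifest_path.parent),
                "label": int(s.blood_label),
                "t": float(s.timestamp_s),
            }
        )
    manifest_path.write_text(manifest.to_json())
    return manifest


def read_manifest(manifest_path: str | Path) -> DatasetManifest:
    """Read a manifest; frame paths are resolved against its location."""
    manifest_path = Path(manifest_path)
    manifest = DatasetManifest.from_json(manifest_path.read_text())
    for fr in manifest.frames:
        for key in ("path", "mask_path"):
            if not Path(fr[key]).is_absolute():
                fr[key] = str(manifest_path.parent / fr[key])
    return manifest


def load_samples(manifest: DatasetManifest) -> list[FrameSample]:
    """Load a written dataset back into memory (images rescaled to [0, 1])."""
    out = []
    for i, fr in enumerate(manifest.frames):
        img = np.asarray(Image.open(fr["path"]), dtype=np.float32) / 255.0
        mask = (np.asarray(Image.open(fr["mask_path"])) > 127).astype(np.uint8)
        out.append(
            FrameSample(
                image=img,
                tool_mask=mask,
                blood_label=int(fr["label"]),
                timestamp_s=float(fr["t"]),
                frame_index=i,
            )
        )
    return out
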