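"""Ground-truthed synthetic near-infrared periocular images.

Renders the structures a NIR eye camera sees — bright skin, brighter sclera
inside a lens-shaped eye opening, a mid-gray iris disc, a dark elliptical
pupil with a slightly rough boundary, near-saturated corneal glints, and an
optional dark eyebrow bar — then applies a Gaussian defocus surrogate and
additive sensor noise.  The gray palette is ordered pupil < iris < sclera by
construction, so the dark-mode assumption the threshold stage relies on
holds on every generated image (pre-noise).

Defocus distance z (cm) maps to blur through sigma = sigma_max * |z| / z_max,
a linear surrogate for the camera's true point-spread function; sigma_max is
configurable so harder regimes can be simulated.  Ground truth is the
centroid of the rasterized pre-blur pupil support, which a symmetric blur
kernel leaves in place — localization error on these images is attributable
to the algorithm, not the rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import InvalidParams
from .io import save_gray_image

_GLINT_GRAY = 245
_EYEBROW_GRAY = 55


@dataclass
class SceneParams:
    """Parameters of one rendered scene.  Defaults give a centered,
    in-focus 640x480 eye."""

    width: int = 640
    height: int = 480
    pupil_center: tuple[float, float] = (320.0, 240.0)
    pupil_axes: tuple[float, float] = (28.0, 25.0)  # semi-axes (a >= b), px
    pupil_angle: float = 0.0  # radians
    pupil_gray: int = 20
    iris_gray: int = 90
    sclera_gray: int = 200
    skin_gray: int = 160
    iris_radius: float = 65.0
    iris_center: tuple[float, float] | None = None  # default: pupil_center
    n_glints: int = 1
    glint_radius_range: tuple[float, float] = (2.0, 4.0)
    eyebrow: bool = True
    boundary_roughness: float = 0.04  # fractional radial perturbation
    blur_sigma: float = 0.0
    defocus_z_cm: float | None = None
    noise_std: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise InvalidParams("image must be at least 1x1")
        if not (0 <= self.pupil_gray < self.iris_gray < self.sclera_gray <= 255):
            raise InvalidParams("palette must satisfy pupil < iris < sclera")
        a, b = self.pupil_axes
        if a <= 0 or b <= 0:
            raise InvalidParams("pupil semi-axes must be positive")
        cx, cy = self.iris_center or self.pupil_center
        px, py = self.pupil_center
        if math.hypot(px - cx, py - cy) + max(a, b) > self.iris_radius:
            raise InvalidParams("pupil ellipse must lie inside the iris disc")
        if (
            cx - self.iris_radius < 0
            or cx + self.iris_radius >= self.width
            or cy - self.iris_radius < 0
            or cy + self.iris_radius >= self.height
        ):
            raise InvalidParams("iris disc must lie inside the image")
        if self.blur_sigma < 0 or self.noise_std < 0:
            raise InvalidParams("blur_sigma and noise_std must be >= 0")


@dataclass
class GroundTruth:
    """True pupil geometry of one rendered scene (pre-blur)."""

    x0: float
    y0: float
    a: float
    b: float
    angle: float
    blur_sigma: float
    defocus_z_cm: float | None = None


def defocus_to_sigma(z_cm: float, sigma_max: float = 6.0, z_max: float = 20.0) -> float:
    """Linear defocus-to-blur surrogate: sigma = sigma_max * |z| / z_max."""
    if abs(z_cm) > z_max:
        raise InvalidParams(f"|z| = {abs(z_cm)} cm exceeds z_max = {z_max} cm")
    return sigma_max * abs(z_cm) / z_max


def _pupil_mask(p: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Rasterize the pupil ellipse with low-order radial roughness, so the
    boundary is convex-concave rather than a perfect conic."""
    px, py = p.pupil_center
    a, b = p.pupil_axes
    ys, xs = np.mgrid[0 : p.height, 0 : p.width]
    dx = xs - px
    dy = ys - py
    ca, sa = math.cos(p.pupil_angle), math.sin(p.pupil_angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)  # 1 on the ideal boundary
    if p.boundary_roughness > 0:
        theta = np.arctan2(dy, dx)
        bound = np.ones_like(q)
        for k in range(2, 6):
            ck, sk = rng.normal(0, 1, size=2)
            bound += p.boundary_roughness / 2.0 * (
                ck * np.cos(k * theta) + sk * np.sin(k * theta)
            )
    else:
        bound = 1.0
    return q <= bound


def render_scene(p: SceneParams) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; fully reproducible from ``p.seed``."""
    p.validate()
    rng = np.random.default_rng(p.seed)
    h, w = p.height, p.width
    canvas = np.full((h, w), float(p.skin_gray))
    icx, icy = p.iris_center or p.pupil_center
    ys, xs = np.mgrid[0:h, 0:w]

    # eye opening: lens-shaped intersection of two discs around the iris
    half_h = 1.6 * p.iris_radius
    half_w = 2.6 * p.iris_radius
    big_r = (half_w**2 + half_h**2) / (2.0 * half_h)
    off = big_r - half_h
    lens = ((xs - icx) ** 2 + (ys - (icy - off)) ** 2 <= big_r**2) & (
        (xs - icx) ** 2 + (ys - (icy + off)) ** 2 <= big_r**2
    )
    canvas[lens] = p.sclera_gray

    canvas[(xs - icx) ** 2 + (ys - icy) ** 2 <= p.iris_radius**2] = p.iris_gray

    pupil = _pupil_mask(p, rng)
    canvas[pupil] = p.pupil_gray

    # eyebrow: dark soft-edged bar above the eye, gray between pupil and iris
    if p.eyebrow:
        bar = np.zeros((h, w))
        bx0 = int(max(0, icx - 2.5 * p.iris_radius))
        bx1 = int(min(w, icx + 2.5 * p.iris_radius))
        by1 = int(max(1, icy - 2.4 * p.iris_radius))
        by0 = int(max(0, by1 - 18))
        bar[by0:by1, bx0:bx1] = 1.0
        alpha = ndi.gaussian_filter(bar, 1.5)
        canvas = canvas * (1 - alpha) + _EYEBROW_GRAY * alpha

    # corneal glints: near-saturated small discs on pupil/iris
    for _ in range(p.n_glints):
        gr = rng.uniform(*p.glint_radius_range)
        ang = rng.uniform(0, 2 * math.pi)
        # keep glints near the pupil so some punch holes into it
        dist = rng.uniform(0, 0.8 * max(p.pupil_axes))
        gx = p.pupil_center[0] + dist * math.cos(ang)
        gy = p.pupil_center[1] + dist * math.sin(ang)
        canvas[(xs - gx) ** 2 + (ys - gy) ** 2 <= gr**2] = _GLINT_GRAY

    if p.blur_sigma > 0:
        canvas = ndi.gaussian_filter(canvas, p.blur_sigma)
    if p.noise_std > 0:
        canvas = canvas + rng.normal(0.0, p.noise_std, size=canvas.shape)
    img = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    rows, cols = np.nonzero(pupil)
    truth = GroundTruth(
        x0=float(cols.mean()),
        y0=float(rows.mean()),
        a=p.pupil_axes[0],
        b=p.pupil_axes[1],
        angle=p.pupil_angle,
        blur_sigma=p.blur_sigma,
        defocus_z_cm=p.defocus_z_cm,
    )
    return img, truth


def sample_scene_params(
    seed: int,
    width: int = 640,
    height: int = 480,
    blur_sigma: float = 0.0,
    defocus_z_cm: float | None = None,
    noise_std: float = 3.0,
) -> SceneParams:
    """Draw one randomized scene (center jitter, axes, glints, eyebrow
    presence) reproducibly from *seed*."""
    rng = np.random.default_rng(seed)
    iris_radius = rng.uniform(55.0, 75.0)
    ecx = width / 2 + rng.uniform(-60, 60)
    ecy = height / 2 + rng.uniform(-40, 40)
    a = rng.uniform(0.30, 0.45) * iris_radius
    b = a * rng.uniform(0.85, 1.0)
    px = ecx + rng.uniform(-3, 3)
    py = ecy + rng.uniform(-3, 3)
    return SceneParams(
        width=width,
        height=height,
        pupil_center=(px, py),
        pupil_axes=(a, b),
        pupil_angle=rng.uniform(0, math.pi),
        iris_radius=iris_radius,
        iris_center=(ecx, ecy),
        n_glints=int(rng.integers(0, 3)),
        eyebrow=bool(rng.random() < 0.7),
        blur_sigma=blur_sigma,
        defocus_z_cm=defocus_z_cm,
        noise_std=noise_std,
        seed=seed,
    )


MANIFEST_COLUMNS = [
    "filename", "x0", "y0", "a", "b", "angle_rad",
    "blur_sigma", "defocus_z_cm", "seed",
]


def generate_dataset(
    out_dir: str | Path,
    n_per_level: int,
    blur_levels_cm: list[float] | None = None,
    seed: int = 0,
    width: int = 640,
    height: int = 480,
    sigma_max: float = 6.0,
    z_max: float = 20.0,
    noise_std: float = 3.0,
) -> pd.DataFrame:
    """Write ``n_per_level`` PNGs per defocus level plus a ground-truth
    manifest CSV; per-image seeds derive deterministically from *seed*.

    Returns the manifest as a DataFrame (also written to
    ``out_dir/manifest.csv``).
    """
    if n_per_level < 1:
        raise InvalidParams("n_per_level must be >= 1")
    blur_levels_cm = blur_levels_cm if blur_levels_cm is not None else [0, 5, 10, 15, 20]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    rows = []
    idx = 0
    for z in blur_levels_cm:
        sigma = defocus_to_sigma(z, sigma_max=sigma_max, z_max=z_max)
        for _ in range(n_per_level):
            child_seed = int(master.integers(0, 2**31 - 1))
            params = sample_scene_params(
                child_seed, width=width, height=height,
                blur_sigma=sigma, defocus_z_cm=z, noise_std=noise_std,
            )
            img, truth = render_scene(params)
            fname = f"eye_z{z:g}_{idx:04d}.png"
            save_gray_image(img, out_dir / fname)
            rows.append(
                {
                    "filename": fname,
                    "x0": truth.x0,
                    "y0": truth.y0,
                    "a": truth.a,
                    "b": truth.b,
                    "angle_rad": truth.angle,
                    "blur_sigma": truth.blur_sigma,
                    "defocus_z_cm": z,
                    "seed": child_seed,
                }
            )
            idx += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
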