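"""Synthetic thallus phantoms and micro-CT-like scenes with known ground truth.

Bodies are voxelized by center-inclusion: a voxel is foreground iff its
center lies inside the analytic solid.  Where closed forms exist (sphere,
cuboid/slab, L-tromino prism, plus-pentomino prism, hemispherical shell)
the analytic V, Vc, A, Ac, C, S are attached as a ground-truth record.

Scenes emulate the acquisition setup: a thin sheet-like "plant" of
intermediate intensity resting above a high-intensity pedestal block,
inside a cylindrical tube shell, plus additive Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import PhantomError
from .volume_io import BinaryVolume, Volume3D

SHAPES = ("sphere", "cuboid", "slab", "twisted_slab", "l_prism", "plus_prism", "shell")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic body.

    Only the fields relevant to ``shape`` are used:

    * ``sphere``: radius
    * ``cuboid`` / ``slab``: length, width, thickness
    * ``twisted_slab``: length, width, thickness, twist (degrees about the
      long axis), undulation_amplitude, undulation_period
    * ``l_prism`` / ``plus_prism``: cell (unit-cell edge; prism height = cell)
    * ``shell``: radius (outer), thickness (radial)

    All lengths are in the same units as ``spacing``.
    """

    shape: str
    radius: float | None = None
    length: float | None = None
    width: float | None = None
    thickness: float | None = None
    cell: float | None = None
    twist: float = 0.0
    undulation_amplitude: float = 0.0
    undulation_period: float | None = None
    buckling: float = 0.1
    buckling_wavelength: float | None = None
    grid_shape: tuple[int, int, int] | None = None
    spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise PhantomError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        for fname in ("radius", "length", "width", "thickness", "cell",
                      "undulation_period", "spacing"):
            v = getattr(self, fname)
            if v is not None and v <= 0:
                raise PhantomError(f"{fname} must be positive, got {v}")
        if self.twist < 0:
            raise PhantomError(f"twist must be >= 0, got {self.twist}")
        if self.undulation_amplitude < 0:
            raise PhantomError("undulation_amplitude must be >= 0")
        if self.buckling < 0:
            raise PhantomError("buckling must be >= 0")


@dataclass
class SceneSpec:
    """Parameters of a full synthetic micro-CT scene."""

    plant: PhantomSpec
    plant_intensity: float = 100.0
    pedestal_intensity: float = 200.0
    tube_wall_intensity: float = 230.0
    background_intensity: float = 0.0
    noise_sd: float = 5.0
    seed: int = 0
    pedestal_height: int = 8
    pedestal_margin: int = 4

    def __post_init__(self) -> None:
        if not (self.pedestal_intensity > self.plant_intensity > self.background_intensity):
            raise PhantomError(
                "intensity ordering violated: need pedestal > plant > background, got "
                f"{self.pedestal_intensity}, {self.plant_intensity}, "
                f"{self.background_intensity}"
            )
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# body generators


def _centered_coords(grid_shape, spacing):
    """Voxel-center coordinates relative to the grid center, per axis."""
    axes = [(np.arange(n) + 0.5 - n / 2.0) * spacing for n in grid_shape]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _auto_grid(half_extents, spacing, margin=3):
    # even dimensions keep voxel centers at half-integer offsets from the
    # body center for every shape, so identical solids voxelize identically
    # whatever grid they land in
    dims = []
    for h in half_extents:
        n = int(math.ceil(2 * h / spacing))
        dims.append(n + n % 2 + 2 * margin)
    return tuple(dims)


def _check_fits(mask: np.ndarray, what: str) -> None:
    if (mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
            or mask[:, :, 0].any() or mask[:, :, -1].any()):
        raise PhantomError(f"{what} exceeds the grid (foreground on a boundary face)")


def make_twisted_slab(length: float, width: float, thickness: float,
                      twist: float = 0.0,
                      undulation_amplitude: float = 0.0,
                      undulation_period: float | None = None,
                      buckling: float = 0.1,
                      buckling_wavelength: float | None = None,
                      spacing: float = 1.0,
                      grid_shape: tuple[int, int, int] | None = None,
                      name: str = "twisted_slab") -> BinaryVolume:
    """Slab with long axis z, cross-sections rotated linearly to a total
    ``twist`` (degrees), with optional sinusoidal out-of-plane undulation.

    The twist carries an across-the-width corrugation ("buckling") whose
    amplitude grows as ``buckling * width * sqrt(twist/90)``: a rigidly
    rotated sheet is near-isometric, so its convex hull would inflate
    faster than its surface and convexity would *rise* with twist — the
    opposite of a deformed growing sheet, which corrugates as it twists.
    The coupled term makes both descriptors decrease monotonically with
    twist.  Set ``buckling=0`` for a pure rigid rotation.

    Requires thickness < width < length; the result is a single connected
    body (checked).
    """
    if not (thickness < width < length):
        raise PhantomError(
            f"need thickness < width < length, got {thickness}, {width}, {length}"
        )
    if buckling < 0:
        raise PhantomError("buckling must be >= 0")
    amp = undulation_amplitude
    period = undulation_period if undulation_period is not None else length / 2.0
    b_amp = buckling * width * math.sqrt(twist / 90.0) if twist > 0 else 0.0
    b_lam = buckling_wavelength if buckling_wavelength is not None else 0.45 * width
    if grid_shape is None:
        half_cross = math.hypot(width, thickness) / 2.0 + amp + b_amp
        grid_shape = _auto_grid((length / 2.0, half_cross, half_cross), spacing)
    z, y, x = _centered_coords(grid_shape, spacing)
    theta = math.radians(twist) * (z / length + 0.5)
    # rotate (y, x) back into the cross-section frame
    yr = y * np.cos(theta) + x * np.sin(theta)
    xr = -y * np.sin(theta) + x * np.cos(theta)
    offset = amp * np.sin(2 * np.pi * z / period) if amp > 0 else 0.0
    if b_amp > 0:
        offset = offset + b_amp * np.sin(2 * np.pi * yr / b_lam)
    mask = ((np.abs(z) <= length / 2.0)
            & (np.abs(yr) <= width / 2.0)
            & (np.abs(xr - offset) <= thickness / 2.0))
    _check_fits(mask, "twisted slab")
    _, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n != 1:
        raise PhantomError(
            f"twisted slab is not a single connected body ({n} components); "
            "reduce twist/undulation or increase resolution"
        )
    return BinaryVolume(data=mask, spacing=spacing, name=name)


def _sphere_truth(r):
    V = 4.0 / 3.0 * math.pi * r**3
    A = 4.0 * math.pi * r**2
    return dict(V=V, Vc=V, A=A, Ac=A, C=1.0, S=1.0)


def _cuboid_truth(a, b, c):
    V = a * b * c
    A = 2 * (a * b + b * c + c * a)
    return dict(V=V, Vc=V, A=A, Ac=A, C=1.0, S=1.0)


def _l_prism_truth(s):
    # footprint: 3 unit cells in an L; hull footprint = 2x2 square minus a
    # 0.5 corner triangle (area 3.5), hull perimeter 6 + sqrt(2)
    V = 3 * s**3
    A = (2 * 3 + 8) * s**2
    Vc = 3.5 * s**3
    Ac = (2 * 3.5 + 6 + math.sqrt(2)) * s**2
    return dict(V=V, Vc=Vc, A=A, Ac=Ac, C=Ac / A, S=V / Vc)


def _plus_prism_truth(s):
    # footprint: plus-pentomino (5 cells); hull footprint = octagon, area 7,
    # perimeter 4 + 4*sqrt(2)
    V = 5 * s**3
    A = (2 * 5 + 12) * s**2
    Vc = 7 * s**3
    Ac = (2 * 7 + 4 + 4 * math.sqrt(2)) * s**2
    return dict(V=V, Vc=Vc, A=A, Ac=Ac, C=Ac / A, S=V / Vc)


def _shell_truth(r, t):
    ri = r - t
    V = 2.0 / 3.0 * math.pi * (r**3 - ri**3)
    Vc = 2.0 / 3.0 * math.pi * r**3
    A = 2 * math.pi * r**2 + 2 * math.pi * ri**2 + math.pi * (r**2 - ri**2)
    Ac = 2 * math.pi * r**2 + math.pi * r**2
    return dict(V=V, Vc=Vc, A=A, Ac=Ac, C=Ac / A, S=V / Vc)


def make_body(spec: PhantomSpec) -> tuple[BinaryVolume, dict]:
    """Voxelize the analytic solid of ``spec``.

    Returns the binary body plus a ground-truth record with the analytic
    V, Vc, A, Ac, C, S where closed forms exist (``twisted_slab`` with a
    nonzero twist/undulation has none; its record carries only metadata).
    """
    s = spec.spacing
    shape = spec.shape
    truth: dict = {"shape": shape, "spacing": s}

    if shape == "sphere":
        r = _require(spec, "radius")
        grid = spec.grid_shape or _auto_grid((r, r, r), s)
        z, y, x = _centered_coords(grid, s)
        mask = z**2 + y**2 + x**2 <= r**2
        truth.update(_sphere_truth(r))
    elif shape in ("cuboid", "slab"):
        a = _require(spec, "length")
        b = _require(spec, "width")
        c = _require(spec, "thickness")
        grid = spec.grid_shape or _auto_grid((a / 2, b / 2, c / 2), s)
        z, y, x = _centered_coords(grid, s)
        mask = (np.abs(z) <= a / 2) & (np.abs(y) <= b / 2) & (np.abs(x) <= c / 2)
        truth.update(_cuboid_truth(a, b, c))
    elif shape == "twisted_slab":
        body = make_twisted_slab(
            _require(spec, "length"), _require(spec, "width"),
            _require(spec, "thickness"), spec.twist,
            spec.undulation_amplitude, spec.undulation_period,
            buckling=spec.buckling,
            buckling_wavelength=spec.buckling_wavelength,
            spacing=s, grid_shape=spec.grid_shape,
        )
        if spec.twist == 0 and spec.undulation_amplitude == 0:
            truth.update(_cuboid_truth(spec.length, spec.width, spec.thickness))
        return body, truth
    elif shape in ("l_prism", "plus_prism"):
        c = _require(spec, "cell")
        if shape == "l_prism":
            cells = [(0, 0), (1, 0), (0, 1)]
            ext_y, ext_x = 2, 2
            truth.update(_l_prism_truth(c))
        else:
            cells = [(1, 1), (0, 1), (2, 1), (1, 0), (1, 2)]
            ext_y, ext_x = 3, 3
            truth.update(_plus_prism_truth(c))
        grid = spec.grid_shape or _auto_grid((c / 2, ext_y * c / 2, ext_x * c / 2), s)
        z, y, x = _centered_coords(grid, s)
        yy = y + ext_y * c / 2.0  # footprint coordinates in [0, ext*c)
        xx = x + ext_x * c / 2.0
        mask = np.zeros(np.broadcast_shapes(z.shape, y.shape, x.shape), dtype=bool)
        in_z = np.abs(z) <= c / 2.0
        for (cy, cx) in cells:
            mask |= (in_z
                     & (yy >= cy * c) & (yy <= (cy + 1) * c)
                     & (xx >= cx * c) & (xx <= (cx + 1) * c))
        truth["cells"] = cells
    elif shape == "shell":
        r = _require(spec, "radius")
        t = _require(spec, "thickness")
        if t >= r:
            raise PhantomError(f"shell thickness {t} must be < radius {r}")
        grid = spec.grid_shape or _auto_grid((r, r, r), s)
        z, y, x = _centered_coords(grid, s)
        d2 = z**2 + y**2 + x**2
        mask = (d2 <= r**2) & (d2 >= (r - t) ** 2) & (z >= 0)
        truth.update(_shell_truth(r, t))
    else:  # pragma: no cover - guarded by PhantomSpec
        raise PhantomError(f"unknown shape {shape!r}")

    _check_fits(mask, shape)
    return BinaryVolume(data=mask, spacing=s, name=shape), truth


def _require(spec: PhantomSpec, fname: str) -> float:
    v = getattr(spec, fname)
    if v is None:
        raise PhantomError(f"shape {spec.shape!r} requires {fname!r}")
    return v


# ---------------------------------------------------------------------------
# scenes


def make_scene(spec: SceneSpec) -> tuple[Volume3D, BinaryVolume]:
    """Assemble a synthetic micro-CT scene with ground truth.

    The plant body (long axis horizontal, thickness vertical) rests one
    voxel above a pedestal cuboid, inside a hollow-cylinder tube wall of
    full height.  Gaussian noise of ``noise_sd`` is added with the scene
    seed; the returned ground-truth mask is unnoised.
    """
    body, _ = make_body(spec.plant)
    return make_scene_from_body(body, spec)


def make_scene_from_body(body: BinaryVolume,
                         spec: SceneSpec) -> tuple[Volume3D, BinaryVolume]:
    """As :func:`make_scene`, but embedding a pre-voxelized plant body."""
    # body axes (z=long, y=width, x=thickness) -> scene axes
    # (z=thickness/vertical, y=long, x=width)
    plant = np.transpose(body.data, (2, 0, 1))
    nz = np.argwhere(plant)
    lo, hi = nz.min(0), nz.max(0) + 1
    plant = plant[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pz, py, px = plant.shape

    m = spec.pedestal_margin
    hp = spec.pedestal_height
    ped_y, ped_x = py + 2 * m, px + 2 * m
    r_in = math.ceil(math.hypot(ped_y / 2.0, ped_x / 2.0)) + 3
    wall = 2
    Z = 3 + hp + 1 + pz + 6
    Y = X = 2 * (r_in + wall) + 4

    scene = np.full((Z, Y, X), float(spec.background_intensity))
    truth = np.zeros((Z, Y, X), dtype=bool)

    cy, cx = Y // 2, X // 2
    yy, xx = np.meshgrid(np.arange(Y) - cy + 0.5, np.arange(X) - cx + 0.5,
                         indexing="ij")
    rr = np.hypot(yy, xx)
    tube = (rr >= r_in) & (rr <= r_in + wall)
    scene[:, tube] = spec.tube_wall_intensity

    z0 = 3
    y0, x0 = cy - ped_y // 2, cx - ped_x // 2
    scene[z0:z0 + hp, y0:y0 + ped_y, x0:x0 + ped_x] = spec.pedestal_intensity

    zp = z0 + hp + 1  # one-voxel air gap: "resting on" the pedestal
    yp, xp = cy - py // 2, cx - px // 2
    region = scene[zp:zp + pz, yp:yp + py, xp:xp + px]
    if (region[plant] != spec.background_intensity).any():
        raise PhantomError("plant overlaps pedestal/tube beyond the contact layer")
    region[plant] = spec.plant_intensity
    truth[zp:zp + pz, yp:yp + py, xp:xp + px] = plant

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        scene = scene + rng.normal(0.0, spec.noise_sd, size=scene.shape)

    name = f"scene_{body.name or spec.plant.shape}"
    return (Volume3D(data=scene, spacing=body.spacing, name=name),
            BinaryVolume(data=truth, spacing=body.spacing, name=name + "_truth"))


# ---------------------------------------------------------------------------
# populations


def sample_population(n: int, base: PhantomSpec, jitter: float = 0.1,
                      label: str = "", seed: int = 0) -> list[tuple[BinaryVolume, str]]:
    """Draw ``n`` bodies with lognormally jittered size (and twist) parameters.

    ``jitter`` is the relative sd of the lognormal multipliers (must be
    >= 0); lognormal jitter keeps all lengths positive.  Bit-reproducible
    from ``seed``.
    """
    if n < 1:
        raise PhantomError(f"population size must be >= 1, got {n}")
    if jitter < 0 or not np.isfinite(jitter):
        raise PhantomError(f"jitter must be a finite value >= 0, got {jitter}")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + jitter**2)) if jitter > 0 else 0.0
    out = []
    jittered_fields = ("radius", "length", "width", "thickness", "cell",
                       "twist", "undulation_amplitude")
    for i in range(n):
        changes = {}
        for fname in jittered_fields:
            v = getattr(base, fname)
            if v is None or v == 0:
                continue
            factor = float(rng.lognormal(mean=0.0, sigma=sigma)) if sigma > 0 else 1.0
            changes[fname] = v * factor
        spec = dataclasses.replace(base, grid_shape=None, **changes)
        body, _ = make_body(spec)
        body.name = f"{label or base.shape}_{i:03d}"
        out.append((body, label))
    return out
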