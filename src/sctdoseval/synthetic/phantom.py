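"""Digital head phantoms: planning-CT truth and the sCT corruption model.

The phantom is an ellipsoidal head with a scalp layer, a bony skull shell,
a thick bony skull base, air-filled sinus cavities carved into bone, a
brain interior, a PTV, and the common brain OARs.  Post-surgical features
(drill holes, metal screws, an optional low-density implant plate replacing
part of the skull) can be rendered in, emulating a post-surgical cohort.

The corruption model turns the planning-CT truth into a synthetic CT by
resampling to the sCT grid and then applying a global HU bias, Gaussian HU
noise inside the body, probabilistic label flips in a shell around bone
interfaces (bone→soft and soft/air→bone — the classic bone/air ambiguity of
MR-derived CT), and deterministic feature mislabeling: drill holes, screws
and the implant are all painted as bone, the dominant failure mode of
deep-learning sCT reconstruction around surgical anomalies.

Default HU values: soft tissue 40, brain 35, skull bone 1000, sinus air
−990, metal screws 3000, implant 20 (a plastic-like material well below the
100 HU bone threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ..grids import BinaryMask, ScalarVolume, VolumeGrid, resample

__all__ = [
    "PhantomSpec",
    "CorruptionSpec",
    "PhantomGeometry",
    "Phantom",
    "make_phantom",
    "corrupt_to_sct",
    "default_ct_grid",
    "default_sct_grid",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and rendering parameters of one head phantom (mm / HU)."""

    head_semiaxes: tuple[float, float, float] = (70.0, 88.0, 80.0)
    scalp_thickness_mm: float = 4.0
    skull_thickness_mm: float = 6.0
    skull_base_z_mm: float = -55.0      # solid bone below this plane
    csf_gap_mm: float = 4.0             # CSF layer between brain and inner skull
    soft_hu: float = 40.0
    brain_hu: float = 35.0
    bone_hu: float = 1000.0
    air_hu: float = -990.0
    metal_hu: float = 3000.0
    implant_hu: float = 20.0
    #: air cavities carved into bone/brain: (center xyz, radius mm)
    sinuses: tuple[tuple[tuple[float, float, float], float], ...] = (
        ((0.0, 58.0, 15.0), 9.0),        # frontal
        ((0.0, 32.0, -45.0), 10.0),      # ethmoid
        ((0.0, 6.0, -50.0), 9.0),        # sphenoid
        ((24.0, 42.0, -56.0), 9.0),      # maxillary R
        ((-24.0, 42.0, -56.0), 9.0),     # maxillary L
    )
    ptv_center_mm: tuple[float, float, float] = (20.0, 10.0, 10.0)
    ptv_semiaxes_mm: tuple[float, float, float] = (30.0, 30.0, 25.0)
    #: OAR name -> (center xyz, semi-axes)
    oars: tuple[tuple[str, tuple[float, float, float], tuple[float, float, float]], ...] = (
        ("brainstem", (0.0, -8.0, -38.0), (7.0, 7.0, 18.0)),
        ("optic_chiasm", (0.0, 22.0, -30.0), (4.0, 4.0, 4.0)),
        ("optic_nerve_l", (-10.0, 34.0, -30.0), (2.5, 9.0, 2.5)),
        ("optic_nerve_r", (10.0, 34.0, -30.0), (2.5, 9.0, 2.5)),
        ("lens_l", (-30.0, 56.0, -25.0), (2.5, 2.5, 2.5)),
        ("lens_r", (30.0, 56.0, -25.0), (2.5, 2.5, 2.5)),
        ("cochlea_l", (-48.0, -5.0, -50.0), (3.0, 3.0, 3.0)),
        ("cochlea_r", (48.0, -5.0, -50.0), (3.0, 3.0, 3.0)),
    )
    n_drill_holes: int = 2
    drill_hole_radius_mm: float = 3.0
    n_screws: int = 2
    screw_radius_mm: float = 2.0
    has_implant: bool = False
    implant_cap_deg: float = 25.0        # angular half-width of the plate
    #: acquisition grids (planning CT / synthetic CT voxel pitch)
    ct_spacing_mm: tuple[float, float, float] = (1.2, 1.2, 3.0)
    sct_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.5)
    grid_margin_mm: float = 8.0
    prescription_gy: float = 50.0

    def validate(self) -> None:
        a = np.asarray(self.head_semiaxes)
        if np.any(a <= self.scalp_thickness_mm + self.skull_thickness_mm):
            raise ValueError("head semi-axes too small for the scalp+skull shell")
        c = np.asarray(self.ptv_center_mm)
        s = np.asarray(self.ptv_semiaxes_mm)
        if np.any((np.abs(c) + s) > a):
            raise ValueError(
                "PTV: bounding box extends outside the head ellipsoid "
                f"(center {self.ptv_center_mm}, semi-axes {self.ptv_semiaxes_mm})"
            )
        for (center, r) in self.sinuses:
            if _ellipsoid_q(np.asarray(center), np.zeros(3), a) > 1.0:
                raise ValueError(f"sinus: center {center} lies outside the head")


def _ellipsoid_q(p, center, semiaxes):
    d = (np.asarray(p, dtype=float) - np.asarray(center)) / np.asarray(semiaxes)
    return float(np.dot(d, d))


def _grid_for(spec: PhantomSpec, spacing) -> VolumeGrid:
    half = np.asarray(spec.head_semiaxes) + spec.grid_margin_mm
    spacing = np.asarray(spacing, dtype=float)
    size = (np.ceil(2 * half / spacing)).astype(int) + 1
    origin = -(size - 1) / 2.0 * spacing
    return VolumeGrid(origin=tuple(origin), spacing=tuple(spacing), size=tuple(size))


def default_ct_grid(spec: PhantomSpec) -> VolumeGrid:
    return _grid_for(spec, spec.ct_spacing_mm)


def default_sct_grid(spec: PhantomSpec) -> VolumeGrid:
    return _grid_for(spec, spec.sct_spacing_mm)


class PhantomGeometry:
    """Analytic truth geometry: continuous membership, renderable on any grid.

    Feature placements (drill holes, screws, implant orientation) are fixed
    at construction from a seeded RNG, after which every rendering is a pure
    function of the grid.
    """

    def __init__(self, spec: PhantomSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        # surgical features sit on the superior skull shell around the PTV side
        self.hole_dirs = [
            _random_cap_direction(rng, polar_max_deg=60.0)
            for _ in range(spec.n_drill_holes)
        ]
        self.screw_dirs = [
            _random_cap_direction(rng, polar_max_deg=60.0)
            for _ in range(spec.n_screws)
        ]
        self.implant_dir = _random_cap_direction(rng, polar_max_deg=45.0)

    # -- continuous membership fields -------------------------------------
    def _q(self, x, y, z, semiaxes, center=(0.0, 0.0, 0.0)):
        a, b, c = semiaxes
        cx, cy, cz = center
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2

    def body(self, x, y, z):
        return self._q(x, y, z, self.spec.head_semiaxes) <= 1.0

    def _shell_surface_point(self, direction):
        # point on the skull shell mid-surface along a unit direction
        mid = np.asarray(self.spec.head_semiaxes) - (
            self.spec.scalp_thickness_mm + self.spec.skull_thickness_mm / 2.0
        )
        d = np.asarray(direction)
        scale = 1.0 / math.sqrt(float(np.sum((d / mid) ** 2)))
        return d * scale

    def bone_region(self, x, y, z):
        """Geometric skull region (shell + base) before any carving."""
        outer = np.asarray(self.spec.head_semiaxes) - self.spec.scalp_thickness_mm
        inner = outer - self.spec.skull_thickness_mm
        in_outer = self._q(x, y, z, outer) <= 1.0
        in_inner = self._q(x, y, z, inner) <= 1.0
        shell = in_outer & ~in_inner
        base = in_outer & (np.broadcast_to(z, shell.shape) < self.spec.skull_base_z_mm)
        return shell | base

    def sinus(self, x, y, z):
        out = np.zeros(np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z)), bool)
        for center, r in self.spec.sinuses:
            out |= self._q(x, y, z, (r, r, r), center) <= 1.0
        return out

    def drill_holes(self, x, y, z):
        out = np.zeros(np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z)), bool)
        # a sphere centered on the shell mid-surface, wide enough to punch
        # through the full shell thickness
        r = max(
            self.spec.drill_hole_radius_mm, self.spec.skull_thickness_mm / 2.0 + 1.0
        )
        for d in self.hole_dirs:
            c = self._shell_surface_point(d)
            out |= self._q(x, y, z, (r, r, r), c) <= 1.0
        return out

    def screws(self, x, y, z):
        out = np.zeros(np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z)), bool)
        r = self.spec.screw_radius_mm
        for d in self.screw_dirs:
            c = self._shell_surface_point(d)
            out |= self._q(x, y, z, (r, r, r), c) <= 1.0
        return out

    def implant(self, x, y, z):
        """Spherical-cap portion of the skull shell replaced by the plate."""
        if not self.spec.has_implant:
            return np.zeros(
                np.broadcast_shapes(np.shape(x), np.shape(y), np.shape(z)), bool
            )
        d = self.implant_dir
        norm = np.sqrt(x**2 + y**2 + z**2) + 1e-9
        cosang = (x * d[0] + y * d[1] + z * d[2]) / norm
        cap = cosang >= math.cos(math.radians(self.spec.implant_cap_deg))
        outer = np.asarray(self.spec.head_semiaxes) - self.spec.scalp_thickness_mm
        inner = outer - self.spec.skull_thickness_mm
        shell = (self._q(x, y, z, outer) <= 1.0) & ~(self._q(x, y, z, inner) <= 1.0)
        return shell & cap

    def bone(self, x, y, z):
        """True bone after carving sinuses, drill holes and the implant."""
        return (
            self.bone_region(x, y, z)
            & ~self.sinus(x, y, z)
            & ~self.drill_holes(x, y, z)
            & ~self.implant(x, y, z)
        )

    def brain(self, x, y, z):
        outer = np.asarray(self.spec.head_semiaxes) - self.spec.scalp_thickness_mm
        # the brain proper sits inside a CSF layer, clear of the inner table
        inner = outer - self.spec.skull_thickness_mm - self.spec.csf_gap_mm
        q = self._q(x, y, z, inner)
        return (
            (q <= 1.0)
            & (np.broadcast_to(z, q.shape) >= self.spec.skull_base_z_mm
               + self.spec.csf_gap_mm)
            & ~self.sinus(x, y, z)
        )

    def ptv(self, x, y, z):
        return self._q(x, y, z, self.spec.ptv_semiaxes_mm, self.spec.ptv_center_mm) <= 1.0

    # -- rendering ---------------------------------------------------------
    def _fields(self, grid: VolumeGrid) -> dict[str, np.ndarray]:
        """All boolean fields on a grid, computed once and cached.

        Large structures use broadcast 1D quadratics; small features
        (sinuses, holes, screws) are painted only inside their bounding
        boxes.
        """
        key = (grid.origin, grid.spacing, grid.size)
        if getattr(self, "_field_key", None) == key:
            return self._field_cache
        spec = self.spec
        xs = grid.axis_coords(0).astype(np.float32)
        ys = grid.axis_coords(1).astype(np.float32)
        zs = grid.axis_coords(2).astype(np.float32)

        def q_grid(center, semi):
            qx = ((xs - center[0]) / semi[0]) ** 2
            qy = ((ys - center[1]) / semi[1]) ** 2
            qz = ((zs - center[2]) / semi[2]) ** 2
            return qx[:, None, None] + qy[None, :, None] + qz[None, None, :]

        head = np.asarray(spec.head_semiaxes)
        outer = head - spec.scalp_thickness_mm
        inner = outer - spec.skull_thickness_mm
        brain_semi = inner - spec.csf_gap_mm
        zero = (0.0, 0.0, 0.0)

        body = q_grid(zero, head) <= 1.0
        in_outer = q_grid(zero, outer) <= 1.0
        shell = in_outer & ~(q_grid(zero, inner) <= 1.0)
        below_base = zs < spec.skull_base_z_mm
        bone_region = shell | (in_outer & below_base[None, None, :])

        def painted(items):
            out = np.zeros(grid.size, dtype=bool)
            for center, semi in items:
                _paint_ellipsoid(out, grid, center, semi)
            return out

        sinus = painted([(c, (r, r, r)) for c, r in spec.sinuses]) & body
        hole_r = max(spec.drill_hole_radius_mm, spec.skull_thickness_mm / 2.0 + 1.0)
        holes = painted(
            [(self._shell_surface_point(d), (hole_r,) * 3) for d in self.hole_dirs]
        ) & bone_region
        screws = painted(
            [
                (self._shell_surface_point(d), (spec.screw_radius_mm,) * 3)
                for d in self.screw_dirs
            ]
        ) & body
        if spec.has_implant:
            d = self.implant_dir
            cosang = (
                xs[:, None, None] * d[0]
                + ys[None, :, None] * d[1]
                + zs[None, None, :] * d[2]
            )
            rad = np.sqrt(q_grid(zero, (1.0, 1.0, 1.0)))
            implant = shell & (cosang >= math.cos(math.radians(spec.implant_cap_deg)) * rad)
        else:
            implant = np.zeros(grid.size, dtype=bool)

        brain = (
            (q_grid(zero, brain_semi) <= 1.0)
            & (zs >= spec.skull_base_z_mm + spec.csf_gap_mm)[None, None, :]
            & ~sinus
        )
        fields = {
            "body": body,
            "bone_region": bone_region,
            "bone": bone_region & ~sinus & ~holes & ~implant,
            "brain": brain,
            "sinus": sinus,
            "drill_holes": holes,
            "screws": screws,
            "implant": implant,
            "ptv": q_grid(spec.ptv_center_mm, spec.ptv_semiaxes_mm) <= 1.0,
        }
        self._field_key = key
        self._field_cache = fields
        return fields

    def render_hu(self, grid: VolumeGrid) -> ScalarVolume:
        f = self._fields(grid)
        hu = np.full(grid.size, -1000.0, dtype=np.float32)
        hu[f["body"]] = self.spec.soft_hu
        hu[f["brain"]] = self.spec.brain_hu
        hu[f["bone"]] = self.spec.bone_hu
        hu[f["sinus"]] = self.spec.air_hu
        hu[f["implant"]] = self.spec.implant_hu
        hu[f["drill_holes"]] = self.spec.soft_hu
        hu[f["screws"]] = self.spec.metal_hu
        return ScalarVolume(grid, hu)

    def render_masks(self, grid: VolumeGrid) -> dict[str, BinaryMask]:
        f = self._fields(grid)
        masks = {
            "body": f["body"],
            "brain": f["brain"],
            "skull_region": f["bone_region"],
            "ptv": f["ptv"],
        }
        for name, center, semi in self.spec.oars:
            m = np.zeros(grid.size, dtype=bool)
            _paint_ellipsoid(m, grid, center, semi)
            masks[name] = m
        return {k: BinaryMask(grid, v) for k, v in masks.items()}

    def render_feature_masks(self, grid: VolumeGrid) -> dict[str, np.ndarray]:
        f = self._fields(grid)
        return {
            k: f[k]
            for k in ("drill_holes", "screws", "implant", "bone", "sinus", "body")
        }

    def bone_fraction_in_ptv(self, supersample_spacing=(0.5, 0.5, 0.75)) -> float:
        """Analytic (finely sampled) true-bone fraction of the PTV volume."""
        c = np.asarray(self.spec.ptv_center_mm)
        s = np.asarray(self.spec.ptv_semiaxes_mm)
        sp = np.asarray(supersample_spacing, dtype=float)
        axes = [
            np.arange(c[a] - s[a], c[a] + s[a] + sp[a] / 2, sp[a]) for a in range(3)
        ]
        x = axes[0][:, None, None]
        y = axes[1][None, :, None]
        z = axes[2][None, None, :]
        inside = self.ptv(x, y, z)
        n_in = int(inside.sum())
        if n_in == 0:
            raise ValueError("PTV: no sample points inside (degenerate geometry)")
        return float((inside & self.bone(x, y, z)).sum() / n_in)


def _paint_ellipsoid(out: np.ndarray, grid: VolumeGrid, center, semiaxes) -> None:
    """OR an ellipsoid into a boolean array, touching only its bounding box."""
    sl = []
    for a in range(3):
        lo = (center[a] - semiaxes[a] - grid.origin[a]) / grid.spacing[a]
        hi = (center[a] + semiaxes[a] - grid.origin[a]) / grid.spacing[a]
        i0 = max(int(np.ceil(lo)), 0)
        i1 = min(int(np.floor(hi)) + 1, grid.size[a])
        if i0 >= i1:
            return
        sl.append((i0, i1))
    ax = [
        (grid.origin[a] + grid.spacing[a] * np.arange(sl[a][0], sl[a][1]) - center[a])
        / semiaxes[a]
        for a in range(3)
    ]
    q = (
        (ax[0] ** 2)[:, None, None]
        + (ax[1] ** 2)[None, :, None]
        + (ax[2] ** 2)[None, None, :]
    )
    region = out[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]]
    region |= q <= 1.0


def _random_cap_direction(rng, polar_max_deg: float) -> np.ndarray:
    """Random unit vector within a superior polar cap (toward +z)."""
    cos_min = math.cos(math.radians(polar_max_deg))
    cosp = rng.uniform(cos_min, 1.0)
    sinp = math.sqrt(1.0 - cosp**2)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([sinp * math.cos(phi), sinp * math.sin(phi), cosp])


@dataclass
class Phantom:
    """A rendered phantom case: planning-CT truth plus analytic geometry."""

    ct: ScalarVolume
    masks: dict[str, BinaryMask]
    geometry: PhantomGeometry
    truth: dict[str, float]


def make_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> Phantom:
    """Render a seeded head phantom on the planning-CT grid."""
    spec = spec or PhantomSpec()
    geom = PhantomGeometry(spec, seed=seed)
    grid = default_ct_grid(spec)
    ct = geom.render_hu(grid)
    masks = geom.render_masks(grid)
    truth = {"bone_fraction_in_ptv": geom.bone_fraction_in_ptv()}
    return Phantom(ct=ct, masks=masks, geometry=geom, truth=truth)


# ---------------------------------------------------------------------------
# sCT corruption


@dataclass(frozen=True)
class CorruptionSpec:
    """How the synthetic CT deviates from the planning-CT truth.

    The defaults are calibrated so that a default phantom corrupted with
    them reproduces clinically reported sCT error levels for this class of
    reconstruction (skull-bone MAE around 240 HU, brain MAE around 13 HU,
    skull DSC around 0.87).
    """

    bias_hu: float = 0.0
    noise_sigma_hu: float = 17.0
    interface_mislabel_prob: float = 0.45
    interface_shell_mm: float = 1.5
    #: correlation length of the mislabeling field; flips come in blobs of
    #: roughly this size rather than as independent voxels
    mislabel_correlation_mm: float = 2.5
    mislabel_drill_holes: bool = True
    mislabel_screws: bool = True
    mislabel_implant: bool = True
    bone_fill_hu: float = 1000.0     # HU painted onto mislabeled-as-bone voxels
    soft_fill_hu: float = 40.0       # HU painted onto missed-bone voxels
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.interface_mislabel_prob <= 1.0:
            raise ValueError("interface mislabel probability must be in [0, 1]")
        if self.noise_sigma_hu < 0 or self.interface_shell_mm < 0:
            raise ValueError("noise sigma and shell width must be >= 0")


def corrupt_to_sct(
    ct: ScalarVolume,
    geometry: PhantomGeometry,
    spec: CorruptionSpec | None = None,
    target_grid: VolumeGrid | None = None,
) -> ScalarVolume:
    """Produce the synthetic CT on the sCT grid from the planning-CT truth."""
    spec = spec or CorruptionSpec()
    spec.validate()
    grid = target_grid or default_sct_grid(geometry.spec)
    sct = resample(ct, grid, mode="trilinear")
    vals = sct.values
    rng = np.random.default_rng(spec.seed)

    feats = geometry.render_feature_masks(grid)
    body = feats["body"]

    if spec.bias_hu:
        vals[body] += np.float32(spec.bias_hu)
    if spec.noise_sigma_hu > 0:
        noise = rng.standard_normal(size=int(body.sum()), dtype=np.float32)
        vals[body] += np.float32(spec.noise_sigma_hu) * noise

    if spec.interface_mislabel_prob > 0 and spec.interface_shell_mm > 0:
        bone = feats["bone"]
        # separable box dilation/erosion (fast); the shell is the band of
        # voxels within the requested width of the bone boundary
        size = tuple(
            2 * max(int(spec.interface_shell_mm / s), 0) + 1 for s in grid.spacing
        )
        b8 = bone.view(np.uint8)
        shell = (ndimage.maximum_filter(b8, size=size) > 0) & ~(
            ndimage.minimum_filter(b8, size=size) > 0
        )
        shell &= body
        if shell.any():
            # spatially correlated flip field: threshold a smoothed Gaussian
            # field at the empirical quantile, so the marginal flip
            # probability inside the shell is exactly the requested one and
            # flips form blobs of roughly the correlation length
            sig = np.asarray(spec.mislabel_correlation_mm) / np.asarray(grid.spacing)
            u = ndimage.gaussian_filter(
                rng.standard_normal(size=grid.size, dtype=np.float32), sigma=sig
            )
            if spec.interface_mislabel_prob >= 1.0:
                flip = shell
            else:
                q = np.quantile(u[shell], 1.0 - spec.interface_mislabel_prob)
                flip = shell & (u > q)
            vals[flip & bone] = np.float32(spec.soft_fill_hu)
            vals[flip & ~bone] = np.float32(spec.bone_fill_hu)

    if spec.mislabel_drill_holes:
        vals[feats["drill_holes"]] = np.float32(spec.bone_fill_hu)
    if spec.mislabel_screws:
        vals[feats["screws"]] = np.float32(spec.bone_fill_hu)
    if spec.mislabel_implant:
        vals[feats["implant"]] = np.float32(spec.bone_fill_hu)

    np.clip(vals, -1000.0, 3100.0, out=vals)
    return ScalarVolume(grid, vals)
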