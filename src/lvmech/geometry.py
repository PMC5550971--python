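"""Idealized left-ventricular geometry, fibre architecture and infarct field.

The LV wall is a truncated prolate ellipsoid: the endocardial surface has
equatorial radius ``r_endo`` and long semi-axis ``l_endo`` (apex at
``Z = -l_endo``), the epicardial surface is offset by the equatorial wall
thickness and the apical thickness, and the ventricle is truncated by the
base plane ``Z = base_z``.  Quadrature points are laid out on a
(transmural x longitudinal x circumferential) grid in the ellipsoidal
parametrization; a thin cap around the apex pole is excluded from the
quadrature to avoid the coordinate singularity.

Myofibre and sheet orientations follow the rule-based construction: the
helix angle varies linearly through the wall from -60 deg at the
endocardium to +60 deg at the epicardium, the sheet angle from -45 deg to
+45 deg.

Strain bookkeeping uses 24 regions: four short-axis slices from the base
toward mid-ventricle, each divided into six circumferential sectors
following the AHA convention.

The infarct-extent field ``M`` is 1 inside a contiguous transmural scar
(parametrized by a circumferential center/half-angle and an apical extent),
0 in remote myocardium, and decays linearly over a transition band
(default 10 mm) around the scar boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .units import MM3_PER_ML

__all__ = ["LVGeometry", "LVMesh", "FiberField", "InfarctSpec", "InfarctMap",
           "build_geometry", "generate_fibers", "fiber_angles", "build_infarct",
           "healthy_infarct", "truncated_ellipsoid_volume"]

N_SLICES = 4
N_SECTORS = 6
N_SEGMENTS = N_SLICES * N_SECTORS


@dataclass(frozen=True)
class LVGeometry:
    """Dimensions (mm) and discretization of the idealized LV."""

    r_endo: float = 18.6        # equatorial endocardial radius
    l_endo: float = 62.0        # endocardial long semi-axis (apex depth)
    wall_thickness: float = 8.6   # equatorial wall thickness
    apex_thickness: float = 5.2   # apical wall thickness
    base_z: float = 18.6        # truncation height of the base plane above equator
    n_trans: int = 4            # transmural quadrature layers
    n_long: int = 14            # longitudinal quadrature points per layer
    n_circ: int = 18            # circumferential quadrature points
    mu_min: float = 0.40        # polar-angle cut excluding the apex cap (rad)
    slice_z_min: float = -10.4  # apical edge of the most apical strain slice

    def __post_init__(self) -> None:
        if min(self.r_endo, self.l_endo, self.wall_thickness, self.apex_thickness) <= 0:
            raise ValueError("geometry dimensions must be positive")
        if not 0 < self.base_z < self.l_endo:
            raise ValueError("base_z must lie strictly between 0 and l_endo")
        if self.slice_z_min >= self.base_z:
            raise ValueError("slice_z_min must lie below base_z")
        if min(self.n_trans, self.n_long, self.n_circ) < 2:
            raise ValueError("need at least 2 quadrature points per direction")

    def scaled(self, linear_scale: float) -> "LVGeometry":
        """Uniformly scale all linear dimensions (volumes scale cubically)."""
        d = asdict(self)
        for k in ("r_endo", "l_endo", "wall_thickness", "apex_thickness",
                  "base_z", "slice_z_min"):
            d[k] *= linear_scale
        return LVGeometry(**d)

    def to_yaml(self, path) -> None:
        import yaml
        from pathlib import Path
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "LVGeometry":
        import yaml
        from pathlib import Path
        return cls(**yaml.safe_load(Path(path).read_text()))


def truncated_ellipsoid_volume(r: float, l: float, z_base: float) -> float:
    """Closed-form volume (ml) of an ellipsoid of revolution with equatorial
    radius ``r`` and long semi-axis ``l``, truncated at ``Z = z_base``."""
    v = np.pi * r**2 * (z_base - z_base**3 / (3 * l**2) + 2 * l / 3)
    return float(v / MM3_PER_ML)


class LVMesh:
    """Quadrature-point layout of the LV wall with region bookkeeping.

    Arrays are flat over all quadrature points (length ``npts``):

    - ``R``, ``Z``, ``theta``: reference cylindrical coordinates (mm, rad)
    - ``u``: transmural coordinate in [0, 1] (0 endo, 1 epi)
    - ``w``: quadrature volume weights (mm^3), summing to the wall volume
    - ``e_c``, ``e_l``, ``e_r``: local circumferential / longitudinal /
      radial unit vectors in cylindrical components (R, Phi, Z)
    - ``segment``: 0..23 strain-region id, or -1 outside the imaged slices
    - ``midwall``: boolean mask of the mid-wall layer used for strains
    """

    def __init__(self, geom: LVGeometry):
        self.geom = geom
        g = geom
        u = (np.arange(g.n_trans) + 0.5) / g.n_trans
        du = 1.0 / g.n_trans
        dth = 2 * np.pi / g.n_circ
        theta_1d = (np.arange(g.n_circ) + 0.5) * dth

        pts = {k: [] for k in ("R", "Z", "theta", "u", "w", "layer")}
        basis = {k: [] for k in ("e_c", "e_l", "e_r")}
        for li, uk in enumerate(u):
            r_u = g.r_endo + uk * g.wall_thickness
            l_u = g.l_endo + uk * g.apex_thickness
            mu_base = np.arccos(-g.base_z / l_u)
            dv = 1.0 / g.n_long
            v = (np.arange(g.n_long) + 0.5) * dv
            mu = g.mu_min + v * (mu_base - g.mu_min)
            MU, TH = np.meshgrid(mu, theta_1d, indexing="ij")
            R = r_u * np.sin(MU)
            Z = -l_u * np.cos(MU)
            # tangent vectors of X(u, mu, theta) in cylindrical components
            X_u = np.stack([g.wall_thickness * np.sin(MU),
                            np.zeros_like(MU),
                            -g.apex_thickness * np.cos(MU)], axis=-1)
            X_mu = np.stack([r_u * np.cos(MU), np.zeros_like(MU), l_u * np.sin(MU)], axis=-1)
            X_th = np.stack([np.zeros_like(MU), R, np.zeros_like(MU)], axis=-1)
            det = np.abs(np.einsum("...i,...i->...", X_u, np.cross(X_mu, X_th)))
            w = det * (mu_base - g.mu_min) * du * dv * dth
            e_l = X_mu / np.linalg.norm(X_mu, axis=-1, keepdims=True)
            e_c = np.broadcast_to(np.array([0.0, 1.0, 0.0]), e_l.shape)
            e_r = np.cross(e_c, e_l)
            pts["R"].append(R.ravel())
            pts["Z"].append(Z.ravel())
            pts["theta"].append(TH.ravel())
            pts["u"].append(np.full(R.size, uk))
            pts["w"].append(w.ravel())
            pts["layer"].append(np.full(R.size, li))
            basis["e_c"].append(e_c.reshape(-1, 3))
            basis["e_l"].append(e_l.reshape(-1, 3))
            basis["e_r"].append(e_r.reshape(-1, 3))

        for k, v_ in pts.items():
            setattr(self, k, np.concatenate(v_))
        for k, v_ in basis.items():
            setattr(self, k, np.concatenate(v_))
        self.npts = self.R.size
        self.layer = self.layer.astype(int)
        self.midwall = self.layer == (g.n_trans // 2 if g.n_trans % 2 else g.n_trans // 2 - 1)

        # segment bookkeeping: 4 slices x 6 sectors between slice_z_min and base_z
        edges = np.linspace(g.slice_z_min, g.base_z, N_SLICES + 1)
        self.slice_edges = edges
        sl = np.digitize(self.Z, edges) - 1
        in_sl = (sl >= 0) & (sl < N_SLICES)
        sec = (self.theta // (2 * np.pi / N_SECTORS)).astype(int) % N_SECTORS
        # slice 0 is the most basal (AHA numbering runs base -> apex)
        self.segment = np.where(in_sl, (N_SLICES - 1 - sl) * N_SECTORS + sec, -1)

        self.wall_volume_ml = float(self.w.sum() / MM3_PER_ML)
        self.cavity_volume_ml = truncated_ellipsoid_volume(g.r_endo, g.l_endo, g.base_z)
        # d(R_i^2)/dZ / 2 = R_i R_i' used by the kinematic map
        self.Ri_sq = g.r_endo**2 * np.maximum(0.0, 1.0 - self.Z**2 / g.l_endo**2)

    def segment_points(self, seg: int) -> np.ndarray:
        """Indices of mid-wall quadrature points in strain region ``seg``."""
        return np.nonzero(self.midwall & (self.segment == seg))[0]


def build_geometry(geom: LVGeometry | None = None, **kwargs) -> LVMesh:
    """Construct the quadrature mesh for an :class:`LVGeometry`.

    Keyword arguments override the default geometry fields.
    """
    if geom is None:
        geom = LVGeometry(**kwargs)
    elif kwargs:
        geom = LVGeometry(**{**asdict(geom), **kwargs})
    return LVMesh(geom)


@dataclass
class FiberField:
    """Rule-based fibre/sheet orientations at every quadrature point.

    ``f0`` and ``s0`` are unit vectors in cylindrical components
    (R, Phi, Z); ``helix_deg`` / ``sheet_deg`` are the generating angles.
    """

    f0: np.ndarray
    s0: np.ndarray
    helix_deg: np.ndarray
    sheet_deg: np.ndarray


def fiber_angles(u, endo_angle: float = -60.0, epi_angle: float = 60.0,
                 sheet_endo: float = -45.0, sheet_epi: float = 45.0):
    """Helix and sheet angles (degrees) at transmural coordinate ``u``
    (0 = endocardium, 1 = epicardium), linearly interpolated."""
    u = np.asarray(u, float)
    return (endo_angle + (epi_angle - endo_angle) * u,
            sheet_endo + (sheet_epi - sheet_endo) * u)


def generate_fibers(mesh: LVMesh, endo_angle: float = -60.0, epi_angle: float = 60.0,
                    sheet_endo: float = -45.0, sheet_epi: float = 45.0) -> FiberField:
    """Linear transmural interpolation of helix and sheet angles (degrees).

    The fibre lies in the local (circumferential, longitudinal) tangent
    plane at the helix angle; the sheet vector is tilted out of the wall
    toward the radial direction by the sheet angle and is orthogonal to
    the fibre by construction.
    """
    hx, sh = fiber_angles(mesh.u, endo_angle, epi_angle, sheet_endo, sheet_epi)
    helix = np.deg2rad(hx)
    sheet = np.deg2rad(sh)
    f0 = np.cos(helix)[:, None] * mesh.e_c + np.sin(helix)[:, None] * mesh.e_l
    f0 /= np.linalg.norm(f0, axis=-1, keepdims=True)
    t = np.cross(f0, mesh.e_r)
    t /= np.linalg.norm(t, axis=-1, keepdims=True)
    s0 = np.cos(sheet)[:, None] * mesh.e_r + np.sin(sheet)[:, None] * t
    s0 /= np.linalg.norm(s0, axis=-1, keepdims=True)
    return FiberField(f0=f0, s0=s0, helix_deg=np.rad2deg(helix), sheet_deg=np.rad2deg(sheet))


@dataclass(frozen=True)
class InfarctSpec:
    """Parametrization of a contiguous transmural infarct.

    The scar core occupies circumferential positions within ``half_angle``
    of ``theta_center`` below the longitudinal level ``z_top`` (mm); the
    transition band extends ``band`` mm beyond the core boundary.
    """

    theta_center: float = 0.7853981633974483   # rad (pi/4)
    half_angle: float = 1.2     # rad (~69 deg half-width)
    z_top: float = 2.0          # mm; scar core lies at Z <= z_top
    band: float = 10.0          # transition bandwidth, mm


@dataclass
class InfarctMap:
    """Infarct extent per quadrature point plus per-segment classes."""

    M: np.ndarray
    segment_class: list          # one of "remote" | "transition" | "infarct" per segment
    volume_fraction: float       # M-weighted share of the wall volume
    spec: InfarctSpec

    @property
    def n_remote(self) -> int:
        return sum(c == "remote" for c in self.segment_class)

    def remote_segments(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.segment_class) if c == "remote"])


def healthy_infarct(mesh: LVMesh) -> InfarctMap:
    """An all-zero infarct map (healthy ventricle)."""
    return InfarctMap(M=np.zeros(mesh.npts), segment_class=["remote"] * N_SEGMENTS,
                      volume_fraction=0.0, spec=InfarctSpec(half_angle=0.0, z_top=-1e9))


def build_infarct(mesh: LVMesh, spec: InfarctSpec | None = None,
                  infarct_threshold: float = 0.5, remote_threshold: float = 0.05,
                  **kwargs) -> InfarctMap:
    """Evaluate the infarct-extent field ``M`` on the mesh.

    ``M`` is 1 in the scar core, 0 beyond the transition band, and decays
    linearly with the approximate in-wall distance to the core boundary.
    Each of the 24 strain regions is classified from its mean mid-wall M:
    infarct above ``infarct_threshold``, remote below ``remote_threshold``,
    transition in between.
    """
    if spec is None:
        spec = InfarctSpec(**kwargs)
    elif kwargs:
        spec = InfarctSpec(**{**asdict(spec), **kwargs})
    dth = np.abs((mesh.theta - spec.theta_center + np.pi) % (2 * np.pi) - np.pi)
    d_circ = np.maximum(0.0, dth - spec.half_angle) * mesh.R        # arc distance, mm
    d_long = np.maximum(0.0, mesh.Z - spec.z_top)                   # toward the base, mm
    dist = np.hypot(d_circ, d_long)
    M = np.clip(1.0 - dist / spec.band, 0.0, 1.0)

    frac = float(np.sum(M * mesh.w) / np.sum(mesh.w))
    if not 0.0 < frac < 1.0:
        raise ValueError(
            f"infarct spec yields degenerate wall-volume fraction {frac:.3f}; "
            "core must cover part but not all of the wall")

    classes = []
    for seg in range(N_SEGMENTS):
        idx = mesh.segment_points(seg)
        m = float(M[idx].mean()) if idx.size else 0.0
        if m > infarct_threshold:
            classes.append("infarct")
        elif m < remote_threshold:
            classes.append("remote")
        else:
            classes.append("transition")
    return InfarctMap(M=M, segment_class=classes, volume_fraction=frac, spec=spec)
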