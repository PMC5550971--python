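"""Reduced-order quasi-static equilibrium model of the left ventricle.

The imaging-scale ventricle is represented by a truncated-ellipsoid wall
(:mod:`lvmech.geometry`) deforming under a kinematic ansatz that is
exactly incompressible at every point.  In reference cylindrical
coordinates (R, Theta, Z) the deformed position is

    z   = lambda_z Z                       (global axial stretch)
    phi = Theta + tau(Z)                   (linear base-to-apex twist)
    r   = sqrt(R^2 / lambda_z + s(Z, Theta))

where the inflation field ``s`` (mm^2) controls the local cavity area.
The deformation gradient of this map is triangular in the cylindrical
basis and has unit determinant identically, so incompressibility holds
pointwise by construction.  ``s`` is pinned to zero at the apex, varies
piecewise-linearly over three longitudinal knots, and carries an extra
degree of freedom localized on the infarct (scaled by the infarct weight)
so that a non-contracting scar can bulge while remote muscle shortens.

Equilibrium at a given cavity pressure is found by minimizing the total
potential energy

    Pi = int_wall [ (1 + 49 M) Psi_HO + T_a ln(lambda_f) ] dV  -  P V_cav

over the ansatz degrees of freedom (lambda_z, three inflation knots,
apical twist, infarct bulge).  The active term ``T_a ln lambda_f`` is the
work-conjugate potential of the rank-one active Cauchy stress
``T_a fhat (x) fhat``; during systole the active tension field is coupled
to the kinetics model by fixed-point iteration (tension frozen within
each inner minimization, then recomputed from the updated fibre-stretch
history until the cavity volume settles).

Cavity volume is an analytic function of the degrees of freedom, and the
24 segmental circumferential strains are mid-wall circumferential
stretches (engineering strain; end-diastolic reference for systole).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import constitutive as con
from .activation import ActiveConfig, simulate_activation, tension_scaling
from .geometry import LVMesh, FiberField, InfarctMap, N_SEGMENTS, N_SLICES
from .units import mmhg_to_kpa, MM3_PER_ML

__all__ = ["LVState", "SolverError", "solve_diastole", "solve_systole",
           "summarize_biomarkers"]


class SolverError(RuntimeError):
    """Raised when the equilibrium search fails to converge."""


@dataclass
class LVState:
    """A converged deformed configuration of the reduced model."""

    dofs: np.ndarray                 # scaled ansatz degrees of freedom
    volume_ml: float                 # cavity volume
    strains: np.ndarray              # 24 segmental circumferential strains
    lambda_f: np.ndarray             # fibre stretch field (vs unloaded)
    lambda_c: np.ndarray             # mid-wall circumferential stretch field
    T_a: np.ndarray                  # active tension field (kPa)
    C_kin: np.ndarray                # myofilament scaling field at evaluation time
    sigma_f: np.ndarray              # total fibre stress field (kPa)
    twist_deg: np.ndarray            # per-slice twist relative to the base
    apex_twist_deg: float
    max_J_dev: float                 # max |J - 1| over quadrature points
    pressure_mmhg: float
    converged: bool = True
    objective: float = 0.0
    phase: str = "diastole"

    def summary_dict(self) -> dict:
        """Scalars and per-region values of the state (JSON-serializable)."""
        return {
            "phase": self.phase,
            "pressure_mmhg": self.pressure_mmhg,
            "volume_ml": float(self.volume_ml),
            "strains": [float(s) for s in self.strains],
            "twist_deg": [float(t) for t in self.twist_deg],
            "apex_twist_deg": self.apex_twist_deg,
            "max_J_dev": self.max_J_dev,
            "converged": self.converged,
        }

    def save(self, json_path, csv_path=None) -> None:
        """Dump the state summary as JSON and, optionally, the 24-region
        strain table as CSV."""
        import json
        from pathlib import Path
        Path(json_path).write_text(json.dumps(self.summary_dict(), indent=2))
        if csv_path is not None:
            import pandas as pd
            slices = np.repeat(np.arange(1, N_SLICES + 1), 6)
            sectors = np.tile(np.arange(1, 7), N_SLICES)
            pd.DataFrame({"segment": np.arange(24), "slice": slices,
                          "sector": sectors, "strain": self.strains}
                         ).to_csv(csv_path, index=False)


class _Ansatz:
    """Kinematic ansatz and potential-energy evaluation on a mesh."""

    # dof scaling: optimizer works in O(1) variables
    SCALE = {"lam_z": 0.1, "s": 100.0, "tau": 0.2, "s_mi": 100.0}

    def __init__(self, mesh: LVMesh, fibers: FiberField, infarct: InfarctMap,
                 params: con.PassiveParams):
        self.mesh = mesh
        self.fibers = fibers
        self.infarct = infarct
        self.params = params
        g = mesh.geom
        self.L = g.base_z + g.l_endo
        self.knots_z = np.array([-g.l_endo,
                                 -g.l_endo + 0.35 * self.L,
                                 -g.l_endo + 0.70 * self.L,
                                 g.base_z])
        self.with_mi = infarct.volume_fraction > 0.0
        self.ndof = 6 if self.with_mi else 5
        # fine grid for the analytic cavity-volume integral of the MI bulge
        if self.with_mi:
            Zg = np.linspace(-g.l_endo, g.base_z, 241)
            Tg = np.linspace(0, 2 * np.pi, 181, endpoint=False)
            ZZ, TT = np.meshgrid(Zg, Tg, indexing="ij")
            W = self._w_mi(ZZ, TT)
            # integrate over theta (uniform grid, periodic) then Z
            self._I_mi = float(np.trapezoid(W.sum(1) * (2 * np.pi / Tg.size), Zg))
        else:
            self._I_mi = 0.0

    # -- infarct bulge weight -------------------------------------------------
    def _w_mi(self, Z, theta):
        sp = self.infarct.spec
        g = self.mesh.geom
        r_m = g.r_endo + 0.5 * g.wall_thickness
        l_m = g.l_endo + 0.5 * g.apex_thickness
        R_mid = r_m * np.sqrt(np.maximum(0.0, 1.0 - np.minimum(Z**2 / l_m**2, 1.0)))
        dth = np.abs((theta - sp.theta_center + np.pi) % (2 * np.pi) - np.pi)
        d_circ = np.maximum(0.0, dth - sp.half_angle) * R_mid
        d_long = np.maximum(0.0, Z - sp.z_top)
        w = np.clip(1.0 - np.hypot(d_circ, d_long) / sp.band, 0.0, 1.0)
        taper = np.clip((Z + g.l_endo) / 6.0, 0.0, 1.0)  # keep the apex closed
        return w * taper

    # -- dof packing ----------------------------------------------------------
    def unpack(self, x):
        lam_z = 1.0 + self.SCALE["lam_z"] * x[0]
        s_k = self.SCALE["s"] * np.asarray(x[1:4])
        tau_apex = self.SCALE["tau"] * x[4]
        s_mi = self.SCALE["s_mi"] * x[5] if self.with_mi else 0.0
        return lam_z, s_k, tau_apex, s_mi

    def x0(self):
        return np.zeros(self.ndof)

    def bounds(self):
        b = [(-2.5, 3.5)]          # lambda_z in [0.75, 1.35]
        for zk in self.knots_z[1:]:
            g = self.mesh.geom
            ri2 = g.r_endo**2 * max(0.0, 1.0 - zk**2 / g.l_endo**2)
            b.append((-0.92 * ri2 / (1.35 * self.SCALE["s"]), 6.0))
        b.append((-3.0, 3.0))      # tau_apex in [-0.6, 0.6] rad
        if self.with_mi:
            b.append((-2.0, 4.0))
        return b

    # -- kinematics -----------------------------------------------------------
    def _s_field(self, x, Z, theta):
        lam_z, s_k, _, s_mi = self.unpack(x)
        s = np.interp(Z, self.knots_z, np.concatenate([[0.0], s_k]))
        if self.with_mi and s_mi != 0.0:
            s = s + s_mi * self._w_mi(Z, theta)
        return s

    def deformation(self, x):
        """Deformation gradient (n,3,3) in the cylindrical basis plus the
        circumferential and fibre stretches."""
        m = self.mesh
        lam_z, s_k, tau_apex, s_mi = self.unpack(x)
        Z, R, th = m.Z, m.R, m.theta
        s = self._s_field(x, Z, th)
        f2 = R**2 / lam_z + s
        if np.any(f2 <= 1.0):
            return None
        r = np.sqrt(f2)
        dZ, dth = 0.25, 0.005
        ds_dZ = (self._s_field(x, Z + dZ, th) - self._s_field(x, Z - dZ, th)) / (2 * dZ)
        ds_dth = (self._s_field(x, Z, th + dth) - self._s_field(x, Z, th - dth)) / (2 * dth)
        tau_p = -tau_apex / self.L

        F = np.zeros((m.npts, 3, 3))
        F[:, 0, 0] = R / (lam_z * r)
        F[:, 0, 1] = ds_dth / (2 * r * R)
        F[:, 0, 2] = ds_dZ / (2 * r)
        F[:, 1, 1] = r / R
        F[:, 1, 2] = r * tau_p
        F[:, 2, 2] = lam_z
        lam_c = np.sqrt(F[:, 0, 1] ** 2 + F[:, 1, 1] ** 2)
        f_cur = np.einsum("nij,nj->ni", F, self.fibers.f0)
        lam_f = np.linalg.norm(f_cur, axis=-1)
        return F, lam_c, lam_f

    def cavity_volume_ml(self, x):
        lam_z, s_k, _, s_mi = self.unpack(x)
        s_int = np.trapezoid(np.concatenate([[0.0], s_k]), self.knots_z)
        v = self.mesh.cavity_volume_ml * MM3_PER_ML + lam_z * (
            np.pi * s_int + 0.5 * s_mi * self._I_mi)
        return v / MM3_PER_ML

    # -- energy ---------------------------------------------------------------
    def potential(self, x, p_kpa: float, active=None):
        """Total potential energy (microjoule): strain + active - pressure work.

        ``active`` is an optional pair (``_ActiveTable``, amplitude field
        ``T_req (1 - M)``) supplying the tabulated active potential.
        """
        kin = self.deformation(x)
        if kin is None:
            return 1e12
        F, _, lam_f = kin
        psi = con.elastic_energy(self.params, F, self.fibers.f0, self.fibers.s0,
                                 self.infarct.M)
        w_int = float(np.sum(self.mesh.w * psi))
        if active is not None:
            table, amp = active
            w_int += float(np.sum(self.mesh.w * amp * table.G(lam_f)))
        return w_int - p_kpa * self.cavity_volume_ml(x) * MM3_PER_ML

    def minimize(self, p_kpa: float, active=None, x0=None):
        x0 = self.x0() if x0 is None else np.asarray(x0, float)
        res = minimize(self.potential, x0, args=(p_kpa, active), method="L-BFGS-B",
                       bounds=self.bounds(),
                       options={"maxiter": 400, "ftol": 1e-12, "gtol": 1e-8})
        if not np.isfinite(res.fun):
            raise SolverError(f"equilibrium search diverged: {res.message}")
        return res

    # -- state assembly -------------------------------------------------------
    def make_state(self, x, p_mmhg, active_cfg=None, C_kin=None, T_a=None,
                   lam_c_ref=None, phase="diastole", objective=0.0,
                   converged=True) -> LVState:
        m = self.mesh
        F, lam_c, lam_f = self.deformation(x)
        J = np.linalg.det(F)
        if T_a is None:
            T_a = np.zeros(m.npts)
        if C_kin is None:
            C_kin = np.zeros(m.npts)
        ratio = lam_c / (lam_c_ref if lam_c_ref is not None else 1.0)
        strains = np.full(N_SEGMENTS, np.nan)
        for seg in range(N_SEGMENTS):
            idx = m.segment_points(seg)
            if idx.size:
                strains[seg] = float(np.mean(ratio[idx])) - 1.0
        sig_p = con.passive_cauchy_stress(self.params, _Frame(F, self.fibers), self.infarct.M)
        sigma_f = con.fiber_stress(sig_p, _Frame(F, self.fibers)) + T_a

        _, _, tau_apex, _ = self.unpack(x)
        edges = m.slice_edges
        zc = 0.5 * (edges[:-1] + edges[1:])[::-1]   # slice 0 = most basal
        twist = np.rad2deg(tau_apex * (m.geom.base_z - zc) / self.L)
        apex_twist = float(np.rad2deg(tau_apex * (m.geom.base_z + m.geom.l_endo) / self.L))
        return LVState(
            dofs=np.array(x, float), volume_ml=self.cavity_volume_ml(x),
            strains=strains, lambda_f=lam_f, lambda_c=lam_c, T_a=np.asarray(T_a),
            C_kin=np.asarray(C_kin), sigma_f=sigma_f, twist_deg=twist,
            apex_twist_deg=apex_twist, max_J_dev=float(np.max(np.abs(J - 1.0))),
            pressure_mmhg=float(p_mmhg), phase=phase, objective=objective,
            converged=converged)


class _Frame:
    """Array-of-points view with the attributes the stress routines read."""

    def __init__(self, F, fibers: FiberField):
        self.F = F
        self.f0 = fibers.f0
        self.s0 = fibers.s0


def solve_diastole(mesh: LVMesh, fibers: FiberField, infarct: InfarctMap,
                   params: con.PassiveParams, edp_mmhg: float,
                   x0=None) -> LVState:
    """Inflate the unloaded ventricle to the end-diastolic pressure.

    Returns the end-diastolic state; strains are referred to the unloaded
    configuration.
    """
    if edp_mmhg < 0:
        raise ValueError("end-diastolic pressure must be nonnegative")
    ans = _Ansatz(mesh, fibers, infarct, params)
    res = ans.minimize(mmhg_to_kpa(edp_mmhg), x0=x0)
    return ans.make_state(res.x, edp_mmhg, phase="diastole", objective=float(res.fun),
                          converged=bool(res.success))


class _ActiveTable:
    """Tabulated myofilament response along linear stretch ramps.

    For a ramp from end-diastolic stretch ``lam_ed`` to end-systolic
    stretch ``lam_es`` over the systolic interval, the kinetics make the
    end-systolic scaling ``C`` a plain function C(lam_ed, lam_es).  The
    active Cauchy stress T_req (1-M) C fhat(x)fhat then derives from the
    potential ``T_req (1-M) G`` with ``G(lam_ed, lam) = int C/l dl``,
    which lets systolic equilibrium be found by a single energy
    minimization instead of a tension/deformation fixed point.
    """

    N_ED, N_ES = 9, 61
    LAM_LO, LAM_HI = 0.55, 1.45

    def __init__(self, cfg: ActiveConfig, lam_ed: np.ndarray):
        self.cfg = cfg
        lo = min(self.LAM_LO, float(np.min(lam_ed)) - 0.02)
        hi = max(self.LAM_HI, float(np.max(lam_ed)) + 0.02)
        self.le_grid = np.linspace(lo, hi, self.N_ES)
        ed_lo, ed_hi = float(np.min(lam_ed)), float(np.max(lam_ed))
        pad = max(1e-3, 0.01 * (ed_hi - ed_lo + 1.0))
        self.led_grid = np.linspace(ed_lo - pad, ed_hi + pad, self.N_ED)
        LED, LES = np.meshgrid(self.led_grid, self.le_grid, indexing="ij")
        kin = simulate_activation(cfg, LES.ravel(), lam_start=LED.ravel())
        self.C_tab = tension_scaling(kin, cfg).reshape(LED.shape)
        # G(led, lam) = cumulative integral of C/l dl along the lam axis
        integrand = self.C_tab / self.le_grid
        dl = np.diff(self.le_grid)
        G = np.zeros_like(self.C_tab)
        G[:, 1:] = np.cumsum(0.5 * (integrand[:, 1:] + integrand[:, :-1]) * dl, axis=1)
        self.G_tab = G
        # per-point row interpolation weights in lam_ed
        i = np.clip(np.searchsorted(self.led_grid, lam_ed) - 1, 0, self.N_ED - 2)
        t = (lam_ed - self.led_grid[i]) / (self.led_grid[i + 1] - self.led_grid[i])
        self._row_i = i
        self._row_t = np.clip(t, 0.0, 1.0)

    def _interp(self, tab, lam):
        lam = np.clip(lam, self.le_grid[0], self.le_grid[-1])
        j = np.clip(np.searchsorted(self.le_grid, lam) - 1, 0, self.le_grid.size - 2)
        u = (lam - self.le_grid[j]) / (self.le_grid[j + 1] - self.le_grid[j])
        i, t = self._row_i, self._row_t
        lo = tab[i, j] * (1 - u) + tab[i, j + 1] * u
        hi = tab[i + 1, j] * (1 - u) + tab[i + 1, j + 1] * u
        return lo * (1 - t) + hi * t

    def G(self, lam):
        return self._interp(self.G_tab, lam)

    def C(self, lam):
        return self._interp(self.C_tab, lam)


def solve_systole(mesh: LVMesh, fibers: FiberField, infarct: InfarctMap,
                  params: con.PassiveParams, active_cfg: ActiveConfig,
                  sbp_mmhg: float, ed_state: LVState, x0=None) -> LVState:
    """End-systolic equilibrium under the systolic cavity pressure.

    The active tension at each point is T_req * C(lambda_f, z) * (1 - M)
    with the kinetics integrated along the point's fibre-stretch ramp from
    its end-diastolic value; the kinetics are folded into the equilibrium
    search through the tabulated active potential (:class:`_ActiveTable`),
    so deformation and activation are solved consistently in one
    minimization.  Systolic strains are referred to end-diastole.
    """
    if sbp_mmhg < 0:
        raise ValueError("systolic pressure must be nonnegative")
    ans = _Ansatz(mesh, fibers, infarct, params)
    p_sys = mmhg_to_kpa(sbp_mmhg)
    M = infarct.M
    lam_ed = ed_state.lambda_f
    x = np.array(ed_state.dofs if x0 is None else x0, float)
    if x.size != ans.ndof:   # healthy ED state reused with an infarct map
        x = np.concatenate([x, np.zeros(ans.ndof - x.size)])
    table = _ActiveTable(active_cfg, lam_ed)
    amp = active_cfg.T_req * (1.0 - M)
    res = ans.minimize(p_sys, active=(table, amp), x0=x)
    _, _, lam_es = ans.deformation(res.x)
    kin = simulate_activation(active_cfg, lam_es, lam_start=lam_ed)
    C = tension_scaling(kin, active_cfg)
    T_a = active_cfg.T_req * C * (1.0 - M)
    return ans.make_state(res.x, sbp_mmhg, C_kin=C, T_a=T_a, lam_c_ref=ed_state.lambda_c,
                          phase="systole", objective=float(res.fun),
                          converged=bool(res.success))


def summarize_biomarkers(mesh: LVMesh, infarct: InfarctMap, sys_state: LVState,
                         sbp_mmhg: float) -> dict:
    """Wall-averaged biomechanical biomarkers of the systolic state.

    Averages of active tension and fibre stress are taken over functional
    myocardium (M < 0.5), weighted by the quadrature volumes; normalized
    values divide by the systolic blood pressure (kPa/mmHg).
    """
    mask = infarct.M < 0.5
    w = mesh.w * mask
    wsum = float(w.sum())
    T_a = float(np.sum(w * sys_state.T_a) / wsum)
    sigma_f = float(np.sum(w * sys_state.sigma_f) / wsum)
    C_s = float(np.sum(w * sys_state.C_kin) / wsum)
    return {
        "T_a": T_a,
        "sigma_f": sigma_f,
        "T_a_norm": float(con.normalize_by_sbp(T_a, sbp_mmhg)),
        "sigma_f_norm": float(con.normalize_by_sbp(sigma_f, sbp_mmhg)),
        "C_s": C_s,
    }
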