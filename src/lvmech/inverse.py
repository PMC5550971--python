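"""Inverse estimation of passive stiffness and contractility.

Subject-specific material parameters are determined by matching the
forward model to per-subject "measurements": cavity volume and the 24
segmental circumferential strains.  The goodness-of-fit objective is a
weighted least-squares mismatch

    f = sum_i ((eps_i - eps_i^meas) / w_eps)^2 + ((V - V^meas) / w_V)^2

with strain scale ``w_eps = 0.05`` and volume scale ``w_V = 10 ml`` so
both terms are O(1) at typical mismatch.  For infarcted ventricles only
the remote (unaffected) segments enter the strain sum, since scar and
transition tissue have prescribed properties (50-fold stiffer,
non-contractile) rather than fitted ones.

Estimation is staged as in practice:

1. passive fit (diastole): a global stiffness scale on all eight
   Holzapfel--Ogden coefficients is matched to the end-diastolic volume,
   then a myofibre-term scale to the diastolic strains, then a joint
   derivative-free polish (:func:`fit_passive`);
2. active fit (systole): the contractility T_req is found by bounded 1-D
   minimization of the systolic objective (:func:`fit_contractility`).

All optimizers are deterministic; given identical inputs the results are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .activation import ActiveConfig
from .constitutive import PassiveParams
from .geometry import LVMesh, FiberField, InfarctMap, N_SEGMENTS
from .mechanics import LVState, solve_diastole, solve_systole

__all__ = ["MeasurementSet", "FitResult", "objective", "fit_passive",
           "fit_contractility", "STRAIN_SCALE", "VOLUME_SCALE_ML"]

STRAIN_SCALE: float = 0.05
VOLUME_SCALE_ML: float = 10.0


@dataclass
class MeasurementSet:
    """Per-subject measurement block used as the inverse-problem target."""

    edv: float
    esv: float
    strains_dia: np.ndarray      # 24 diastolic strains (unloaded reference)
    strains_sys: np.ndarray      # 24 systolic strains (end-diastolic reference)
    segment_class: list          # "remote" | "transition" | "infarct" per segment
    edp: float                   # mmHg
    sbp: float                   # mmHg

    def __post_init__(self) -> None:
        self.strains_dia = np.asarray(self.strains_dia, float)
        self.strains_sys = np.asarray(self.strains_sys, float)
        for s in (self.strains_dia, self.strains_sys):
            if s.shape != (N_SEGMENTS,):
                raise ValueError(f"expected {N_SEGMENTS} segmental strains")
        if not (np.all(np.isfinite(self.strains_dia)) and np.all(np.isfinite(self.strains_sys))):
            raise ValueError("strains must be finite")

    def remote_mask(self) -> np.ndarray:
        return np.array([c == "remote" for c in self.segment_class])


@dataclass
class FitResult:
    """Outcome of an inverse fit."""

    params: PassiveParams | None = None
    stiffness_scale: float = 1.0
    fiber_scale: float = 1.0
    T_req: float = 0.0
    objective_value: float = np.nan
    trace: list = field(default_factory=list)   # (parameter, objective) pairs
    converged: bool = False
    n_solves: int = 0


def objective(meas: MeasurementSet, model_out: LVState, mode: str = "healthy") -> float:
    """Volume + segmental-strain mismatch between model state and measurements.

    The diastolic phase is scored against (EDV, diastolic strains), the
    systolic phase against (ESV, systolic strains).  In ``mi`` mode only
    remote segments contribute strain terms.
    """
    if mode not in ("healthy", "mi"):
        raise ValueError("mode must be 'healthy' or 'mi'")
    if model_out.phase == "diastole":
        v_meas, s_meas = meas.edv, meas.strains_dia
    else:
        v_meas, s_meas = meas.esv, meas.strains_sys
    s_model = model_out.strains
    if mode == "mi":
        mask = meas.remote_mask()
        if not mask.any():
            raise ValueError("mi-mode objective requires at least one remote segment")
    else:
        mask = np.ones(N_SEGMENTS, bool)
    ds = (s_model[mask] - s_meas[mask]) / STRAIN_SCALE
    dv = (model_out.volume_ml - v_meas) / VOLUME_SCALE_ML
    return float(np.sum(ds**2) + dv**2)


def fit_passive(meas: MeasurementSet, mesh: LVMesh, fibers: FiberField,
                infarct: InfarctMap, init: PassiveParams,
                mode: str = "healthy", scale_bounds=(0.2, 5.0),
                polish_iters: int = 40) -> FitResult:
    """Multi-step passive parameter estimation from diastolic data.

    Step 1 matches a global stiffness scale (all eight coefficients) to
    the end-diastolic volume; step 2 matches a myofibre-pair (a_f, b_f)
    scale to the diastolic strains; step 3 polishes both scales jointly
    with a Nelder--Mead search on the full diastolic objective.
    """
    trace: list = []
    counter = {"n": 0}

    def run(q_all: float, q_f: float) -> LVState:
        counter["n"] += 1
        p = init.scaled(stiffness_scale=q_all, fiber_scale=q_f)
        return solve_diastole(mesh, fibers, infarct, p, meas.edp)

    def vol_obj(q_all):
        st = run(q_all, 1.0)
        val = ((st.volume_ml - meas.edv) / VOLUME_SCALE_ML) ** 2
        trace.append((("q_all", float(q_all)), val))
        return val

    r1 = minimize_scalar(vol_obj, bounds=scale_bounds, method="bounded",
                         options={"xatol": 1e-3})
    q_all = float(r1.x)

    def strain_obj(q_f):
        st = run(q_all, q_f)
        mask = meas.remote_mask() if mode == "mi" else np.ones(N_SEGMENTS, bool)
        val = float(np.sum(((st.strains[mask] - meas.strains_dia[mask]) / STRAIN_SCALE) ** 2))
        trace.append((("q_f", float(q_f)), val))
        return val

    r2 = minimize_scalar(strain_obj, bounds=scale_bounds, method="bounded",
                         options={"xatol": 1e-3})
    q_f = float(r2.x)

    def joint_obj(q):
        qa = float(np.clip(q[0], *scale_bounds))
        qf = float(np.clip(q[1], *scale_bounds))
        st = run(qa, qf)
        val = objective(meas, st, mode)
        trace.append((("joint", qa, qf), val))
        return val

    r3 = minimize(joint_obj, x0=[q_all, q_f], method="Nelder-Mead",
                  options={"maxiter": polish_iters, "xatol": 1e-3, "fatol": 1e-8})
    q_all, q_f = (float(np.clip(v, *scale_bounds)) for v in r3.x)
    return FitResult(
        params=init.scaled(stiffness_scale=q_all, fiber_scale=q_f),
        stiffness_scale=q_all, fiber_scale=q_f,
        objective_value=float(r3.fun), trace=trace,
        converged=bool(np.isfinite(r3.fun)), n_solves=counter["n"])


def fit_contractility(meas: MeasurementSet, mesh: LVMesh, fibers: FiberField,
                      infarct: InfarctMap, params: PassiveParams,
                      active_cfg: ActiveConfig | None = None,
                      mode: str = "healthy", bounds=(0.0, 400.0),
                      xatol: float = 0.1) -> FitResult:
    """Estimate T_req by matching end-systolic volume and systolic strains.

    Bounded 1-D minimization of the systolic objective over T_req (kPa);
    the end-diastolic state is solved once with the supplied passive
    parameters and reused.  Returns the optimum and the objective trace.
    """
    base = active_cfg if active_cfg is not None else ActiveConfig.default()
    ed_state = solve_diastole(mesh, fibers, infarct, params, meas.edp)
    trace: list = []
    counter = {"n": 1}

    def obj(T_req: float) -> float:
        # every trial starts the equilibrium search from the end-diastolic
        # dofs so the objective is a path-independent function of T_req
        counter["n"] += 1
        cfg = ActiveConfig.from_dict({**base.to_dict(), "T_req": float(T_req)})
        st = solve_systole(mesh, fibers, infarct, params, cfg, meas.sbp, ed_state)
        val = objective(meas, st, mode)
        trace.append((float(T_req), val))
        return val

    res = minimize_scalar(obj, bounds=bounds, method="bounded",
                          options={"xatol": xatol})
    vals = [v for _, v in trace]
    spread = max(vals) - min(vals) if vals else 0.0
    return FitResult(params=params, T_req=float(res.x),
                     objective_value=float(res.fun), trace=trace,
                     converged=bool(res.success and spread > 1e-12),
                     n_solves=counter["n"])
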