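"""Synthetic cohort generation calibrated to the published group statistics.

The study population the package emulates -- 27 healthy controls and 11
acute-MI patients with CMR-derived measurements -- is not publicly
deposited, so every downstream stage (inverse estimation, classification,
association analysis) is exercised on synthetic subjects instead.  Two
generation modes are provided:

* **calibrated mode** draws per-subject biomechanical feature vectors
  (T_req, T_a, SBP, EDV, C^s, T_a^norm, sigma_f, sigma_f^norm) from
  group-conditional truncated multivariate normals whose marginal means
  and SDs are the published cohort statistics; the within-group
  correlation structure is a documented assumption of the generator.

* **pipeline mode** samples ground-truth contractility and loading per
  subject, runs the forward ventricle model, and reports the resulting
  volumes and segmental strains (with configurable observation noise) as
  the subject's "measurements" -- the input the inverse stage consumes.

Six-month surrogate outcomes (LVEF change, follow-up GLS) are generated
with configurable population correlations against baseline T_req, C^s and
GLS.  All sampling is reproducible given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .activation import ActiveConfig
from .constitutive import PassiveParams
from .geometry import (LVGeometry, LVMesh, FiberField, InfarctMap, build_geometry,
                       build_infarct, generate_fibers, healthy_infarct, N_SEGMENTS)
from .inverse import MeasurementSet
from .mechanics import solve_diastole, solve_systole, summarize_biomarkers

__all__ = ["CohortConfig", "SyntheticSubject", "FEATURES", "DATASETS",
           "generate_features", "generate_feature_table", "generate_outcomes",
           "generate_subject", "generate_cohort", "nearest_psd"]

FEATURES = ["T_req", "T_a", "SBP", "EDV", "C_s", "T_a_norm",
            "sigma_f", "sigma_f_norm"]

#: Classification feature sets: D1 is the full biomechanical panel, D2
#: drops the normalized ratios, D3 drops SBP and T_req (their effects are
#: carried by T_a_norm and C_s).
DATASETS = {
    "D1": ["T_req", "T_a", "SBP", "EDV", "C_s", "T_a_norm"],
    "D2": ["T_req", "T_a", "SBP", "EDV"],
    "D3": ["T_a", "EDV", "C_s", "T_a_norm"],
}

# hard physical bounds applied on top of the +-k SD truncation
_PHYS_BOUNDS = {
    "T_req": (0.0, np.inf), "T_a": (0.0, np.inf), "SBP": (1.0, np.inf),
    "EDV": (1.0, np.inf), "C_s": (0.0, 1.0), "T_a_norm": (0.0, np.inf),
    "sigma_f": (0.0, np.inf), "sigma_f_norm": (0.0, np.inf),
    "age": (18.0, 110.0), "DBP": (1.0, np.inf), "LVEF": (1.0, 85.0),
    "GLS": (-45.0, 0.0), "CS": (-0.6, 0.0), "infarct_size": (1.0, 75.0),
    "MVO": (0.0, 60.0),
}

_DATA_DIR = Path(__file__).parent / "data"


def nearest_psd(R: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest correlation-like PSD matrix
    (eigenvalue clipping followed by unit-diagonal rescaling)."""
    w, V = np.linalg.eigh((R + R.T) / 2)
    R2 = (V * np.maximum(w, eps)) @ V.T
    d = np.sqrt(np.diag(R2))
    return R2 / np.outer(d, d)


class CohortConfig:
    """Configuration of the synthetic generator (see ``data/cohort_default.yaml``).

    Construct with :meth:`default` or from a YAML file / dict; edits to the
    correlation block are validated and, if necessary, repaired to the
    nearest positive semi-definite matrix with a warning.
    """

    def __init__(self, raw: dict):
        self.raw = raw
        self.n_healthy = int(raw["n_healthy"])
        self.n_mi = int(raw["n_mi"])
        self.truncation_sd = float(raw.get("truncation_sd", 4.0))
        for grp in ("healthy", "mi"):
            feats = raw["groups"][grp]["features"]
            for name, (mu, sd) in feats.items():
                if sd <= 0:
                    raise ValueError(f"SD of {name} in group {grp} must be positive")
        self.corr = self._build_corr(raw.get("correlations", {}))

    @classmethod
    def default(cls) -> "CohortConfig":
        return cls(yaml.safe_load((_DATA_DIR / "cohort_default.yaml").read_text()))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        return cls(yaml.safe_load(Path(path).read_text()))

    def _build_corr(self, spec: dict) -> np.ndarray:
        p = len(FEATURES)
        R = np.full((p, p), float(spec.get("default", 0.2)))
        np.fill_diagonal(R, 1.0)
        for a, b, r in spec.get("pairs", []):
            i, j = FEATURES.index(a), FEATURES.index(b)
            R[i, j] = R[j, i] = float(r)
        if np.min(np.linalg.eigvalsh(R)) < -1e-10:
            warnings.warn("feature correlation matrix is not PSD; "
                          "repairing with nearest-PSD projection")
            R = nearest_psd(R)
        return R

    def group(self, name: str) -> dict:
        return self.raw["groups"][name]

    def moments(self, name: str):
        feats = self.group(name)["features"]
        mu = np.array([feats[f][0] for f in FEATURES])
        sd = np.array([feats[f][1] for f in FEATURES])
        return mu, sd

    def outcome_cfg(self) -> dict:
        return self.raw["outcomes"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _sample_truncated_mvn(mu, sd, corr, bounds_lo, bounds_hi, n, rng, k_sd):
    """Rejection-sample an MVN with per-coordinate truncation at +-k_sd SD
    and hard physical bounds."""
    cov = corr * np.outer(sd, sd)
    L = np.linalg.cholesky(cov + 1e-12 * np.diag(sd**2))
    lo = np.maximum(mu - k_sd * sd, bounds_lo)
    hi = np.minimum(mu + k_sd * sd, bounds_hi)
    if np.any(lo >= hi):
        raise ValueError("impossible truncation bounds for the configured moments")
    out = np.empty((n, mu.size))
    got = 0
    for _ in range(1000):
        m = max(n - got, 64)
        draw = mu + rng.standard_normal((m, mu.size)) @ L.T
        ok = np.all((draw >= lo) & (draw <= hi), axis=1)
        acc = draw[ok]
        take = min(acc.shape[0], n - got)
        out[got:got + take] = acc[:take]
        got += take
        if got == n:
            return out
    raise RuntimeError("truncated-normal rejection sampling failed to converge")


def generate_features(cfg: CohortConfig, group: str, n: int, seed=None) -> pd.DataFrame:
    """Calibrated-mode feature vectors for one group.

    Draws ``n`` subjects from the group-conditional truncated MVN over
    :data:`FEATURES` and returns them with a ``label`` column.
    """
    rng = _as_rng(seed)
    mu, sd = cfg.moments(group)
    lo = np.array([_PHYS_BOUNDS[f][0] for f in FEATURES])
    hi = np.array([_PHYS_BOUNDS[f][1] for f in FEATURES])
    X = _sample_truncated_mvn(mu, sd, cfg.corr, lo, hi, n, rng, cfg.truncation_sd)
    df = pd.DataFrame(X, columns=FEATURES)
    df.insert(0, "label", group)
    return df


def _sample_extra(cfg: CohortConfig, group: str, n: int, rng) -> pd.DataFrame:
    cols = {}
    for name, (mu, sd) in cfg.group(group).get("extra", {}).items():
        lo, hi = _PHYS_BOUNDS.get(name, (-np.inf, np.inf))
        lo = max(lo, mu - cfg.truncation_sd * sd)
        hi = min(hi, mu + cfg.truncation_sd * sd)
        v = np.empty(n)
        got = 0
        while got < n:
            draw = mu + sd * rng.standard_normal(max(n - got, 64))
            acc = draw[(draw >= lo) & (draw <= hi)]
            take = min(acc.size, n - got)
            v[got:got + take] = acc[:take]
            got += take
        cols[name] = v
    return pd.DataFrame(cols)


def generate_feature_table(cfg: CohortConfig | None = None, n_healthy=None,
                           n_mi=None, seed=None, extra: bool = False) -> pd.DataFrame:
    """Calibrated-mode cohort table: both groups, subject ids, features.

    With ``extra=True`` the clinical covariates (age, LVEF, GLS, ...) are
    appended; derived ESV = EDV (1 - LVEF/100) keeps volumes coherent.
    """
    cfg = cfg or CohortConfig.default()
    rng = _as_rng(seed)
    n_h = cfg.n_healthy if n_healthy is None else int(n_healthy)
    n_m = cfg.n_mi if n_mi is None else int(n_mi)
    parts = []
    for grp, n in (("healthy", n_h), ("mi", n_m)):
        if n == 0:
            continue
        df = generate_features(cfg, grp, n, rng)
        if extra:
            df = pd.concat([df.reset_index(drop=True),
                            _sample_extra(cfg, grp, n, rng)], axis=1)
            df["ESV"] = df["EDV"] * (1.0 - df["LVEF"] / 100.0)
        parts.append(df)
    out = pd.concat(parts, ignore_index=True)
    out.insert(0, "subject_id", [f"S{i:05d}" for i in range(len(out))])
    return out


def dataset_columns(name: str) -> list:
    """Feature columns of classification dataset D1, D2 or D3."""
    if name not in DATASETS:
        raise ValueError(f"unknown dataset {name!r}; expected one of {sorted(DATASETS)}")
    return list(DATASETS[name])


def outcome_loadings(rho: float, r1: float, r2: float):
    """Loadings (b1, b2, sigma_noise) such that Y = b1 Z1 + b2 Z2 + noise
    has unit variance and corr(Y, Z1) = r1, corr(Y, Z2) = r2 when
    corr(Z1, Z2) = rho.  Raises if the correlation triple is infeasible."""
    den = 1.0 - rho**2
    if den <= 0:
        raise ValueError("predictor correlation must lie strictly inside (-1, 1)")
    b1 = (r1 - rho * r2) / den
    b2 = (r2 - rho * r1) / den
    r2_tot = b1**2 + b2**2 + 2 * b1 * b2 * rho
    if r2_tot > 1.0 + 1e-12:
        raise ValueError(
            f"infeasible correlation triple: corr(Y,Z1)={r1}, corr(Y,Z2)={r2} "
            f"with corr(Z1,Z2)={rho} requires explained variance {r2_tot:.3f} > 1; "
            "adjust the outcome correlations or the T_req-C_s feature correlation")
    return b1, b2, float(np.sqrt(max(0.0, 1.0 - r2_tot)))


def generate_outcomes(cfg: CohortConfig | None, table: pd.DataFrame,
                      seed=None) -> pd.DataFrame:
    """Attach six-month surrogate outcomes to a feature table.

    ``dLVEF6`` (LVEF change at six months) is a linear combination of the
    standardized baseline T_req (negative loading) and C^s (positive
    loading) plus Gaussian noise, with loadings solved so the population
    correlations equal the configured targets.  If a baseline ``GLS``
    column is present, follow-up ``GLS6`` is generated analogously.
    Standardization uses the configured group moments, so the targets are
    population values within each group.
    """
    cfg = cfg or CohortConfig.default()
    for c in ("T_req", "C_s"):
        if c not in table.columns:
            raise ValueError(f"outcome generation requires feature column {c!r}")
    rng = _as_rng(seed)
    oc = cfg.outcome_cfg()["dLVEF6"]
    out = table.copy()
    i_tr, i_cs = FEATURES.index("T_req"), FEATURES.index("C_s")
    rho = float(cfg.corr[i_tr, i_cs])
    b1, b2, s_eps = outcome_loadings(rho, float(oc["corr_T_req"]), float(oc["corr_C_s"]))
    y = np.empty(len(out))
    for grp in out["label"].unique():
        m = (out["label"] == grp).to_numpy()
        mu, sd = cfg.moments(grp)
        z1 = (out.loc[m, "T_req"].to_numpy() - mu[i_tr]) / sd[i_tr]
        z2 = (out.loc[m, "C_s"].to_numpy() - mu[i_cs]) / sd[i_cs]
        y[m] = b1 * z1 + b2 * z2 + s_eps * rng.standard_normal(m.sum())
    out["dLVEF6"] = oc["mean"] + oc["sd"] * y

    if "GLS" in out.columns:
        gc = cfg.outcome_cfg()["GLS6"]
        r = float(gc["corr_GLS"])
        yg = np.empty(len(out))
        for grp in out["label"].unique():
            m = (out["label"] == grp).to_numpy()
            mu_g, sd_g = cfg.group(grp)["extra"]["GLS"]
            zg = (out.loc[m, "GLS"].to_numpy() - mu_g) / sd_g
            yg[m] = r * zg + np.sqrt(1 - r**2) * rng.standard_normal(m.sum())
        out["GLS6"] = gc["mean"] + gc["sd"] * yg
    return out


# ---------------------------------------------------------------------------
# pipeline mode: forward-model-backed subjects
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSubject:
    """One pipeline-mode subject: ground truth plus forward measurements."""

    group: str
    measurements: MeasurementSet
    t_req_true: float
    passive_params: PassiveParams
    geometry_scale: float
    mesh: LVMesh
    fibers: FiberField
    infarct: InfarctMap
    biomarkers: dict = field(default_factory=dict)

    @property
    def n_remote(self) -> int:
        return self.infarct.n_remote


_BASE_EDV_CACHE: dict = {}


def _base_edv(group: str, params: PassiveParams, edp: float) -> float:
    """End-diastolic volume of the unscaled default geometry (cached)."""
    key = (group, round(edp, 3), tuple(sorted(params.to_dict().items())))
    if key not in _BASE_EDV_CACHE:
        mesh = build_geometry()
        fib = generate_fibers(mesh)
        inf = build_infarct(mesh) if group == "mi" else healthy_infarct(mesh)
        st = solve_diastole(mesh, fib, inf, params, edp)
        _BASE_EDV_CACHE[key] = st.volume_ml
    return _BASE_EDV_CACHE[key]


def generate_subject(cfg: CohortConfig | None = None, group: str = "healthy",
                     seed=None, noise: float = 0.0, t_req=None, sbp=None,
                     edv_target=None, active_cfg: ActiveConfig | None = None,
                     ) -> SyntheticSubject:
    """Build one pipeline-mode subject and its measurement block.

    Ground-truth contractility, SBP and target EDV default to draws from
    the group marginals (or may be pinned explicitly, e.g. for noise-free
    recovery experiments).  The geometry is scaled isotropically so the
    forward model's EDV matches the target; measurements are the forward
    model's volumes and strains with relative observation noise ``noise``
    (0 = exact).
    """
    cfg = cfg or CohortConfig.default()
    rng = _as_rng(seed)
    feats = cfg.group(group)["features"]
    edp = float(cfg.group(group)["edp"])
    t_req = float(t_req if t_req is not None else
                  max(1.0, rng.normal(*feats["T_req"])))
    sbp = float(sbp if sbp is not None else max(60.0, rng.normal(*feats["SBP"])))
    edv_target = float(edv_target if edv_target is not None else
                       max(40.0, rng.normal(*feats["EDV"])))
    params = PassiveParams.mi_remote() if group == "mi" else PassiveParams.healthy()
    base_edv = _base_edv(group, params, edp)
    k = (edv_target / base_edv) ** (1.0 / 3.0)
    mesh = build_geometry(LVGeometry().scaled(k))
    fibers = generate_fibers(mesh)
    infarct = build_infarct(mesh) if group == "mi" else healthy_infarct(mesh)
    acfg = active_cfg or ActiveConfig.default()
    acfg = ActiveConfig.from_dict({**acfg.to_dict(), "T_req": t_req})

    ed = solve_diastole(mesh, fibers, infarct, params, edp)
    es = solve_systole(mesh, fibers, infarct, params, acfg, sbp, ed)
    bm = summarize_biomarkers(mesh, infarct, es, sbp)

    def jitter(x):
        return x * (1.0 + noise * rng.standard_normal(np.shape(x))) if noise else x

    meas = MeasurementSet(
        edv=float(jitter(ed.volume_ml)), esv=float(jitter(es.volume_ml)),
        strains_dia=jitter(ed.strains), strains_sys=jitter(es.strains),
        segment_class=list(infarct.segment_class), edp=edp, sbp=sbp)
    return SyntheticSubject(group=group, measurements=meas, t_req_true=t_req,
                            passive_params=params, geometry_scale=k, mesh=mesh,
                            fibers=fibers, infarct=infarct, biomarkers=bm)


def generate_cohort(cfg: CohortConfig | None = None, seed=None,
                    noise: float = 0.0, n_healthy=None, n_mi=None) -> list:
    """Pipeline-mode cohort: a list of :class:`SyntheticSubject`.

    Sizes default to the configured 27 healthy / 11 MI.  Reproducible
    given the seed; with ``noise=0`` the measurement blocks equal the
    forward-model outputs exactly.
    """
    cfg = cfg or CohortConfig.default()
    rng = _as_rng(seed)
    n_h = cfg.n_healthy if n_healthy is None else int(n_healthy)
    n_m = cfg.n_mi if n_mi is None else int(n_mi)
    subjects = []
    for grp, n in (("healthy", n_h), ("mi", n_m)):
        for _ in range(n):
            subjects.append(generate_subject(cfg, grp, rng, noise=noise))
    return subjects
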