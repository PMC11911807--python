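"""Data containers, readers/writers and configuration handling.

Input data are two CSV tables:

* a *marker* table in long format with columns ``id``, ``time`` (years since
  baseline), ``y`` (marker on the analysis scale) -- a row exists iff a visit
  with a measurement occurred;
* a *subject* table with columns ``id``, ``T`` (follow-up time, years),
  ``cause`` (0 = noninformatively right-censored, 1..K = event cause) and
  baseline covariate columns.

Times are in years; visit times must be strictly increasing within subject
and the follow-up time must not precede the last visit.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("jointvisit")

__all__ = ["SubjectRecord", "read_data", "write_data", "validate_config",
           "default_config", "config_hash"]


@dataclass
class SubjectRecord:
    """One subject's visits, marker values, follow-up and covariates."""

    id: object
    times: np.ndarray
    y: np.ndarray
    T: float
    cause: int
    covariates: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.times.ndim != 1 or self.y.shape != self.times.shape:
            raise ValueError(f"subject {self.id}: times and y must be 1-d and equal length")
        if self.times.size == 0:
            raise ValueError(f"subject {self.id}: at least one visit is required")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"subject {self.id}: visit times must be strictly increasing")
        if self.T < self.times[-1] - 1e-12:
            raise ValueError(
                f"subject {self.id}: follow-up T={self.T} precedes last visit {self.times[-1]}")

    @property
    def n_visits(self) -> int:
        return int(self.times.shape[0])


def read_data(marker_path, subject_path, covariate_cols: Optional[Sequence[str]] = None
              ) -> List[SubjectRecord]:
    """Read and validate the long-format marker table and the subject table.

    ``covariate_cols`` restricts which subject-table columns become baseline
    covariates; by default every column other than id/T/cause is used.
    """
    mk = pd.read_csv(marker_path)
    sb = pd.read_csv(subject_path)
    for col in ("id", "time", "y"):
        if col not in mk.columns:
            raise ValueError(f"marker table lacks required column {col!r}")
    for col in ("id", "T", "cause"):
        if col not in sb.columns:
            raise ValueError(f"subject table lacks required column {col!r}")
    if sb["id"].duplicated().any():
        dup = sb.loc[sb["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate subject id {dup!r} in subject table")
    if mk.duplicated(["id", "time"]).any():
        row = mk[mk.duplicated(["id", "time"])].iloc[0]
        raise ValueError(f"duplicate (id, time) pair ({row['id']!r}, {row['time']})")
    mk_ids = set(mk["id"])
    sb_ids = set(sb["id"])
    if mk_ids != sb_ids:
        only = (mk_ids - sb_ids) or (sb_ids - mk_ids)
        raise ValueError(f"subjects present in only one table, e.g. {sorted(only)[:5]}")
    cov_cols = list(covariate_cols) if covariate_cols is not None else \
        [c for c in sb.columns if c not in ("id", "T", "cause")]
    records = []
    for _, srow in sb.iterrows():
        sub = mk[mk["id"] == srow["id"]].sort_values("time")
        records.append(SubjectRecord(
            id=srow["id"],
            times=sub["time"].to_numpy(dtype=float),
            y=sub["y"].to_numpy(dtype=float),
            T=float(srow["T"]),
            cause=int(srow["cause"]),
            covariates={c: float(srow[c]) for c in cov_cols},
        ))
    causes = sorted({r.cause for r in records if r.cause > 0})
    logger.info("read %d subjects, %d visits, events per cause: %s",
                len(records), sum(r.n_visits for r in records),
                {k: sum(r.cause == k for r in records) for k in causes})
    return records


def write_data(records: Sequence[SubjectRecord], marker_path, subject_path) -> None:
    """Write records back to the two-CSV layout (inverse of read_data)."""
    mk_rows = [(r.id, t, y) for r in records for t, y in zip(r.times, r.y)]
    pd.DataFrame(mk_rows, columns=["id", "time", "y"]).to_csv(marker_path, index=False)
    cov_names = sorted({k for r in records for k in r.covariates})
    sb_rows = [
        {"id": r.id, "T": r.T, "cause": r.cause, **{c: r.covariates.get(c, np.nan) for c in cov_names}}
        for r in records
    ]
    pd.DataFrame(sb_rows).to_csv(subject_path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "marker": {"basis": "cd4", "q": 3},
    "visit": {
        "enabled": True,
        "scale": "gap",
        "n_knots": 3,
        "gamma_features": [],
        "phi_features": ["last_y"],
        "assoc_m0": True,
        "assoc_slope": True,
        "frailty": False,
        "prev_gap_center": 0.15,
    },
    "causes": [],
    "quadrature": {"kind": "GH", "nodes": 7, "draws": 500, "seed": 0,
                   "prune": 1e-10},
    "optimizer": {"gtol": 1e-5, "maxiter": 500},
    "seed": 0,
}

_CAUSE_DEFAULTS = {
    "n_knots": 1,
    "gamma_features": [],
    "phi_features": ["last_y"],
    "assoc_m0": True,
    "assoc_slope": True,
    "prev_gap_center": 0.15,
}


def _merge(defaults: dict, user: dict, path: str) -> dict:
    out = {}
    for key, val in user.items():
        if key not in defaults:
            hint = difflib.get_close_matches(key, defaults.keys(), n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"unknown config key {path}{key!r}{extra}")
    for key, dval in defaults.items():
        uval = user.get(key, dval)
        if isinstance(dval, dict) and isinstance(uval, dict):
            out[key] = _merge(dval, uval, f"{path}{key}.")
        else:
            out[key] = uval
    return out


def default_config() -> dict:
    import copy

    return copy.deepcopy(_DEFAULTS)


def validate_config(config: Optional[dict]) -> dict:
    """Fill defaults, reject unknown keys and contradictory settings; the
    resolved config is echoed into every output artifact for provenance."""
    config = config or {}
    causes_user = config.get("causes", [])
    cfg = _merge({k: v for k, v in _DEFAULTS.items() if k != "causes"},
                 {k: v for k, v in config.items() if k != "causes"}, "")
    cfg["causes"] = [_merge(_CAUSE_DEFAULTS, c, f"causes[{i}].")
                     for i, c in enumerate(causes_user)]
    vis = cfg["visit"]
    if vis["enabled"]:
        if vis["scale"] not in ("gap", "calendar"):
            raise ValueError("visit.scale must be 'gap' or 'calendar'")
        if vis["frailty"] is False and "eta" in config.get("visit", {}):
            raise ValueError("visit.eta given but frailty disabled")
    if cfg["quadrature"]["kind"] not in ("GH", "QMC"):
        raise ValueError("quadrature.kind must be 'GH' or 'QMC'")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of a resolved configuration (for provenance)."""
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# model construction from a resolved config + data
# ---------------------------------------------------------------------------

def build_model(cfg: Optional[dict], data: Sequence[SubjectRecord]):
    """Instantiate a :class:`jointvisit.estimation.JointModel` from a config.

    Spline knots are data-driven: interior knots at equally spaced quantiles
    of the observed gap times (gap scale) or visit/event times (calendar
    scale), boundary knots at 0 and the observed maximum.
    """
    from .estimation import JointModel
    from .hazards import CauseModel, SplineBasis, VisitProcessModel
    from .lmm import cd4_preset_basis

    cfg = validate_config(cfg)
    if cfg["marker"]["basis"] != "cd4":
        raise ValueError(f"unknown marker basis preset {cfg['marker']['basis']!r}")
    basis = cd4_preset_basis()
    q = int(cfg["marker"]["q"])
    p = basis.X(0.0, {}).shape[1]

    max_T = max(float(r.T) for r in data)
    visit_model = None
    vis = cfg["visit"]
    if vis["enabled"]:
        if vis["scale"] == "gap":
            gaps = np.concatenate([
                np.diff(np.append(r.times, r.T)) for r in data])
            spline = SplineBasis.from_times(gaps, n_interior=int(vis["n_knots"]))
        else:
            arrivals = np.concatenate([r.times[1:] for r in data])
            if arrivals.size == 0:
                arrivals = np.array([max_T])
            spline = SplineBasis.from_times(
                np.append(arrivals, max_T), n_interior=int(vis["n_knots"]))
        visit_model = VisitProcessModel(
            scale=vis["scale"], spline=spline,
            gamma_features=list(vis["gamma_features"]),
            phi_features=list(vis["phi_features"]),
            assoc_m0=bool(vis["assoc_m0"]), assoc_slope=bool(vis["assoc_slope"]),
            frailty=bool(vis["frailty"]),
            prev_gap_center=float(vis["prev_gap_center"]))

    cause_models = []
    for k, ccfg in enumerate(cfg["causes"], start=1):
        ev_times = np.array([r.T for r in data if r.cause == k], dtype=float)
        if ev_times.size < 4:
            ev_times = np.array([r.T for r in data], dtype=float)
        spline = SplineBasis.from_times(
            np.append(ev_times, max_T), n_interior=int(ccfg["n_knots"]))
        cause_models.append(CauseModel(
            spline=spline, gamma_features=list(ccfg["gamma_features"]),
            phi_features=list(ccfg["phi_features"]),
            assoc_m0=bool(ccfg["assoc_m0"]), assoc_slope=bool(ccfg["assoc_slope"]),
            prev_gap_center=float(ccfg["prev_gap_center"])))

    from .integration import QuadratureRule

    qd = cfg["quadrature"]
    rule = QuadratureRule(kind=qd["kind"], n_nodes=int(qd["nodes"]),
                          n_draws=int(qd["draws"]), seed=int(qd["seed"]),
                          prune=float(qd["prune"]))
    return JointModel(marker_basis=basis, q=q, p=p, visit_model=visit_model,
                      cause_models=cause_models, rule=rule)
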