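"""Agreement scoring between back-calculated and experimental relaxation data.

Per observable: the same cosine distance used for cluster-population vectors,
plus RMSE and MAE.  The combined score is the (by default unweighted) mean of
the per-observable cosine distances; ensembles are ranked ascending by it.
NOE values, which can be negative for flexible residues, are shifted by +1
before cosine scoring so all components are non-negative (raw values are used
for RMSE/MAE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import cosine_distance
from .io_core import RelaxationTable

DEFAULT_OBSERVABLES = ("R1", "R2", "NOE", "eta_xy")
#: Shift applied to NOE vectors before cosine scoring (keeps components >= 0).
NOE_COSINE_SHIFT = 1.0


def match_probes(
    calc: RelaxationTable,
    exp: RelaxationTable,
    observable: str,
    probe: str = "backbone_NH",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair calculated and experimental values on common, finite probes.

    Returns (residues, calc_values, exp_values) in ascending residue order.
    Requires at least 3 common probes.
    """
    c = calc.select(observable, probe).dropna(subset=["value"])
    e = exp.select(observable, probe).dropna(subset=["value"])
    merged = c.merge(e, on="residue", suffixes=("_calc", "_exp"))
    merged = merged[np.isfinite(merged["value_calc"]) & np.isfinite(merged["value_exp"])]
    if len(merged) < 3:
        raise ValueError(
            f"only {len(merged)} common probes for {observable}; need >= 3"
        )
    merged = merged.sort_values("residue")
    return (
        merged["residue"].to_numpy(),
        merged["value_calc"].to_numpy(float),
        merged["value_exp"].to_numpy(float),
    )


def cosine_score(
    calc: RelaxationTable,
    exp: RelaxationTable,
    observables=DEFAULT_OBSERVABLES,
    weights: dict | None = None,
) -> tuple[dict, float]:
    """Per-observable cosine distances and their (weighted) mean.

    Observables absent from either table are skipped; the combined score
    averages over those available.
    """
    per_obs = {}
    for obs in observables:
        try:
            _, c, e = match_probes(calc, exp, obs)
        except ValueError:
            continue
        if obs == "NOE":
            c = c + NOE_COSINE_SHIFT
            e = e + NOE_COSINE_SHIFT
        if np.any(c < 0) or np.any(e < 0):
            raise ValueError(f"negative components in {obs} vectors; cosine undefined")
        per_obs[obs] = cosine_distance(c, e)
    if not per_obs:
        raise ValueError("no observable had enough matched probes")
    if weights:
        w = np.array([weights.get(o, 1.0) for o in per_obs])
    else:
        w = np.ones(len(per_obs))
    combined = float(np.average(list(per_obs.values()), weights=w))
    return per_obs, combined


def error_metrics(
    calc: RelaxationTable,
    exp: RelaxationTable,
    observables=DEFAULT_OBSERVABLES,
) -> dict:
    """Per-observable RMSE and MAE in the observable's own units."""
    out = {}
    for obs in observables:
        try:
            _, c, e = match_probes(calc, exp, obs)
        except ValueError:
            continue
        diff = c - e
        out[obs] = {
            "rmse": float(np.sqrt(np.mean(diff**2))),
            "mae": float(np.mean(np.abs(diff))),
        }
    return out


@dataclass
class ScoreReport:
    """Agreement of one candidate ensemble with the experimental table."""

    ensemble_id: str
    cosine_per_observable: dict
    combined_score: float
    rmse_per_observable: dict
    mae_per_observable: dict
    rank: int | None = None

    def to_rows(self) -> list[dict]:
        rows = []
        for obs, d in self.cosine_per_observable.items():
            rows.append({
                "ensemble": self.ensemble_id, "observable": obs,
                "cosine_distance": d,
                "rmse": self.rmse_per_observable.get(obs, np.nan),
                "mae": self.mae_per_observable.get(obs, np.nan),
            })
        return rows


def score_ensemble(
    ensemble_id: str,
    calc: RelaxationTable,
    exp: RelaxationTable,
    observables=DEFAULT_OBSERVABLES,
    weights: dict | None = None,
) -> ScoreReport:
    per_obs, combined = cosine_score(calc, exp, observables, weights)
    errs = error_metrics(calc, exp, observables)
    return ScoreReport(
        ensemble_id=ensemble_id,
        cosine_per_observable=per_obs,
        combined_score=combined,
        rmse_per_observable={o: v["rmse"] for o, v in errs.items()},
        mae_per_observable={o: v["mae"] for o, v in errs.items()},
    )


def rank_ensembles(reports: list[ScoreReport]) -> list[ScoreReport]:
    """Rank ascending by combined cosine score (1 = best agreement).

    Ties are broken by mean z-scored RMSE across observables, then by
    ensemble id.  Input order does not affect the result.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 ensembles to rank")
    obs_all = sorted({o for r in reports for o in r.rmse_per_observable})
    z_mean = {}
    for r in reports:
        zs = []
        for obs in obs_all:
            vals = np.array([q.rmse_per_observable.get(obs, np.nan) for q in reports])
            ok = np.isfinite(vals)
            mu, sd = vals[ok].mean(), vals[ok].std()
            v = r.rmse_per_observable.get(obs, np.nan)
            if np.isfinite(v):
                zs.append((v - mu) / sd if sd > 0 else 0.0)
        z_mean[r.ensemble_id] = float(np.mean(zs)) if zs else 0.0
    ordered = sorted(
        reports, key=lambda r: (r.combined_score, z_mean[r.ensemble_id], r.ensemble_id)
    )
    out = []
    for i, r in enumerate(ordered):
        out.append(ScoreReport(**{**r.__dict__, "rank": i + 1}))
    return out


def reports_to_frame(reports: list[ScoreReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        for row in r.to_rows():
            row["combined_score"] = r.combined_score
            row["rank"] = r.rank
            rows.append(row)
    return pd.DataFrame(rows)
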