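"""Back-calculation of NMR spin-relaxation observables from bond-vector dynamics.

Chain: internal P2 autocorrelation of unit bond vectors (after removing global
tumbling by superposition) -> constrained multi-exponential model-free fit
C_I(t) = S^2 + sum_i A_i exp(-t/tau_i), S^2 + sum A_i = 1 -> Lorentzian
spectral density with isotropic overall tumbling tau_c,

    J(w) = (2/5) [ S^2 tau_c/(1+(w tau_c)^2) + sum_i A_i tau_i'/(1+(w tau_i')^2) ],
    1/tau_i' = 1/tau_i + 1/tau_c,

-> standard 15N Redfield expressions for R1, R2, heteronuclear NOE and the
transverse CSA/dipole cross-correlation rate eta_xy, plus methyl 13C R1/Gamma2
from the methyl symmetry-axis spectral density.

Conventions (documented, config-exposed): r_NH = 1.02 A, 15N CSA -170 ppm,
CSA/dipole angle 17 deg, methyl C-H vs symmetry-axis angle 110.5 deg;
eta_xy = (1/6) d c P2(cos theta) [4J(0) + 3J(wN)] with d the dipolar and
c = |Dsigma| wN / sqrt(3) the CSA interaction constants (magnitudes);
Gamma2 = (d_CH^2/8) [4J_eff(0) + 3J_eff(wC)] with J_eff = [P2(cos beta)]^2 J_axis.
Uncertainties by circular block bootstrap over trajectory blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io_core import RegionSpec, TrajectoryRecord
from .synthetic import PlantedTruth

MU0_OVER_4PI = 1e-7          # T m / A
HBAR = 1.054571817e-34       # J s
GAMMA_H = 2.6752218744e8     # rad/s/T
GAMMA_N = -2.7126189e7
GAMMA_C = 6.728284e7


def p2(x):
    """Second Legendre polynomial P2(x) = (3x^2 - 1)/2."""
    return 1.5 * np.asarray(x) ** 2 - 0.5


@dataclass
class NmrConstants:
    """Interaction constants and geometry for the Redfield expressions."""

    field_mhz: float = 900.0
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N
    gamma_c: float = GAMMA_C
    r_nh_angstrom: float = 1.02
    r_ch_angstrom: float = 1.115
    csa_n_ppm: float = -170.0
    csa_dipole_angle_deg: float = 17.0
    methyl_axis_angle_deg: float = 110.5

    def __post_init__(self):
        if self.field_mhz <= 0 or self.r_nh_angstrom <= 0:
            raise ValueError("field and bond length must be positive")

    @property
    def omega_h(self) -> float:
        return 2 * np.pi * self.field_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """|w_N| in rad/s (spectral densities are even)."""
        return self.omega_h * abs(self.gamma_n) / self.gamma_h

    @property
    def omega_c(self) -> float:
        return self.omega_h * abs(self.gamma_c) / self.gamma_h

    @property
    def d_nh(self) -> float:
        """N-H dipolar interaction constant magnitude (rad/s)."""
        r = self.r_nh_angstrom * 1e-10
        return MU0_OVER_4PI * HBAR * self.gamma_h * abs(self.gamma_n) / r**3

    @property
    def d_ch(self) -> float:
        r = self.r_ch_angstrom * 1e-10
        return MU0_OVER_4PI * HBAR * self.gamma_h * abs(self.gamma_c) / r**3

    @property
    def c_n(self) -> float:
        """15N CSA interaction constant magnitude c = |Dsigma| wN / sqrt(3) (rad/s)."""
        return abs(self.csa_n_ppm) * 1e-6 * self.omega_n / np.sqrt(3.0)

    @property
    def c_c(self) -> float:
        return abs(self.csa_n_ppm) * 1e-6 * self.omega_c / np.sqrt(3.0)


# ---------------------------------------------------------------------------
# ACF
# ---------------------------------------------------------------------------

@dataclass
class AcfCurve:
    """P2 bond-vector autocorrelation values on a lag grid, one row per probe."""

    lags_ns: np.ndarray          # strictly increasing, lags_ns[0] == 0
    values: np.ndarray           # (n_probes, n_lags)
    probe_ids: list              # residue numbers or methyl group labels
    n_origins: np.ndarray        # origins averaged per lag

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if abs(self.lags_ns[0]) > 1e-12:
            raise ValueError("lag grid must start at 0")
        if np.max(np.abs(self.values[:, 0] - 1.0)) > 1e-9:
            raise ValueError("C(0) must equal 1")

    def for_probe(self, probe_id) -> np.ndarray:
        return self.values[self.probe_ids.index(probe_id)]


def default_lag_grid(dt_ns: float, max_lag_ns: float, n_per_decade: int = 12,
                     report_lags_ns: Sequence[float] = ()) -> np.ndarray:
    """Log-spaced lag grid (multiples of dt) from dt to max_lag, plus 0 and any
    requested report lags that fall on the sampling grid."""
    lo, hi = np.log10(dt_ns), np.log10(max_lag_ns)
    n = max(int((hi - lo) * n_per_decade) + 1, 8)
    lags = np.unique(np.round(np.logspace(lo, hi, n) / dt_ns).astype(int))
    extra = [int(round(l / dt_ns)) for l in report_lags_ns if l <= max_lag_ns + 1e-9]
    lags = np.unique(np.concatenate([[0], lags, extra]))
    return lags[lags * dt_ns <= max_lag_ns + 1e-9] * dt_ns


def vector_acf_p2(
    vectors: np.ndarray,
    dt_ns: float,
    lags_ns: np.ndarray,
    probe_ids: list | None = None,
) -> AcfCurve:
    """Origin-averaged internal ACF C_I(t) = <P2(u(t0) . u(t0+t))> per probe.

    ``vectors``: (n_steps, n_probes, 3) unit vectors; lags must be integer
    multiples of dt.  Direct origin averaging at the requested lags.
    """
    u = np.asarray(vectors, dtype=float)
    T, N, _ = u.shape
    lag_idx = np.round(np.asarray(lags_ns) / dt_ns).astype(int)
    if np.max(np.abs(lag_idx * dt_ns - lags_ns)) > 1e-9 * max(dt_ns, 1):
        raise ValueError("lags must be integer multiples of the sampling interval")
    if lag_idx.max() >= T:
        raise ValueError("max lag exceeds series length")
    vals = np.empty((N, len(lag_idx)))
    n_origins = np.empty(len(lag_idx), dtype=int)
    for k, ell in enumerate(lag_idx):
        if ell == 0:
            dots = np.einsum("tnc,tnc->tn", u, u)
        else:
            dots = np.einsum("tnc,tnc->tn", u[:-ell], u[ell:])
        vals[:, k] = p2(dots).mean(axis=0)
        n_origins[k] = T - ell
    ids = probe_ids if probe_ids is not None else list(range(N))
    return AcfCurve(np.asarray(lags_ns, dtype=float), vals, ids, n_origins)


def extract_nh_vectors(
    traj: TrajectoryRecord, superpose: bool = True
) -> tuple[np.ndarray, list[int]]:
    """Unit N-H bond vectors per residue after superposing frames on the N atoms.

    Residues lacking an amide H (prolines, termini) are skipped.  Returns
    (vectors (n_frames, n_residues, 3), residue_numbers).
    """
    from .conformation import superpose_kabsch

    at = traj.atom_table.df
    n_rows = at[at["atom_name"] == "N"]
    pairs, residues = [], []
    for i, row in n_rows.iterrows():
        h = at[(at["residue_number"] == row["residue_number"])
               & (at["atom_name"].isin(["H", "HN"]))]
        if len(h) == 1:
            pairs.append((i, h.index[0]))
            residues.append(int(row["residue_number"]))
    if not pairs:
        raise ValueError("no N-H probe pairs found in the atom table")
    coords = traj.coordinates
    if superpose and traj.n_frames > 1:
        n_idx = np.array([p[0] for p in pairs])
        ref = coords[0]
        coords = coords.copy()
        for f in range(traj.n_frames):
            fit = superpose_kabsch(coords[f], ref, n_idx)
            coords[f] = fit.apply(coords[f])
    vec = np.stack(
        [coords[:, hi] - coords[:, ni] for ni, hi in pairs], axis=1
    )
    vec /= np.linalg.norm(vec, axis=-1, keepdims=True)
    return vec, residues


def bond_vector_acf(
    traj: TrajectoryRecord,
    max_lag_ns: float | None = None,
    report_lags_ns: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    lags_ns: np.ndarray | None = None,
) -> AcfCurve:
    """Internal N-H ACF of a trajectory (global tumbling removed by superposition).

    ``max_lag_ns`` defaults to half the trajectory duration; the lag grid is
    log-spaced with the conventional report lags (0.1, 1, 10, 100 ns) included
    where they fit.
    """
    vec, residues = extract_nh_vectors(traj)
    dt = traj.spacing_ns()
    if max_lag_ns is None:
        max_lag_ns = traj.duration_ns / 2
    if max_lag_ns > traj.duration_ns / 2 + 1e-9:
        raise ValueError("max lag exceeds half the trajectory duration")
    if lags_ns is None:
        lags_ns = default_lag_grid(dt, max_lag_ns, report_lags_ns=report_lags_ns)
    return vector_acf_p2(vec, dt, lags_ns, probe_ids=residues)


# ---------------------------------------------------------------------------
# Model-free fit and spectral density
# ---------------------------------------------------------------------------

@dataclass
class ModelFreeFit:
    """Constrained multi-exponential decomposition of an internal ACF."""

    S2: float
    components: list          # [(amplitude, tau_ns), ...] sorted by tau
    rss: float
    converged: bool = True

    def __post_init__(self):
        total = self.S2 + sum(a for a, _ in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("S2 + sum(amplitudes) must equal 1")
        if self.S2 < -1e-9 or self.S2 > 1 + 1e-6:
            raise ValueError("S2 out of range [0, 1]")

    def evaluate(self, t_ns) -> np.ndarray:
        t = np.asarray(t_ns, dtype=float)
        out = np.full_like(t, self.S2, dtype=float)
        for a, tau in self.components:
            out = out + a * np.exp(-t / tau)
        return out


def fit_acf_multiexp(
    acf_lags_ns: np.ndarray,
    acf_values: np.ndarray,
    n_components: int = 2,
    n_starts: int = 4,
) -> ModelFreeFit:
    """Least-squares fit C(t) ~ S^2 + sum A_i exp(-t/tau_i), S^2 = 1 - sum A_i.

    Multi-start over log-spaced initial correlation times; amplitudes bounded
    to [0, 1].  Falls back to fewer components when a fit fails to converge.
    """
    from scipy.optimize import least_squares

    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    t = np.asarray(acf_lags_ns, dtype=float)
    y = np.asarray(acf_values, dtype=float)
    pos = t > 0
    t_pos = t[pos]

    def residuals(params):
        A = params[:n_components]
        tau = 10.0 ** params[n_components:]
        model = (1.0 - A.sum()) + (A[None, :] * np.exp(-t[:, None] / tau[None, :])).sum(axis=1)
        penalty = max(A.sum() - 1.0, 0.0) * 100.0
        return np.append(model - y, penalty)

    lo_t, hi_t = np.log10(t_pos.min() / 10), np.log10(t_pos.max() * 10)
    best = None
    amp0 = max(min(1.0 - y[-1], 1.0), 1e-3)
    for s in range(n_starts):
        centers = np.linspace(lo_t + 0.5, hi_t - 0.5, n_components) + 0.3 * (s - n_starts / 2)
        x0 = np.concatenate([np.full(n_components, amp0 / n_components), centers])
        bounds = (
            np.concatenate([np.zeros(n_components), np.full(n_components, lo_t - 1)]),
            np.concatenate([np.ones(n_components), np.full(n_components, hi_t + 1)]),
        )
        try:
            res = least_squares(residuals, x0, bounds=bounds, max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        if n_components > 1:
            return fit_acf_multiexp(acf_lags_ns, acf_values, n_components - 1, n_starts)
        raise RuntimeError("ACF fit failed to converge")
    A = np.clip(best.x[:n_components], 0.0, 1.0)
    tau = 10.0 ** best.x[n_components:]
    if A.sum() > 1.0:
        A = A / A.sum()
    comps = sorted(zip(A.tolist(), tau.tolist()), key=lambda at: at[1])
    S2 = 1.0 - float(A.sum())
    rss = float(np.sum(residuals(best.x)[:-1] ** 2))
    return ModelFreeFit(S2=S2, components=comps, rss=rss, converged=best.success)


@dataclass
class SpectralDensity:
    """Sum-of-Lorentzians spectral density J(w) = (2/5) sum a_j tau_j'/(1+(w tau_j')^2)."""

    terms: list          # [(amplitude, effective tau ns), ...]
    tau_c_ns: float

    def __post_init__(self):
        total = sum(a for a, _ in self.terms)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("spectral-density amplitudes must sum to 1")

    def __call__(self, omega: float) -> float:
        """J(omega) in s/rad for omega in rad/s."""
        J = 0.0
        for a, tau_ns in self.terms:
            tau = tau_ns * 1e-9
            J += a * tau / (1.0 + (omega * tau) ** 2)
        return 0.4 * J


def compose_spectral_density(fit: ModelFreeFit, tau_c_ns: float) -> SpectralDensity:
    """Fold isotropic overall tumbling into a model-free fit.

    Terms: (S^2, tau_c) plus (A_i, tau_i') with 1/tau_i' = 1/tau_i + 1/tau_c.
    """
    if tau_c_ns <= 0:
        raise ValueError("tau_c must be positive")
    terms = [(fit.S2, tau_c_ns)]
    for a, tau in fit.components:
        tau_eff = 1.0 / (1.0 / tau + 1.0 / tau_c_ns)
        terms.append((a, tau_eff))
    return SpectralDensity(terms, tau_c_ns)


def modelfree_spectral_density(S2: float, tau_e_ps: float, tau_c_ns: float) -> SpectralDensity:
    """Analytic two-term Lipari-Szabo spectral density from planted parameters."""
    fit = ModelFreeFit(S2=S2, components=[(1.0 - S2, tau_e_ps / 1000.0)], rss=0.0)
    return compose_spectral_density(fit, tau_c_ns)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def backbone_rates(J: Callable[[float], float], constants: NmrConstants) -> dict:
    """15N R1, R2, heteronuclear NOE and eta_xy from a spectral density."""
    c = constants
    wH, wN = c.omega_h, c.omega_n
    d2 = c.d_nh**2
    c2 = c.c_n**2
    J0 = J(0.0)
    JwN = J(wN)
    JwH = J(wH)
    Jdiff = J(wH - wN)
    Jsum = J(wH + wN)
    R1 = (d2 / 4.0) * (Jdiff + 3 * JwN + 6 * Jsum) + c2 * JwN
    R2 = (d2 / 8.0) * (4 * J0 + Jdiff + 3 * JwN + 6 * JwH + 6 * Jsum) \
        + (c2 / 6.0) * (4 * J0 + 3 * JwN)
    sigma = (d2 / 4.0) * (6 * Jsum - Jdiff)
    NOE = 1.0 + (c.gamma_h / c.gamma_n) * sigma / R1 if R1 > 0 else 1.0
    theta = np.deg2rad(c.csa_dipole_angle_deg)
    eta_xy = (c.d_nh * c.c_n / 6.0) * p2(np.cos(theta)) * (4 * J0 + 3 * JwN)
    return {"R1": R1, "R2": R2, "NOE": NOE, "eta_xy": float(eta_xy)}


def methyl_rates(J_axis: Callable[[float], float], constants: NmrConstants) -> dict:
    """Methyl 13C R1 and Gamma2 from the symmetry-axis spectral density.

    Fast methyl spinning is folded in analytically: the three C-H dipolar
    interactions see the axis motion scaled by [P2(cos beta)]^2 (beta = angle
    between C-H bond and the symmetry axis, ~1/9 at 110.5 deg).
    """
    c = constants
    wH, wC = c.omega_h, c.omega_c
    scale = p2(np.cos(np.deg2rad(c.methyl_axis_angle_deg))) ** 2

    def Jeff(w):
        return scale * J_axis(w)

    d2 = c.d_ch**2
    R1 = 3.0 * (d2 / 4.0) * (Jeff(wH - wC) + 3 * Jeff(wC) + 6 * Jeff(wH + wC))
    G2 = (d2 / 8.0) * (4 * Jeff(0.0) + 3 * Jeff(wC))
    return {"methyl_R1": float(R1), "methyl_G2": float(G2)}


# ---------------------------------------------------------------------------
# Bootstrap and trajectory-facing composition
# ---------------------------------------------------------------------------

def bootstrap_uncertainty(
    traj: TrajectoryRecord,
    estimator: Callable[[TrajectoryRecord], np.ndarray],
    block_length_ns: float = 10.0,
    n_replicates: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Circular block bootstrap SD of a per-probe estimator.

    The trajectory is cut into contiguous blocks of ``block_length_ns``;
    replicates draw blocks with replacement (wrapping circularly) and re-run
    the estimator on the concatenation.  Requires >= 10 blocks.
    """
    dt = traj.spacing_ns()
    block = max(int(round(block_length_ns / dt)), 1)
    n = traj.n_frames
    n_blocks = n // block
    if n_blocks < 10:
        raise ValueError(f"segment too short: {n_blocks} blocks < 10")
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_replicates):
        starts = rng.integers(0, n, size=n_blocks)
        idx = (starts[:, None] + np.arange(block)[None, :]) % n
        coords = traj.coordinates[idx.ravel()]
        times = np.arange(coords.shape[0]) * dt
        estimates.append(estimator(TrajectoryRecord(times, coords, traj.atom_table)))
    return np.std(np.array(estimates, dtype=float), axis=0, ddof=1)


def ensemble_rates(
    traj: TrajectoryRecord,
    constants: NmrConstants,
    tau_c_ns: float,
    time_range_ns: tuple[float, float] | None = None,
    n_components: int = 2,
    max_lag_ns: float | None = None,
    n_bootstrap: int = 0,
    block_length_ns: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Back-calculate backbone R1/R2/NOE/eta_xy per residue from a trajectory slice.

    Composition: slice -> superpose -> internal N-H ACF -> model-free fit ->
    spectral density with isotropic tau_c -> Redfield rates; optional circular
    block bootstrap SDs.  One row per residue carrying an amide proton.
    """
    seg = traj if time_range_ns is None else traj.slice_time(*time_range_ns)

    def _rates_frame(t: TrajectoryRecord) -> pd.DataFrame:
        acf = bond_vector_acf(t, max_lag_ns=max_lag_ns)
        rows = []
        for i, res in enumerate(acf.probe_ids):
            fit = fit_acf_multiexp(acf.lags_ns, acf.values[i], n_components)
            J = compose_spectral_density(fit, tau_c_ns)
            r = backbone_rates(J, constants)
            rows.append({"residue": res, "S2": fit.S2, **r})
        return pd.DataFrame(rows)

    out = _rates_frame(seg)
    if n_bootstrap > 0:
        observables = ["R1", "R2", "NOE", "eta_xy"]

        def est(t: TrajectoryRecord) -> np.ndarray:
            df = _rates_frame(t)
            return df[observables].to_numpy().ravel()

        sd = bootstrap_uncertainty(seg, est, block_length_ns, n_bootstrap, seed)
        sd = sd.reshape(len(out), len(observables))
        for k, obs in enumerate(observables):
            out[f"{obs}_sd"] = sd[:, k]
    return out


def rates_to_table(df: pd.DataFrame, constants: NmrConstants,
                   default_uncertainty: float = 1e-3):
    """Convert an ensemble_rates frame into a RelaxationTable."""
    from .io_core import RelaxationTable

    rows = []
    for _, r in df.iterrows():
        for obs in ("R1", "R2", "NOE", "eta_xy"):
            if obs in df.columns:
                rows.append({
                    "residue": int(r["residue"]), "observable": obs,
                    "value": float(r[obs]),
                    "uncertainty": float(r.get(f"{obs}_sd", default_uncertainty)) or default_uncertainty,
                    "field_mhz": constants.field_mhz,
                    "probe": "backbone_NH", "group": "",
                })
    return RelaxationTable(pd.DataFrame(rows))
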