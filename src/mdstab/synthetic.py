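"""Planted-truth synthetic data generators.

These generators produce inputs with the statistical structure that the
downstream analyses assume, so that clustering, stability detection,
relaxation back-calculation and ensemble scoring can all be validated
against a known ground truth without multi-microsecond MD trajectories:

* Markov jump dynamics among well-separated conformer templates with
  Gaussian coordinate jitter (multi-basin trajectories);
* unit bond-vector time series with Lipari-Szabo model-free statistics
  C(t) = S^2 exp(-t/tau_c) + (1 - S^2) exp(-t/tau'), 1/tau' = 1/tau_c + 1/tau_e,
  realized as isotropic global rotational diffusion composed with
  wobble-in-a-cone internal diffusion;
* noisy per-residue relaxation tables from known rates;
* circular dihedral traces with a single planted ring-flip.

Templates are toy bead chains (one CA per residue, 0.38 nm spacing); the
analyses only consume coordinates, so no force field is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import AtomTable, RelaxationTable, TrajectoryRecord, RELAXATION_COLUMNS

CA_SPACING_NM = 0.38
NH_BOND_NM = 0.102


@dataclass
class PlantedTruth:
    """Ground truth accompanying a synthetic dataset."""

    state_path: np.ndarray | None = None
    stationary_populations: np.ndarray | None = None
    regime_boundaries_ns: list | None = None
    flip_time_ns: float | None = None
    S2: float | None = None
    tau_e_ps: float | None = None
    tau_c_ns: float | None = None

    def __post_init__(self):
        if self.stationary_populations is not None:
            p = np.asarray(self.stationary_populations, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("stationary populations must sum to 1")
            self.stationary_populations = p


@dataclass
class DihedralTrace:
    """chi1/chi2 side-chain dihedral time series in degrees, wrapped to (-180, 180]."""

    times_ns: np.ndarray
    chi1_deg: np.ndarray
    chi2_deg: np.ndarray


def wrap_deg(angle):
    """Wrap angles (deg) to the branch (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    out = -np.mod(-a + 180.0, 360.0) + 180.0
    return out if out.ndim else float(out)


def make_bead_chain(n_residues: int, spacing_nm: float = CA_SPACING_NM) -> np.ndarray:
    """Self-avoiding CA-only chain laid out on a gentle helix."""
    # helix with rise + radius chosen so consecutive CA are `spacing_nm` apart
    # and non-consecutive beads never approach closer than ~one spacing
    turn = 0.7  # rad per residue
    radius = 0.6
    chord = 2 * radius * np.sin(turn / 2)
    rise = np.sqrt(max(spacing_nm**2 - chord**2, 1e-8))
    i = np.arange(n_residues)
    return np.stack(
        [radius * np.cos(turn * i), radius * np.sin(turn * i), rise * i], axis=1
    )


def make_chain_atoms(n_residues: int, first_residue: int = 339,
                     atom_names: Sequence[str] = ("CA",)) -> AtomTable:
    recs = []
    for r in range(n_residues):
        for name in atom_names:
            recs.append((name, first_residue + r, "ALA", "A"))
    return AtomTable.from_records(recs)


def make_state_templates(
    n_residues: int,
    n_states: int,
    displaced_span: tuple[int, int] | None = None,
    amplitude_nm: float = 0.5,
) -> np.ndarray:
    """K templates sharing a bead-chain scaffold with one loop segment displaced
    in a different direction per state (state 0 keeps the reference chain)."""
    base = make_bead_chain(n_residues)
    if displaced_span is None:
        displaced_span = (n_residues // 3, 2 * n_residues // 3)
    lo, hi = displaced_span
    templates = np.repeat(base[None], n_states, axis=0)
    for k in range(1, n_states):
        phi = 2 * np.pi * (k - 1) / max(n_states - 1, 1)
        direction = np.array([np.cos(phi), np.sin(phi), 0.25 * k])
        direction /= np.linalg.norm(direction)
        # smooth displacement bump so the segment stays chain-like
        t = np.linspace(0, np.pi, hi - lo)
        bump = np.sin(t)[:, None] * direction[None, :] * amplitude_nm * 2.0
        templates[k, lo:hi] += bump
    return templates


def _template_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    from .conformation import superpose_kabsch

    return superpose_kabsch(a, b).rmsd


@dataclass
class MarkovConformerModel:
    """Discrete-time Markov jump model over conformer templates."""

    transition: np.ndarray
    templates: np.ndarray
    atoms: AtomTable
    jitter_sd_nm: float = 0.01
    frame_interval_ns: float = 1.0

    def __post_init__(self):
        T = np.asarray(self.transition, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < 0) or np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        self.transition = T
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.shape[0] != T.shape[0]:
            raise ValueError("one template per Markov state required")
        K = T.shape[0]
        for i in range(K):
            for j in range(i + 1, K):
                r = _template_rmsd(self.templates[i], self.templates[j])
                if r <= 4 * self.jitter_sd_nm:
                    raise ValueError(
                        f"templates {i},{j} RMSD {r:.3g} nm not separable at "
                        f"jitter {self.jitter_sd_nm} nm (need > 4x jitter)"
                    )

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left Perron eigenvector)."""
        w, v = np.linalg.eig(self.transition.T)
        i = np.argmin(np.abs(w - 1.0))
        p = np.real(v[:, i])
        p = np.abs(p)
        return p / p.sum()


def two_state_model(
    n_residues: int = 50,
    stationary: Sequence[float] = (0.5, 0.5),
    switch_rate: float = 0.1,
    template_separation_nm: float = 0.5,
    jitter_sd_nm: float = 0.01,
    frame_interval_ns: float = 1.0,
) -> MarkovConformerModel:
    """Convenience two-state model with given stationary populations.

    Detailed balance: p0 * T01 = p1 * T10, with overall switching scale
    ``switch_rate`` (probability per frame of leaving the rarer state).
    """
    p0, p1 = float(stationary[0]), float(stationary[1])
    if abs(p0 + p1 - 1) > 1e-9:
        raise ValueError("stationary populations must sum to 1")
    t10 = switch_rate
    t01 = switch_rate * p1 / p0
    T = np.array([[1 - t01, t01], [t10, 1 - t10]])
    templates = make_state_templates(
        n_residues, 2, amplitude_nm=template_separation_nm
    )
    # rescale displacement so the Kabsch RMSD between templates hits the target
    r = _template_rmsd(templates[0], templates[1])
    templates[1] = templates[0] + (templates[1] - templates[0]) * (
        template_separation_nm / r
    )
    atoms = make_chain_atoms(n_residues)
    return MarkovConformerModel(T, templates, atoms, jitter_sd_nm, frame_interval_ns)


def gen_markov_trajectory(
    model: MarkovConformerModel,
    n_frames: int,
    seed: int,
    transition_schedule: Sequence[tuple[int, np.ndarray]] | None = None,
    initial_state: int | None = None,
) -> tuple[TrajectoryRecord, PlantedTruth]:
    """Sample a jittered Markov jump trajectory over the model's templates.

    ``transition_schedule`` optionally replaces the transition matrix from
    given frame indices on (piecewise-stationary runs); the switch times are
    recorded as regime boundaries in the truth.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    schedule = sorted(transition_schedule or [], key=lambda x: x[0])
    for start, T in schedule:
        T = np.asarray(T)
        if np.any(T < 0) or np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("scheduled transition matrix is not row-stochastic")

    pi = model.stationary()
    state = int(initial_state) if initial_state is not None else int(
        rng.choice(model.n_states, p=pi)
    )
    path = np.empty(n_frames, dtype=int)
    T = model.transition
    nxt = 0
    for i in range(n_frames):
        while nxt < len(schedule) and i >= schedule[nxt][0]:
            T = np.asarray(schedule[nxt][1], dtype=float)
            nxt += 1
        path[i] = state
        state = int(rng.choice(model.n_states, p=T[state]))

    coords = model.templates[path] + rng.normal(
        0.0, model.jitter_sd_nm, size=(n_frames,) + model.templates.shape[1:]
    )
    times = np.arange(n_frames, dtype=float) * model.frame_interval_ns
    truth = PlantedTruth(
        state_path=path,
        stationary_populations=pi,
        regime_boundaries_ns=[s * model.frame_interval_ns for s, _ in schedule] or None,
    )
    return TrajectoryRecord(times, coords, model.atoms), truth


#: Fast-mixing regime over states {0, 1}, stationary (0.8, 0.2).
REGIME_A = np.array([[0.9, 0.1, 0.0], [0.4, 0.6, 0.0], [0.5, 0.5, 0.0]])
#: Fast-mixing regime over states {1, 2}, stationary (0.2, 0.8); state 0 exits
#: immediately so the switch is sharp.
REGIME_B = np.array([[0.0, 0.5, 0.5], [0.0, 0.6, 0.4], [0.0, 0.1, 0.9]])


def stability_scenario(
    n_frames: int = 3000,
    switch_frame: int | None = 1000,
    n_residues: int = 50,
    jitter_sd_nm: float = 0.01,
    seed: int = 1,
) -> tuple[TrajectoryRecord, PlantedTruth]:
    """Canonical 3-state piecewise-stationary trajectory for stability analysis.

    Two fast-mixing regimes with asymmetric stationary populations (0.8/0.2
    over disjoint-but-adjacent state pairs) keep window-to-window population
    fluctuations well inside the stability threshold within each regime while
    the regimes themselves are nearly orthogonal in population space.  With
    ``switch_frame=None`` the run is stationary throughout (control).
    """
    templates = make_state_templates(n_residues, 3, amplitude_nm=0.5)
    model = MarkovConformerModel(
        REGIME_A, templates, make_chain_atoms(n_residues), jitter_sd_nm
    )
    schedule = None if switch_frame is None else [(switch_frame, REGIME_B)]
    return gen_markov_trajectory(
        model, n_frames, seed, transition_schedule=schedule, initial_state=0
    )


# ---------------------------------------------------------------------------
# Model-free bond vectors: wobble-in-a-cone + isotropic tumbling
# ---------------------------------------------------------------------------

def cone_half_angle(S2: float) -> float:
    """Cone semi-angle theta0 with order parameter S = cos(theta0)(1+cos(theta0))/2."""
    S = np.sqrt(S2)
    x0 = (-1.0 + np.sqrt(1.0 + 8.0 * S)) / 2.0  # root of x^2 + x - 2S = 0
    return float(np.arccos(np.clip(x0, -1.0, 1.0)))


def _cone_tau_factor(x0: float) -> float:
    """tau_eff * D_w * (1 - S^2) for diffusion in a cone of cos(semi-angle) x0
    (Lipari-Szabo closed form)."""
    term1 = (
        x0**2 * (1 + x0) ** 2 * (np.log((1 + x0) / 2.0) + (1 - x0) / 2.0)
        / (2.0 * (x0 - 1.0))
    )
    term2 = (1 - x0) * (6 + 8 * x0 - x0**2 - 12 * x0**3 - 7 * x0**4) / 24.0
    return term1 + term2


def wobble_diffusion_coefficient(S2: float, tau_e_ps: float) -> float:
    """Internal (cone) diffusion constant D_w [1/ps] giving effective internal
    correlation time tau_e for the chosen cone geometry."""
    x0 = np.cos(cone_half_angle(S2))
    return _cone_tau_factor(x0) / (tau_e_ps * (1.0 - S2))


def _rotation_matrices(omega: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices for rotation vectors omega (..., 3)."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(omega).as_matrix()


def gen_modelfree_vectors(
    S2: float,
    tau_e_ps: float,
    tau_c_ns: float,
    dt_ps: float,
    n_steps: int,
    n_vectors: int,
    seed: int,
) -> tuple[np.ndarray, PlantedTruth]:
    """Unit bond-vector time series with model-free ensemble statistics.

    Internal motion: diffusion in a cone (reflecting boundary at the semi-angle
    implied by S^2) with diffusion constant tuned so the internal ACF's
    effective decay time equals ``tau_e_ps``.  Global motion: one shared
    isotropic rotational diffusion with D_r = 1/(6 tau_c), disabled when
    ``tau_c_ns`` is infinite.

    Returns vectors of shape (n_steps, n_vectors, 3), unit norm at every step.
    """
    if not (0.0 < S2 <= 1.0):
        raise ValueError("S2 must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    theta0 = cone_half_angle(S2)

    local = np.empty((n_steps, n_vectors, 3))
    if S2 >= 1.0 - 1e-12:
        local[:] = np.array([0.0, 0.0, 1.0])
    else:
        Dw = wobble_diffusion_coefficient(S2, tau_e_ps)  # 1/ps
        sd = np.sqrt(2.0 * Dw * dt_ps)
        # start at equilibrium: uniform on the spherical cap (cone axis = z)
        x0 = np.cos(theta0)
        cz = rng.uniform(x0, 1.0, size=n_vectors)
        sz = np.sqrt(1.0 - cz**2)
        ph = rng.uniform(0, 2 * np.pi, size=n_vectors)
        u = np.stack([sz * np.cos(ph), sz * np.sin(ph), cz], axis=1)
        for t in range(n_steps):
            local[t] = u
            # isotropic tangent-plane step (singularity-free sphere diffusion)
            r = sd * rng.standard_normal((n_vectors, 3))
            r -= np.einsum("vi,vi->v", r, u)[:, None] * u
            u = u + r
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            # reflect the polar angle at the cone boundary, keeping the azimuth
            cth = np.clip(u[:, 2], -1.0, 1.0)
            th = np.arccos(cth)
            over = th > theta0
            if over.any():
                th_new = 2 * theta0 - th[over]
                sin_old = np.maximum(np.sin(th[over]), 1e-12)
                scale = np.sin(th_new) / sin_old
                u[over, 0] *= scale
                u[over, 1] *= scale
                u[over, 2] = np.cos(th_new)
                u[over] /= np.linalg.norm(u[over], axis=1, keepdims=True)

    # randomize each vector's cone-axis orientation (fixed per vector)
    axis_rot = _rotation_matrices(
        rng.standard_normal((n_vectors, 3))
        * rng.uniform(0, np.pi, size=(n_vectors, 1))
    )
    local = np.einsum("vij,tvj->tvi", axis_rot, local)

    if np.isfinite(tau_c_ns):
        Dr = 1.0 / (6.0 * tau_c_ns * 1000.0)  # 1/ps
        steps = rng.standard_normal((n_steps, 3)) * np.sqrt(2.0 * Dr * dt_ps)
        out = np.empty_like(local)
        R = np.eye(3)
        mats = _rotation_matrices(steps)
        for t in range(n_steps):
            out[t] = local[t] @ R.T
            R = mats[t] @ R
        local = out

    local /= np.linalg.norm(local, axis=-1, keepdims=True)
    truth = PlantedTruth(S2=S2, tau_e_ps=tau_e_ps, tau_c_ns=tau_c_ns)
    return local, truth


def embed_nh_vectors(
    vectors: np.ndarray,
    dt_ns: float,
    first_residue: int = 460,
) -> TrajectoryRecord:
    """Build a trajectory whose N-H bond vectors follow the supplied series.

    Amide N atoms sit on a rigid bead chain; each residue's H atom is placed
    at N + 0.102 nm * u(t).  Useful for exercising the trajectory-facing
    relaxation chain against planted bond-vector statistics.
    """
    n_steps, n_res, _ = vectors.shape
    chain = make_bead_chain(n_res)
    atoms = make_chain_atoms(n_res, first_residue=first_residue, atom_names=("N", "H"))
    coords = np.empty((n_steps, 2 * n_res, 3))
    coords[:, 0::2, :] = chain[None]
    coords[:, 1::2, :] = chain[None] + NH_BOND_NM * vectors
    times = np.arange(n_steps) * dt_ns
    return TrajectoryRecord(times, coords, atoms)


def gen_relaxation_table(
    truth: pd.DataFrame | RelaxationTable,
    noise_sd,
    seed: int,
) -> RelaxationTable:
    """Add Gaussian noise to a truth table of rates; uncertainty column = noise SD.

    ``noise_sd`` may be a scalar or a per-row array; with 0 the table equals
    the truth exactly.
    """
    df = (truth.df if isinstance(truth, RelaxationTable) else truth).copy()
    rng = np.random.default_rng(seed)
    sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (len(df),)).copy()
    df["value"] = df["value"].to_numpy() + rng.normal(0.0, 1.0, len(df)) * sd
    df["uncertainty"] = np.where(sd > 0, sd, df.get("uncertainty", 1e-6))
    if "group" not in df.columns:
        df["group"] = ""
    return RelaxationTable(df[RELAXATION_COLUMNS])


def gen_flip_trace(
    t_flip_ns: float | None,
    pre_mean_deg: float,
    post_mean_deg: float,
    noise_sd_deg: float,
    n_frames: int,
    seed: int,
    frame_interval_ns: float = 1.0,
    chi1_mean_deg: float = -170.0,
) -> tuple[DihedralTrace, PlantedTruth]:
    """Noisy chi2 trace with a single mean shift at ``t_flip_ns`` (chi1 held at a
    constant mean).  Noise is wrapped-normal with the given SD in degrees."""
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames, dtype=float) * frame_interval_ns
    chi2_mean = np.full(n_frames, pre_mean_deg)
    flipped = t_flip_ns is not None and wrap_deg(pre_mean_deg - post_mean_deg) != 0.0
    if flipped:
        chi2_mean[times >= t_flip_ns] = post_mean_deg
    chi1 = wrap_deg(chi1_mean_deg + rng.normal(0, noise_sd_deg, n_frames))
    chi2 = wrap_deg(chi2_mean + rng.normal(0, noise_sd_deg, n_frames))
    truth = PlantedTruth(flip_time_ns=float(t_flip_ns) if flipped else None)
    return DihedralTrace(times, chi1, chi2), truth
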