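"""Conformational descriptors: superposition, RMSD series, RMSF, Cartesian PCA,
side-chain dihedral traces and ring-state classification.

Conventions: lengths in nm except RMSF (reported in Angstrom, as customarily
plotted); dihedrals follow the IUPAC sign convention in degrees, wrapped to
(-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import AtomTable, RegionSpec, TrajectoryRecord, resolve_region
from .synthetic import DihedralTrace, wrap_deg

#: Standard chi1/chi2 atom quadruples for tryptophan.
TRP_CHI_ATOMS = {
    "chi1": ("N", "CA", "CB", "CG"),
    "chi2": ("CA", "CB", "CG", "CD1"),
}


@dataclass
class SuperposeResult:
    rotation: np.ndarray     # (3,3), proper (det = +1)
    translation: np.ndarray  # nm; maps centered mobile onto reference frame
    rmsd: float              # nm

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose_kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    atom_indices=None,
    weights=None,
) -> SuperposeResult:
    """Weighted Kabsch superposition of ``mobile`` onto ``reference``.

    The fit uses ``atom_indices`` (default: all atoms); the returned transform
    x -> x @ R.T + t minimizes the weighted RMSD over those atoms and is a
    proper rotation even for mirror-image inputs.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(len(mobile)) if atom_indices is None else np.asarray(atom_indices)
    X = mobile[idx]
    Y = reference[idx]
    if len(X) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    w = np.ones(len(X)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    xc = (w[:, None] * X).sum(axis=0)
    yc = (w[:, None] * Y).sum(axis=0)
    X0 = X - xc
    Y0 = Y - yc
    # collinearity / coincidence check via the covariance spectrum
    gram = (w[:, None] * X0).T @ X0
    if np.linalg.matrix_rank(gram, tol=1e-12) < 2:
        raise ValueError("degenerate (collinear or coincident) atom selection")
    H = (w[:, None] * X0).T @ Y0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = X0 @ R.T - Y0
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    return SuperposeResult(R, t, rmsd)


def rmsd_series(
    traj: TrajectoryRecord,
    reference_frame: int | np.ndarray,
    region: RegionSpec,
) -> np.ndarray:
    """Kabsch-minimized RMSD (nm) of every frame to a reference over a region.

    ``reference_frame`` is a frame index or an explicit (n_atoms, 3) coordinate
    array sharing the trajectory's atom table.
    """
    idx = resolve_region(region, traj.atom_table)
    if isinstance(reference_frame, (int, np.integer)):
        ref = traj.coordinates[int(reference_frame)]
    else:
        ref = np.asarray(reference_frame, dtype=float)
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        out[i] = superpose_kabsch(traj.coordinates[i], ref, idx).rmsd
    return out


def superpose_trajectory(
    traj: TrajectoryRecord, reference: np.ndarray, atom_indices
) -> np.ndarray:
    """All frames superposed onto ``reference`` over the given atoms; returns
    the transformed full coordinate array."""
    out = np.empty_like(traj.coordinates)
    for i in range(traj.n_frames):
        fit = superpose_kabsch(traj.coordinates[i], reference, atom_indices)
        out[i] = fit.apply(traj.coordinates[i])
    return out


def rmsf_profile(
    traj: TrajectoryRecord,
    region: RegionSpec,
    align_to: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF in Angstrom over the region's atoms.

    Two-pass alignment by default: frames are first superposed on frame 0,
    the mean structure is computed, then frames are re-superposed onto that
    mean before taking sqrt(mean ||r_i(t) - <r_i>||^2).  ``align_to='first'``
    skips the second pass.  Returns (residue_numbers, rmsf_A).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    if align_to not in ("mean", "first"):
        raise ValueError("align_to must be 'mean' or 'first'")
    idx = resolve_region(region, traj.atom_table)
    coords = superpose_trajectory(traj, traj.coordinates[0], idx)[:, idx]
    if align_to == "mean":
        mean = coords.mean(axis=0)
        sub = TrajectoryRecord(traj.frame_times, coords,
                               _subtable(traj.atom_table, idx))
        full = np.empty_like(coords)
        for i in range(len(coords)):
            fit = superpose_kabsch(coords[i], mean, None)
            full[i] = fit.apply(coords[i])
        coords = full
    mean = coords.mean(axis=0)
    msf = np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0)
    residues = traj.atom_table.residue_numbers[idx]
    return residues, np.sqrt(msf) * 10.0  # nm -> Angstrom


def _subtable(atoms: AtomTable, idx) -> AtomTable:
    return AtomTable(atoms.df.iloc[idx].reset_index(drop=True))


@dataclass
class PcaResult:
    """Cartesian PCA of superposed region coordinates."""

    mean_coords: np.ndarray   # (n_atoms, 3) nm
    components: np.ndarray    # (n_components, 3*n_atoms), orthonormal rows
    variances: np.ndarray     # nm^2, non-increasing
    projections: np.ndarray   # (n_frames, n_components)
    total_variance: float

    def atom_loadings(self, component: int) -> np.ndarray:
        """Per-atom displacement vectors of one component, shape (n_atoms, 3)."""
        return self.components[component].reshape(-1, 3)


def pca_cartesian(
    traj: TrajectoryRecord, region: RegionSpec, n_components: int = 2
) -> PcaResult:
    """PCA of the covariance of region coordinates after superposition to the
    trajectory mean (two-pass, as in RMSF)."""
    from sklearn.decomposition import PCA

    idx = resolve_region(region, traj.atom_table)
    if n_components > 3 * len(idx):
        raise ValueError("n_components exceeds coordinate dimensionality")
    if traj.n_frames < n_components:
        raise ValueError("need at least n_components frames")
    coords = superpose_trajectory(traj, traj.coordinates[0], idx)[:, idx]
    mean = coords.mean(axis=0)
    for i in range(len(coords)):
        fit = superpose_kabsch(coords[i], mean, None)
        coords[i] = fit.apply(coords[i])
    X = coords.reshape(traj.n_frames, -1)
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(X)
    total = float(X.var(axis=0, ddof=1).sum())
    return PcaResult(
        mean_coords=X.mean(axis=0).reshape(-1, 3),
        components=pca.components_,
        variances=pca.explained_variance_,
        projections=proj,
        total_variance=total,
    )


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed IUPAC dihedral (deg) for points of shape (..., 3)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1n)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return wrap_deg(np.degrees(np.arctan2(y, x)))


def dihedral_trace(
    traj: TrajectoryRecord,
    residue_number: int,
    chi_atom_quadruples: dict | None = None,
) -> DihedralTrace:
    """chi1/chi2 time series for one residue (default: tryptophan quadruples)."""
    quads = chi_atom_quadruples or TRP_CHI_ATOMS
    at = traj.atom_table.df
    angles = {}
    for chi, names in quads.items():
        pts = []
        for name in names:
            sel = at[(at["residue_number"] == residue_number) & (at["atom_name"] == name)]
            if len(sel) != 1:
                raise ValueError(
                    f"atom {name} of residue {residue_number} missing or ambiguous"
                )
            pts.append(traj.coordinates[:, sel.index[0], :])
        angles[chi] = dihedral_angle(*pts)
    return DihedralTrace(traj.frame_times, angles["chi1"], angles["chi2"])


@dataclass
class RingStateTrace:
    """Per-frame ring orientation labels with hysteresis-filtered transitions."""

    times_ns: np.ndarray
    labels: np.ndarray                 # 'inward' | 'outward' | 'undefined'
    transitions: list                  # (time_ns, from_label, to_label)

    def runs(self) -> list:
        """Consecutive identical labels merged to (start_ns, end_ns, label) runs."""
        out = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[start]:
                out.append((self.times_ns[start], self.times_ns[i - 1], self.labels[start]))
                start = i
        return out


def circular_distance_deg(a, b) -> np.ndarray:
    return np.abs(wrap_deg(np.asarray(a, dtype=float) - b))


def classify_ring_state(
    trace: DihedralTrace,
    inward_center_deg: float = -100.0,
    outward_center_deg: float = 90.0,
    half_width_deg: float = 60.0,
    min_dwell_frames: int = 10,
) -> RingStateTrace:
    """Classify chi2 frames as inward/outward ring orientation with hysteresis.

    A frame gets the label of the nearer center if within ``half_width_deg``
    (circular distance), else 'undefined'.  A transition between defined
    states is accepted only once the new label persists for at least
    ``min_dwell_frames`` frames; shorter excursions keep the previous state.
    """
    if circular_distance_deg(inward_center_deg, outward_center_deg) < 1e-9:
        raise ValueError("inward and outward centers must be distinct")
    if circular_distance_deg(inward_center_deg, outward_center_deg) < 2 * half_width_deg:
        raise ValueError("acceptance windows overlap; reduce half_width_deg")
    chi2 = trace.chi2_deg
    d_in = circular_distance_deg(chi2, inward_center_deg)
    d_out = circular_distance_deg(chi2, outward_center_deg)
    raw = np.where(
        (d_in <= half_width_deg) & (d_in <= d_out), "inward",
        np.where((d_out <= half_width_deg), "outward", "undefined"),
    )

    labels = raw.copy()
    transitions = []
    current = raw[0]
    i = 1
    n = len(raw)
    while i < n:
        if raw[i] != current:
            j = i
            while j < n and raw[j] == raw[i]:
                j += 1
            dwell = j - i
            if raw[i] != "undefined" and dwell >= min_dwell_frames:
                if current != "undefined":
                    transitions.append((float(trace.times_ns[i]), str(current), str(raw[i])))
                current = raw[i]
                labels[i:j] = current
                i = j
            elif raw[i] == "undefined" and dwell >= min_dwell_frames:
                current = "undefined"
                i = j
            else:
                labels[i:j] = current  # short excursion: keep previous state
                i = j
        else:
            i += 1
    return RingStateTrace(trace.times_ns, labels, transitions)
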