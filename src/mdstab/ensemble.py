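"""Detection of temporally stable conformational ensembles.

Pipeline: GROMOS-style structural clustering of down-sampled frames at a
backbone RMSD cutoff (default 0.1 nm) with a pairwise admission rule, so the
pairwise RMSD between any two members of a cluster is guaranteed <= cutoff;
overlapping time windows of duration 10*tau_c advanced in 15 ns steps; a
cluster population vector per window; the cosine distance

    d(a, b) = 1 - (a . b) / (|a| |b|)

between all window pairs; and maximal contiguous diagonal blocks of the
distance matrix with all pairwise distances below a threshold (default 0.1)
reported as stable segments [t_a, t_b + 10*tau_c].

Also provides combined clustering of two trajectories with per-source
occupancancies/overlap and medoid-ensemble extraction (default 20 structures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import RegionSpec, TrajectoryRecord, resolve_region

DEFAULT_CUTOFF_NM = 0.1
FINAL_ENSEMBLE_CUTOFF_NM = 0.105
DEFAULT_WINDOW_STEP_NS = 15.0
DEFAULT_STABILITY_THRESHOLD = 0.1


def _mdtraj_from_record(traj: TrajectoryRecord, atom_indices: np.ndarray):
    """Build an mdtraj Trajectory over the selected atoms (coordinates already nm)."""
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    at = traj.atom_table.df.iloc[atom_indices]
    res_cache = {}
    for _, row in at.iterrows():
        key = (row["chain_id"], row["residue_number"])
        if key not in res_cache:
            res_cache[key] = top.add_residue(row["residue_name"], chain,
                                             resSeq=int(row["residue_number"]))
        elem = md.element.carbon if row["atom_name"].startswith("C") else (
            md.element.nitrogen if row["atom_name"].startswith("N") else md.element.hydrogen
        )
        top.add_atom(row["atom_name"], elem, res_cache[key])
    return md.Trajectory(traj.coordinates[:, atom_indices].astype(np.float32), top)


def pairwise_rmsd_matrix(traj: TrajectoryRecord, region: RegionSpec) -> np.ndarray:
    """All-vs-all Kabsch/quaternion-minimized RMSD over the region's atoms (nm).

    Uses mdtraj's QCP kernel row by row; the matrix is symmetrized exactly.
    """
    idx = resolve_region(region, traj.atom_table)
    mt = _mdtraj_from_record(traj, idx)
    mt.center_coordinates()
    n = traj.n_frames
    D = np.empty((n, n), dtype=np.float32)
    import mdtraj as md

    for i in range(n):
        D[i] = md.rmsd(mt, mt, i, precentered=True)
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class ClusterAssignment:
    """Per-frame cluster labels with medoids and populations.

    Cluster ids run 1..K in descending-population order (ties broken by the
    medoid's frame index); 0 is reserved for the pooled "other" bucket, which
    exists only at the reporting level -- every frame carries a real id.
    """

    labels: np.ndarray            # (n_frames,), values 1..K
    medoid_frames: np.ndarray     # (K,), frame index of each cluster's medoid
    populations_percent: np.ndarray  # (K,), descending
    frame_times: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.medoid_frames)

    def populations_report(self, max_rank: int = 20) -> pd.DataFrame:
        """Populations with clusters ranked beyond ``max_rank`` pooled as "other"."""
        rows = [
            {"cluster": k + 1, "population_percent": float(self.populations_percent[k])}
            for k in range(min(self.n_clusters, max_rank))
        ]
        other = float(self.populations_percent[max_rank:].sum())
        rows.append({"cluster": 0, "population_percent": other})
        return pd.DataFrame(rows)


def gromos_cluster(
    traj: TrajectoryRecord,
    region: RegionSpec,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
    rmsd_matrix: np.ndarray | None = None,
) -> ClusterAssignment:
    """GROMOS neighbor-count clustering with a pairwise admission rule.

    Iteratively: the unclustered frame with most neighbors within the cutoff
    seeds a cluster (ties -> lowest frame index); its neighbors are admitted
    in ascending-RMSD order but only if within the cutoff of every member
    already admitted, so the maximum intra-cluster pairwise RMSD is <= cutoff
    by construction.  Clustered frames are removed and the procedure repeats.
    Deterministic for identical input.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    D = pairwise_rmsd_matrix(traj, region) if rmsd_matrix is None else rmsd_matrix
    n = D.shape[0]
    labels = np.zeros(n, dtype=int)
    medoids, sizes = [], []
    remaining = np.ones(n, dtype=bool)
    within = D <= cutoff_nm
    cid = 0
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        cand = np.nonzero(within[seed] & remaining)[0]
        cand = cand[cand != seed]
        order = cand[np.argsort(D[seed, cand], kind="stable")]
        members = [seed]
        for c in order:
            if np.all(D[c, members] <= cutoff_nm):
                members.append(int(c))
        members = np.array(sorted(members))
        cid += 1
        labels[members] = cid
        sub = D[np.ix_(members, members)]
        medoids.append(int(members[np.argmin(sub.sum(axis=1))]))
        sizes.append(len(members))
        remaining[members] = False

    # reorder ids by descending population, ties by medoid frame index
    sizes = np.array(sizes)
    medoids = np.array(medoids)
    order = np.lexsort((medoids, -sizes))
    remap = np.empty(len(order), dtype=int)
    remap[order] = np.arange(1, len(order) + 1)
    labels = remap[labels - 1]
    return ClusterAssignment(
        labels=labels,
        medoid_frames=medoids[order],
        populations_percent=100.0 * sizes[order] / n,
        frame_times=traj.frame_times.copy(),
    )


@dataclass
class PopulationVector:
    """Fractional cluster occupancies within one time window [t, t + W)."""

    window_start_ns: float
    window_length_ns: float
    fractions: np.ndarray  # length K (all clusters, zero-population included)

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")
        self.fractions = f


def window_population_vectors(
    assignment: ClusterAssignment,
    W_ns: float,
    step_ns: float = DEFAULT_WINDOW_STEP_NS,
) -> list[PopulationVector]:
    """Cluster population vectors over overlapping windows of duration W.

    Windows start at t0, t0+step, ... while start + W <= end of trajectory;
    each window counts the preassigned cluster identities of frames with
    start <= t < start + W (no re-clustering).  Every vector spans all K
    clusters, including those with zero population in the window.
    """
    if step_ns <= 0:
        raise ValueError("step must be positive")
    times = assignment.frame_times
    t0, t_end = times[0], times[-1]
    if W_ns > t_end - t0 + 1e-9:
        raise ValueError("window length exceeds trajectory duration")
    K = assignment.n_clusters
    out = []
    start = t0
    while start + W_ns <= t_end + 1e-9:
        mask = (times >= start - 1e-9) & (times < start + W_ns - 1e-9)
        counts = np.bincount(assignment.labels[mask], minlength=K + 1)[1:]
        total = counts.sum()
        if total > 0:
            out.append(PopulationVector(float(start), float(W_ns), counts / total))
        start += step_ns
    return out


def cosine_distance(a: PopulationVector | np.ndarray, b: PopulationVector | np.ndarray) -> float:
    """Cosine distance d = 1 - a.b/(|a||b|) between population vectors.

    0 for identical population distributions, 1 for disjoint cluster support;
    scale-invariant.  Vectors must cover the same cluster index set.
    """
    va = a.fractions if isinstance(a, PopulationVector) else np.asarray(a, dtype=float)
    vb = b.fractions if isinstance(b, PopulationVector) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError("population vectors cover different cluster sets")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm population vector")
    if np.array_equal(va, vb):
        return 0.0
    d = 1.0 - float(np.dot(va, vb) / (na * nb))
    return min(max(d, 0.0), 1.0)


@dataclass
class CosineDistanceMatrix:
    window_starts_ns: np.ndarray
    window_length_ns: float
    matrix: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        t = np.round(self.window_starts_ns, 6)
        return pd.DataFrame(self.matrix, index=t, columns=t)


def distance_matrix(vectors: list[PopulationVector]) -> CosineDistanceMatrix:
    """Full pairwise cosine-distance matrix between window population vectors."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 windows")
    n = len(vectors)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = cosine_distance(vectors[i], vectors[j])
    return CosineDistanceMatrix(
        np.array([v.window_start_ns for v in vectors]),
        vectors[0].window_length_ns,
        M,
    )


@dataclass
class StableSegment:
    """Contiguous run of windows whose pairwise distances all stay below threshold."""

    t_a_ns: float
    t_b_ns: float
    window_length_ns: float
    first_window: int
    last_window: int
    max_internal_distance: float

    @property
    def duration_ns(self) -> float:
        return self.t_b_ns - self.t_a_ns + self.window_length_ns

    @property
    def n_windows(self) -> int:
        return self.last_window - self.first_window + 1


def find_stable_segments(
    dm: CosineDistanceMatrix,
    threshold: float = DEFAULT_STABILITY_THRESHOLD,
    min_windows: int = 2,
) -> list[StableSegment]:
    """Maximal diagonal blocks with all pairwise distances strictly below threshold.

    Greedy left-to-right expansion: starting from window i, j grows while the
    new column's maximum distance against [i..j] stays below the threshold;
    the block [i..j] is reported if it spans >= min_windows and the next
    search resumes at j+1.  Durations are t_b - t_a + W.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    M = dm.matrix
    t = dm.window_starts_ns
    n = len(t)
    segments = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and M[i : j + 2, j + 1].max() < threshold:
            j += 1
        if j - i + 1 >= min_windows:
            block = M[i : j + 1, i : j + 1]
            segments.append(
                StableSegment(
                    t_a_ns=float(t[i]),
                    t_b_ns=float(t[j]),
                    window_length_ns=dm.window_length_ns,
                    first_window=i,
                    last_window=j,
                    max_internal_distance=float(block.max()),
                )
            )
        i = j + 1
    return segments


def combined_cluster(
    traj_a: TrajectoryRecord,
    traj_b: TrajectoryRecord,
    region: RegionSpec,
    cutoff_nm: float = DEFAULT_CUTOFF_NM,
) -> tuple[ClusterAssignment, pd.DataFrame, float]:
    """Joint clustering of two trajectories' concatenated frames.

    Returns the joint assignment, a per-cluster occupancy table with each
    source's fractional contribution, and the ensemble overlap
    sum_k min(fracA_k, fracB_k) in [0, 1].
    """
    if traj_a.atom_table != traj_b.atom_table:
        raise ValueError("trajectories have different atom tables")
    coords = np.concatenate([traj_a.coordinates, traj_b.coordinates])
    # synthetic strictly-increasing time axis; window analysis is not meaningful here
    times = np.arange(coords.shape[0], dtype=float)
    joint = TrajectoryRecord(times, coords, traj_a.atom_table)
    assignment = gromos_cluster(joint, region, cutoff_nm)
    na = traj_a.n_frames
    src = np.zeros(coords.shape[0], dtype=int)
    src[na:] = 1
    rows = []
    frac_a = np.zeros(assignment.n_clusters)
    frac_b = np.zeros(assignment.n_clusters)
    for k in range(1, assignment.n_clusters + 1):
        in_k = assignment.labels == k
        ca = int(np.sum(in_k & (src == 0)))
        cb = int(np.sum(in_k & (src == 1)))
        frac_a[k - 1] = ca / na
        frac_b[k - 1] = cb / traj_b.n_frames
        rows.append({
            "cluster": k,
            "frames_a": ca,
            "frames_b": cb,
            "frac_a": frac_a[k - 1],
            "frac_b": frac_b[k - 1],
            "frac_of_cluster_from_a": ca / (ca + cb),
        })
    overlap = float(np.minimum(frac_a, frac_b).sum())
    return assignment, pd.DataFrame(rows), overlap


def extract_representatives(
    assignment: ClusterAssignment,
    traj: TrajectoryRecord,
    k: int = 20,
) -> TrajectoryRecord:
    """Medoid frames of the k most populated clusters, descending population."""
    if k < 1:
        raise ValueError("k must be >= 1")
    take = assignment.medoid_frames[: min(k, assignment.n_clusters)]
    # preserve descending-population order; retime to the medoids' original stamps
    coords = traj.coordinates[take]
    times = traj.frame_times[take]
    order = np.arange(len(take))
    # frame_times must be strictly increasing for the record; keep rank times
    return TrajectoryRecord(order.astype(float), coords, traj.atom_table)
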