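"""Trajectory-level statistics.

Superposition-based RMSD/RMSF, inter-strand phosphate distances, greedy
neighbour-count (gromos) clustering under a pairwise-RMSD cutoff, and
distribution summaries with a conservative two-component Gaussian-mixture
bimodality test (the detector behind the high/low twist-state analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._geom import kabsch
from .core import ResidueKey, Structure, Trajectory

__all__ = [
    "superpose", "rmsd_series", "rmsf", "interstrand_p_distances",
    "gromos_cluster", "ClusterResult", "distribution_summary", "DistSummary",
]

NM_TO_ANGSTROM = 10.0
GROMOS_DEFAULT_CUTOFF_NM = 0.2    # the clustering cutoff used for PS/PO runs

#: bimodality detector constants: BIC margin and minimum mean separation in
#: pooled standard deviations
BIMODAL_DELTA_BIC = 10.0
BIMODAL_MIN_SEPARATION_SD = 1.0
BIMODAL_MIN_SAMPLES = 50
_MIXTURE_SEED = 1234


def superpose(mobile: Structure, ref: Structure,
              selection: str = "all") -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile coordinates onto the
    reference; the rotation is proper (det = +1).
    """
    i_m = mobile.select(selection)
    i_r = ref.select(selection)
    if len(i_m) != len(i_r) or len(i_m) == 0:
        raise ValueError("selections do not map 1:1")
    return kabsch(mobile.coords[i_m], ref.coords[i_r])


def rmsd_series(traj: Trajectory, ref: Structure,
                selection: str = "P") -> np.ndarray:
    """Per-frame superposed RMSD on the selection (default: P atoms)."""
    return np.array([superpose(f, ref, selection)[2] for f in traj.frames])


def _superpose_stack(stack: np.ndarray, ref: np.ndarray) -> np.ndarray:
    out = np.empty_like(stack)
    for i, x in enumerate(stack):
        R, t, _ = kabsch(x, ref)
        out[i] = x @ R.T + t
    return out


def rmsf(traj: Trajectory, selection: str = "heavy",
         fit: bool = True) -> pd.DataFrame:
    """Per-residue root-mean-square fluctuation about the time average.

    Frames are superposed onto their mean structure in two passes (mean,
    re-superpose, mean) before the fluctuations are measured; ``fit=False``
    skips superposition for closed-form checks.
    """
    top = traj.topology
    idx = top.select(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    stack = traj.coord_stack(selection)
    if fit and len(idx) >= 3:
        for _ in range(2):
            mean = stack.mean(axis=0)
            stack = _superpose_stack(stack, mean)
    mean = stack.mean(axis=0)
    sq = ((stack - mean) ** 2).sum(axis=2)        # (frames, atoms)
    keys = list(zip(top.strand_ids[idx], top.res_indices[idx]))
    rows = []
    for key in dict.fromkeys(keys):
        cols = [j for j, k in enumerate(keys) if k == key]
        rows.append({"strand": key[0], "residue": int(key[1]),
                     "rmsf": float(np.sqrt(sq[:, cols].mean()))})
    return pd.DataFrame(rows)


def interstrand_p_distances(
    obj, pairing: Sequence[Tuple[ResidueKey, ResidueKey]]
) -> pd.DataFrame:
    """Phosphate-phosphate distance per base pair (mean ± sd over frames).

    Pairs whose member lacks a phosphate (5'-terminal residues) are
    reported with ``defined=False`` rather than raising.
    """
    frames = obj.frames if isinstance(obj, Trajectory) else [obj]
    top = frames[0]
    rows = []
    for k1, k2 in pairing:
        a1 = top.residue_atoms(k1)
        a2 = top.residue_atoms(k2)
        if "P" not in a1 or "P" not in a2:
            rows.append({"res1": f"{k1[0]}{k1[1]}", "res2": f"{k2[0]}{k2[1]}",
                         "defined": False, "mean": np.nan, "sd": np.nan})
            continue
        d = np.array([
            np.linalg.norm(f.coords[a1["P"]] - f.coords[a2["P"]])
            for f in frames
        ])
        rows.append({"res1": f"{k1[0]}{k1[1]}", "res2": f"{k2[0]}{k2[1]}",
                     "defined": True, "mean": float(d.mean()),
                     "sd": float(d.std(ddof=0))})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusterResult:
    """Partition of frames; cluster ids are 1-based in discovery order."""

    assignments: np.ndarray     # (n_frames,) cluster id per frame
    centers: List[int]          # frame index of each cluster centre
    sizes: List[int]

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def pairwise_rmsd_matrix(traj: Trajectory,
                         selection: str = "heavy") -> np.ndarray:
    stack = traj.coord_stack(selection)
    n = len(stack)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = kabsch(stack[j], stack[i])
            m[i, j] = m[j, i] = r
    return m


def gromos_cluster(traj: Trajectory, cutoff_nm: float = GROMOS_DEFAULT_CUTOFF_NM,
                   selection: str = "heavy") -> ClusterResult:
    """Greedy neighbour-count clustering on pairwise superposed RMSD.

    Repeatedly takes the frame with the most neighbours within the cutoff
    as a cluster centre, removes the cluster, and recurses on the rest.
    Ties are broken by the lowest frame index.  The cutoff is given in nm
    (the unit conventional for this method) and converted internally.
    """
    if cutoff_nm <= 0:
        raise ValueError("cutoff must be positive")
    cutoff = cutoff_nm * NM_TO_ANGSTROM
    m = pairwise_rmsd_matrix(traj, selection)
    n = m.shape[0]
    remaining = np.ones(n, bool)
    assignments = np.zeros(n, int)
    centers: List[int] = []
    sizes: List[int] = []
    cluster_id = 0
    while remaining.any():
        cluster_id += 1
        idx = np.nonzero(remaining)[0]
        neigh = (m[np.ix_(idx, idx)] <= cutoff)
        counts = neigh.sum(axis=1)
        centre_pos = int(np.argmax(counts))      # argmax keeps lowest index on ties
        centre = int(idx[centre_pos])
        members = idx[neigh[centre_pos]]
        assignments[members] = cluster_id
        centers.append(centre)
        sizes.append(len(members))
        remaining[members] = False
    # re-rank clusters by non-increasing size (stable for ties)
    order = sorted(range(len(sizes)), key=lambda k: (-sizes[k], k))
    remap = {old + 1: new + 1 for new, old in enumerate(order)}
    assignments = np.array([remap[a] for a in assignments])
    centers = [centers[k] for k in order]
    sizes = [sizes[k] for k in order]
    return ClusterResult(assignments=assignments, centers=centers, sizes=sizes)


@dataclass(frozen=True)
class DistSummary:
    mean: float
    sd: float
    bin_edges: np.ndarray
    counts: np.ndarray
    bimodal: bool
    component_means: Optional[Tuple[float, float]] = None
    note: Optional[str] = None


def distribution_summary(series, bins: int = 50) -> DistSummary:
    """Mean/SD/histogram plus a conservative bimodality call.

    Bimodality requires a two-component Gaussian mixture to beat one
    component by ΔBIC > 10 *and* the component means to differ by more
    than one pooled standard deviation; fewer than 50 samples always
    yields ``bimodal=False`` with a note.  The mixture fit uses a fixed
    internal seed for reproducibility.
    """
    x = np.asarray(series, float).ravel()
    if x.size == 0:
        raise ValueError("empty series")
    if x.max() - x.min() < 1e-9:     # (near-)constant: pad the bin range
        counts, edges = np.histogram(x, bins=bins,
                                     range=(x.mean() - 0.5, x.mean() + 0.5))
    else:
        counts, edges = np.histogram(x, bins=bins)
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    if x.size < BIMODAL_MIN_SAMPLES:
        return DistSummary(mean, sd, edges, counts, False,
                           note="too few samples for bimodality test")
    if sd == 0.0:
        return DistSummary(mean, sd, edges, counts, False)
    X = x[:, None]
    g1 = GaussianMixture(1, random_state=_MIXTURE_SEED).fit(X)
    g2 = GaussianMixture(2, random_state=_MIXTURE_SEED, n_init=3).fit(X)
    delta_bic = g1.bic(X) - g2.bic(X)
    mu = np.sort(g2.means_.ravel())
    pooled_sd = float(np.sqrt(g2.covariances_.ravel() @ g2.weights_))
    separated = abs(mu[1] - mu[0]) > BIMODAL_MIN_SEPARATION_SD * pooled_sd
    bimodal = bool(delta_bic > BIMODAL_DELTA_BIC and separated)
    return DistSummary(mean, sd, edges, counts, bimodal,
                       component_means=(float(mu[0]), float(mu[1])) if bimodal else None)
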