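"""Mass-univariate inference: voxelwise GLM, cluster-extent FWE, TFCE-FWE.

The regressor of interest (serum CRP) is tested voxel-by-voxel with an OLS
multiple regression against nuisance covariates.  Family-wise error is
controlled by permutation rather than random-field theory: nuisance
covariates are handled with the Freedman-Lane scheme (residuals of the
reduced model are permuted and added back to the reduced-model fit), and the
null distribution of the maximum statistic — maximum suprathreshold cluster
extent for volumetric fALFF maps, maximum TFCE score for skeletonized
diffusion panels — is accumulated over permutations, separately per contrast
sign.  Permutation p-values use the (1 + #exceedances)/(n_perm + 1)
convention, so they are never exactly zero.

TFCE (threshold-free cluster enhancement) integrates, over an ascending
ladder of thresholds h, extent(h, v)^E * h^H * dh for each voxel v, where
extent is the size of the connected component containing v at threshold h.
Defaults E=0.5, H=2 are the de-facto standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage, stats

__all__ = [
    "build_design",
    "fit_voxelwise_glm",
    "freedman_lane_tstats",
    "cluster_fwe",
    "tfce_transform",
    "tfce_fwe",
    "extract_roi",
    "TfceParams",
    "grid_edges",
]


@dataclass
class TfceParams:
    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100

    def validate(self):
        if self.E <= 0 or self.H <= 0 or self.n_steps <= 0:
            raise ValueError("TFCE parameters must be positive")


def build_design(subjects: pd.DataFrame, interest: str = "crp",
                 covariates=("age", "sex", "education", "fd")):
    """Design matrix [intercept, interest, covariates...].

    Returns (X, names, interest_index).  Raises on rank deficiency, naming
    the collinear columns.
    """
    cols = [interest] + list(covariates)
    X = np.column_stack([np.ones(len(subjects))] +
                        [subjects[c].to_numpy(float) for c in cols])
    names = ["intercept"] + cols
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify columns whose removal restores full rank
        bad = [names[i] for i in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == r]
        raise ValueError(f"design matrix rank-deficient; collinear columns: "
                         f"{bad}")
    if len(subjects) <= X.shape[1] + 2:
        raise ValueError("too few subjects for design")
    return X, names, 1


def _tstat_engine(X: np.ndarray, j: int):
    """Precompute pieces for fast repeated t-statistics of column j."""
    XtXinv = np.linalg.inv(X.T @ X)
    P = XtXinv @ X.T                      # (p, n)
    cjj = XtXinv[j, j]
    dof = X.shape[0] - X.shape[1]

    def tstats(Y: np.ndarray) -> np.ndarray:
        beta = P @ Y                      # (p, V)
        resid = Y - X @ beta
        sigma2 = (resid * resid).sum(0) / dof
        se = np.sqrt(sigma2 * cjj)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta[j] / se, 0.0)
        return t

    return tstats, dof


def fit_voxelwise_glm(Y: np.ndarray, X: np.ndarray, interest_idx: int = 1):
    """OLS t-statistics of the regressor of interest for each voxel.

    Y : (n_subjects, V) panel; X : (n_subjects, p) full-rank design.
    Returns (t (V,), dof).
    """
    Y = np.asarray(Y, float)
    if np.isnan(Y).any() or np.isnan(X).any():
        raise ValueError("missing values in panel or design; apply listwise "
                         "deletion first")
    tstats, dof = _tstat_engine(X, interest_idx)
    return tstats(Y), dof


def freedman_lane_tstats(Y: np.ndarray, X: np.ndarray, interest_idx: int,
                         n_perm: int, rng: np.random.Generator):
    """Yield permutation t-maps under the Freedman-Lane scheme.

    The reduced model (nuisance only) is fitted once; its residuals are
    row-permuted and added back to the reduced fit before refitting the full
    model, which keeps nuisance effects intact under the null.
    """
    Z = np.delete(X, interest_idx, axis=1)
    Bz = np.linalg.lstsq(Z, Y, rcond=None)[0]
    F = Z @ Bz
    R = Y - F
    tstats, _ = _tstat_engine(X, interest_idx)
    n = Y.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yield tstats(F + R[perm])


def _label_clusters(vol: np.ndarray, connectivity: int = 26):
    struct = ndimage.generate_binary_structure(3, 3 if connectivity == 26
                                               else 1)
    return ndimage.label(vol, structure=struct)


def cluster_fwe(Y: np.ndarray, X: np.ndarray, shape, mask: np.ndarray,
                interest_idx: int = 1, cdt_p: float = 0.001,
                n_perm: int = 1000, connectivity: int = 26,
                seed: int = 0, voxel_size: float = 1.0):
    """Cluster-extent FWE inference on a volumetric panel.

    Clusters are formed at |t| above the one-sided cluster-defining threshold
    separately for positive and negative contrasts; the permutation null of
    the maximum cluster extent is built per sign.

    Returns (cluster_table DataFrame, label_volume, t_volume).
    """
    if not 0 < cdt_p < 1:
        raise ValueError("cdt_p must be in (0, 1)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    mask = np.asarray(mask, bool)
    t, dof = fit_voxelwise_glm(Y, X, interest_idx)
    thr = stats.t.ppf(1 - cdt_p, dof)

    tvol = np.zeros(shape)
    tvol[mask] = t

    null_max = {1: np.zeros(n_perm, int), -1: np.zeros(n_perm, int)}
    rng = np.random.default_rng(seed)
    for k, t_perm in enumerate(freedman_lane_tstats(Y, X, interest_idx,
                                                    n_perm, rng)):
        pvol = np.zeros(shape)
        pvol[mask] = t_perm
        for sign in (1, -1):
            lab, nlab = _label_clusters(sign * pvol > thr, connectivity)
            if nlab:
                null_max[sign][k] = np.bincount(lab.ravel())[1:].max()

    rows = []
    label_vol = np.zeros(shape, int)
    next_id = 1
    for sign in (1, -1):
        lab, nlab = _label_clusters(sign * tvol > thr, connectivity)
        for c in range(1, nlab + 1):
            members = lab == c
            size = int(members.sum())
            p_fwe = (1 + (null_max[sign] >= size).sum()) / (n_perm + 1)
            tv = tvol[members]
            peak_flat = np.argmax(sign * tv)
            peak_ijk = np.argwhere(members)[peak_flat]
            rows.append({
                "cluster_id": next_id, "sign": sign, "size": size,
                "peak_i": int(peak_ijk[0]), "peak_j": int(peak_ijk[1]),
                "peak_k": int(peak_ijk[2]),
                "peak_t": float(tv[peak_flat]), "p_fwe": p_fwe,
            })
            label_vol[members] = next_id
            next_id += 1
    table = pd.DataFrame(rows, columns=["cluster_id", "sign", "size",
                                        "peak_i", "peak_j", "peak_k",
                                        "peak_t", "p_fwe"])
    if len(table):
        table = table.sort_values("size", ascending=False,
                                  ignore_index=True)
    return table, label_vol, tvol


@njit(cache=True)
def _uf_find(parent, i):
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        parent[i], i = root, parent[i]
    return root


@njit(cache=True)
def _tfce_core(t, edges, E, H, dh, n_steps):
    V = t.shape[0]
    out = np.zeros(V)
    parent = np.empty(V, np.int64)
    size = np.empty(V, np.int64)
    for s in range(1, n_steps + 1):
        h = dh * s
        active = t >= h
        if not active.any():
            break
        for i in range(V):
            parent[i] = i
            size[i] = 1
        for e in range(edges.shape[0]):
            a, b = edges[e, 0], edges[e, 1]
            if active[a] and active[b]:
                ra = _uf_find(parent, a)
                rb = _uf_find(parent, b)
                if ra != rb:
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    parent[rb] = ra
                    size[ra] += size[rb]
        inc = h ** H * dh
        for i in range(V):
            if active[i]:
                out[i] += size[_uf_find(parent, i)] ** E * inc
    return out


def grid_edges(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Edge list (pairs of in-mask flat indices) for a voxel grid."""
    mask = np.asarray(mask, bool)
    idx = -np.ones(mask.shape, int)
    idx[mask] = np.arange(mask.sum())
    offs = []
    rng3 = (-1, 0, 1)
    for di in rng3:
        for dj in rng3:
            for dk in rng3:
                if (di, dj, dk) <= (0, 0, 0):
                    continue
                if connectivity == 6 and abs(di) + abs(dj) + abs(dk) != 1:
                    continue
                offs.append((di, dj, dk))
    edges = []
    coords = np.argwhere(mask)
    for di, dj, dk in offs:
        nb = coords + np.array([di, dj, dk])
        ok = ((nb >= 0).all(1) & (nb < np.array(mask.shape)).all(1))
        nb = nb[ok]
        src = idx[coords[ok, 0], coords[ok, 1], coords[ok, 2]]
        dst = idx[nb[:, 0], nb[:, 1], nb[:, 2]]
        good = dst >= 0
        edges.append(np.column_stack([src[good], dst[good]]))
    if edges:
        return np.vstack(edges).astype(np.int64)
    return np.empty((0, 2), np.int64)


def tfce_transform(t: np.ndarray, edges, params: TfceParams | None = None,
                   dh: float | None = None) -> np.ndarray:
    """TFCE scores of the positive part of ``t`` on an arbitrary graph.

    ``edges`` is an (E, 2) array of voxel-index pairs (e.g. skeleton
    adjacency, or :func:`grid_edges` output).  Negative effects are handled
    by the callers via ``tfce_transform(-t, ...)``.  ``dh`` defaults to
    max(t)/n_steps; passing it explicitly keeps the integration grid fixed
    across permutations.
    """
    params = params or TfceParams()
    params.validate()
    t = np.ascontiguousarray(np.asarray(t, float))
    edges = np.ascontiguousarray(np.asarray(edges, np.int64).reshape(-1, 2))
    tmax = t.max(initial=0.0)
    if tmax <= 0:
        return np.zeros_like(t)
    if dh is None:
        dh = tmax / params.n_steps
    n_steps = int(np.ceil(tmax / dh))
    return _tfce_core(t, edges, params.E, params.H, dh, n_steps)


def tfce_fwe(Y: np.ndarray, X: np.ndarray, edges, interest_idx: int = 1,
             params: TfceParams | None = None, n_perm: int = 1000,
             seed: int = 0):
    """Voxelwise FWE-corrected p from the max-TFCE permutation null.

    Returns (p_pos, p_neg, tfce_pos, tfce_neg, t): per-voxel corrected
    p-values for the positive and the negative contrast.
    """
    params = params or TfceParams()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t, _ = fit_voxelwise_glm(Y, X, interest_idx)
    dh = max(np.abs(t).max(), 1e-12) / params.n_steps
    obs = {1: tfce_transform(t, edges, params, dh),
           -1: tfce_transform(-t, edges, params, dh)}
    null_max = {1: np.zeros(n_perm), -1: np.zeros(n_perm)}
    rng = np.random.default_rng(seed)
    for k, t_perm in enumerate(freedman_lane_tstats(Y, X, interest_idx,
                                                    n_perm, rng)):
        for sign in (1, -1):
            s = tfce_transform(sign * t_perm, edges, params, dh)
            null_max[sign][k] = s.max(initial=0.0)
    p = {}
    for sign in (1, -1):
        exceed = (null_max[sign][None, :] >= obs[sign][:, None]).sum(1)
        p[sign] = (1 + exceed) / (n_perm + 1)
    return p[1], p[-1], obs[1], obs[-1], t


def extract_roi(panel: np.ndarray, labels: np.ndarray,
                roi_ids=None) -> np.ndarray:
    """Per-subject mean over member voxels of each ROI.

    panel : (n_subjects, V); labels : (V,) integer ROI labels (0 ignored).
    Returns (n_subjects, n_rois) in ascending ROI-id order (or ``roi_ids``).
    """
    panel = np.atleast_2d(np.asarray(panel, float))
    labels = np.asarray(labels).ravel()
    if labels.shape[0] != panel.shape[1]:
        raise ValueError("labels length must match panel voxels")
    if roi_ids is None:
        roi_ids = np.unique(labels)
        roi_ids = roi_ids[roi_ids != 0]
    out = np.empty((panel.shape[0], len(roi_ids)))
    for k, r in enumerate(roi_ids):
        m = labels == r
        if not m.any():
            raise ValueError(f"ROI {r} has no member voxels")
        out[:, k] = panel[:, m].mean(1)
    return out
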