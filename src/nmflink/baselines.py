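"""Classical similarity indices for link prediction.

Twelve local indices (CN, Salton, Jaccard, Sorenson, HPI, HDI, LHN, AA,
RA, PA, LP, CRA) and five global ones (Katz, LHNII, ACT, TSCN, SPM).
Local indices are built from common-neighbour counts and degrees; global
indices use whole-matrix quantities (path sums, Laplacian pseudo-inverse,
spectral perturbation). Degree-zero denominators score 0 by convention.

TSCN is figure-mangled in its source description; the implementation here
follows the transferring-similarity idea (propagating common-neighbour
similarity along edges with damping eps) and should be treated as
experimental.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import derive_rng
from .net_core import Network
from .predictor import SimilarityMatrix, symmetrize
from .sampling import round_half_away

__all__ = [
    "BaselineParams",
    "LOCAL_INDICES",
    "GLOBAL_INDICES",
    "local_similarity",
    "global_similarity",
    "baseline_similarity",
]

LOCAL_INDICES = (
    "CN",
    "Salton",
    "Jaccard",
    "Sorenson",
    "HPI",
    "HDI",
    "LHN",
    "AA",
    "RA",
    "PA",
    "LP",
    "CRA",
)
GLOBAL_INDICES = ("Katz", "LHNII", "ACT", "TSCN", "SPM")


@dataclass(frozen=True)
class BaselineParams:
    lp_alpha: float = 1e-4
    katz_alpha: float = 0.01
    lhn2_phi: float = 0.99
    lhn2_psi: float = 1.0
    spm_eta: float = 0.1
    spm_r: int = 20
    tscn_eps: float = 0.01


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    mask = den > 0
    out[mask] = num[mask] / den[mask]
    return out


def _cra_scores(a: np.ndarray, cn: np.ndarray, deg: np.ndarray) -> np.ndarray:
    """CRA: sum over common neighbours z of d_z / k_z, where d_z counts
    links from z to the other common neighbours of the pair."""
    n = a.shape[0]
    s = np.zeros((n, n))
    ii, jj = np.nonzero(np.triu(cn, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        common = np.nonzero((a[i] > 0) & (a[j] > 0))[0]
        sub = a[np.ix_(common, common)]
        d = sub.sum(axis=1)
        val = float(np.sum(_safe_div(d, deg[common])))
        s[i, j] = s[j, i] = val
    return s


def local_similarity(
    train: Network, index: str, params: BaselineParams | None = None
) -> SimilarityMatrix:
    """Score every node pair with one of the local indices."""
    if index not in LOCAL_INDICES:
        raise ValueError(f"unknown local index {index!r}")
    params = params or BaselineParams()
    a = train.adjacency.astype(np.float64)
    deg = train.degrees().astype(np.float64)
    cn = a @ a
    kx = deg[:, None]
    ky = deg[None, :]

    if index == "CN":
        s = cn
    elif index == "Salton":
        s = _safe_div(cn, np.sqrt(kx * ky))
    elif index == "Jaccard":
        s = _safe_div(cn, kx + ky - cn)
    elif index == "Sorenson":
        s = _safe_div(2.0 * cn, kx + ky)
    elif index == "HPI":
        s = _safe_div(cn, np.minimum(kx, ky))
    elif index == "HDI":
        s = _safe_div(cn, np.maximum(kx, ky))
    elif index == "LHN":
        s = _safe_div(cn, kx * ky)
    elif index == "AA":
        # common neighbours necessarily have degree >= 2, so log(k) > 0
        w = np.where(deg > 1, 1.0 / np.log(np.where(deg > 1, deg, 2.0)), 0.0)
        s = a @ np.diag(w) @ a
    elif index == "RA":
        w = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
        s = a @ np.diag(w) @ a
    elif index == "PA":
        s = kx * ky
    elif index == "LP":
        s = cn + params.lp_alpha * (cn @ a)
    elif index == "CRA":
        s = _cra_scores(a, cn, deg)
    return SimilarityMatrix(scores=symmetrize(s), method_tag=index)


def _spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvalsh(a))))


def _katz(a: np.ndarray, alpha: float) -> np.ndarray:
    rho = _spectral_radius(a)
    if rho > 0 and alpha >= 1.0 / rho:
        raise ValueError(
            f"katz_alpha={alpha} must be below 1/spectral_radius = {1.0 / rho:.6g}"
        )
    n = a.shape[0]
    return np.linalg.inv(np.eye(n) - alpha * a) - np.eye(n)


def _lhn2(a: np.ndarray, m: int, phi: float, psi: float) -> np.ndarray:
    lam1 = _spectral_radius(a)
    if lam1 == 0:
        raise ValueError("LHNII undefined on an edgeless graph")
    if not 0 < phi < 1:
        raise ValueError("lhn2_phi must be in (0, 1)")
    n = a.shape[0]
    deg = a.sum(axis=1)
    dinv = np.diag(np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0))
    core = np.linalg.inv(np.eye(n) - (phi / lam1) * a)
    return psi * 2.0 * m * lam1 * (dinv @ core @ dinv)


def _act(a: np.ndarray) -> np.ndarray:
    deg = a.sum(axis=1)
    lap = np.diag(deg) - a
    lp = np.linalg.pinv(lap)
    d = np.diag(lp)
    denom = d[:, None] + d[None, :] - 2.0 * lp
    s = np.zeros_like(a)
    mask = denom > 1e-12
    s[mask] = 1.0 / denom[mask]
    return s


def _tscn(a: np.ndarray, eps: float) -> np.ndarray:
    rho = _spectral_radius(a)
    if rho > 0 and eps >= 1.0 / rho:
        raise ValueError(
            f"tscn_eps={eps} must be below 1/spectral_radius = {1.0 / rho:.6g}"
        )
    n = a.shape[0]
    cn = a @ a
    return np.linalg.inv(np.eye(n) - eps * a) @ cn


def _spm(train: Network, eta: float, r: int, seed: int) -> np.ndarray:
    """Spectral perturbation average: for each draw, remove a random
    eta-fraction of training edges, eigendecompose the reduced matrix and
    add first-order eigenvalue corrections from the removed part."""
    a = train.adjacency.astype(np.float64)
    edges = train.edges()
    n_delta = round_half_away(eta * len(edges))
    acc = np.zeros_like(a)
    for rep in range(r):
        rng = derive_rng(seed, "spm", rep)
        da = np.zeros_like(a)
        if n_delta:
            for i in rng.choice(len(edges), size=n_delta, replace=False):
                u, v = edges[i]
                da[u, v] = da[v, u] = 1.0
        reduced = a - da
        lam, x = np.linalg.eigh(reduced)
        dlam = np.einsum("ik,ij,jk->k", x, da, x)  # x_k^T dA x_k, x orthonormal
        acc += (x * (lam + dlam)) @ x.T
        if n_delta == 0:
            # all draws identical; no need to repeat
            return acc
    return acc / r


def global_similarity(
    train: Network,
    index: str,
    params: BaselineParams | None = None,
    seed: int = 0,
) -> SimilarityMatrix:
    """Score every node pair with one of the global indices. Only SPM is
    stochastic (seeded edge-removal draws)."""
    if index not in GLOBAL_INDICES:
        raise ValueError(f"unknown global index {index!r}")
    params = params or BaselineParams()
    a = train.adjacency.astype(np.float64)

    if index == "Katz":
        s = _katz(a, params.katz_alpha)
    elif index == "LHNII":
        s = _lhn2(a, train.n_edges, params.lhn2_phi, params.lhn2_psi)
    elif index == "ACT":
        s = _act(a)
    elif index == "TSCN":
        s = _tscn(a, params.tscn_eps)
    elif index == "SPM":
        s = _spm(train, params.spm_eta, params.spm_r, seed)
    return SimilarityMatrix(scores=symmetrize(s), method_tag=index)


def baseline_similarity(
    train: Network,
    index: str,
    params: BaselineParams | None = None,
    seed: int = 0,
) -> SimilarityMatrix:
    """Dispatch to the local or global implementation by index name."""
    if index in LOCAL_INDICES:
        return local_similarity(train, index, params)
    if index in GLOBAL_INDICES:
        return global_similarity(train, index, params, seed)
    raise ValueError(f"unknown similarity index {index!r}")
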