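"""Ecological distances, their kernel transforms, and composition kernels.

Distances on the community matrix Z:

* Bray-Curtis: D_ab = sum_j |Z_aj - Z_bj| / sum_j (Z_aj + Z_bj), no tree.
* UniFrac family on a rooted tree: each branch b with length l_b carries the
  total abundance of its descendant tips, p_ab for sample a. Unweighted
  UniFrac compares presence/absence of lineages; generalized UniFrac with
  exponent theta weights each branch by (p_a + p_b)^theta and compares
  |p_a - p_b| / (p_a + p_b); theta = 1 recovers the normalised weighted
  UniFrac and theta = 0.5 the usual compromise.

Distances feed the kernel machinery through Gower's double centering
K = -(1/2) (I - 11'/n) D^2 (I - 11'/n) with negative eigenvalues clamped
to zero, and the composition itself provides the powered linear kernels
R(gamma) = Z^gamma (Z^gamma)^T used by MiSALN.

For taxon-level testing Z carries community-total-normalised abundances
(rows do not sum to one) and the tree is pruned to the taxon's tips; the
same branch-proportion formulas then apply unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import skbio
from scipy.spatial.distance import pdist, squareform

from .exceptions import ConfigurationError, ParameterError, ValidationError
from .io_formats import CommunityMatrix

GAMMA_DEFAULT = (0.25, 1 / 3, 0.5, 1.0)
PSI_DEFAULT = ("u", "g0.5", "w", "bc")

KERNEL_LABELS = {"u": "MiRKAT-S(Ku)", "g0.5": "MiRKAT-S(K0.5)",
                 "w": "MiRKAT-S(Kw)", "bc": "MiRKAT-S(Kbc)"}

PSD_TOL = 1e-10


def gamma_label(gamma: float) -> str:
    for num, den in ((1, 4), (1, 3), (1, 2), (1, 1), (2, 3), (3, 4)):
        if abs(gamma - num / den) < 1e-12:
            return f"MiSALN({num}/{den})" if den != 1 else f"MiSALN({num})"
    return f"MiSALN({gamma:g})"


@dataclass
class DistanceMatrix:
    data: np.ndarray
    metric: str
    sample_ids: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n, m = self.data.shape
        if n != m:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(self.data, self.data.T, atol=1e-10):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.data)) > 1e-12):
            raise ValidationError("distance matrix must have a zero diagonal")
        if np.any(self.data < -1e-12):
            raise ValidationError("distances must be non-negative")


@dataclass
class KernelBank:
    """Named collection of symmetric PSD matrices: the candidate set of the
    adaptive tests. ``misaln_labels`` index the powered-composition
    correlations (one per gamma), ``mirkats_labels`` the distance kernels."""

    matrices: dict[str, np.ndarray] = field(default_factory=dict)
    misaln_labels: list[str] = field(default_factory=list)
    mirkats_labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def labels(self) -> list[str]:
        return list(self.matrices)


# ---------------------------------------------------------------------------
# tree indexing
# ---------------------------------------------------------------------------

class TreeIndex:
    """Branch-length vector and branch x OTU membership matrix for fast
    UniFrac. Build once per (tree, OTU set) and reuse across samples."""

    def __init__(self, tree: skbio.TreeNode, otu_ids: list[str]):
        otu_pos = {o: i for i, o in enumerate(otu_ids)}
        tip_names = {t.name for t in tree.tips()}
        missing = [o for o in otu_ids if o not in tip_names]
        if missing:
            raise ValidationError(f"OTUs absent from tree: {missing[:10]}")
        lens = []
        member_rows = []
        for node in tree.postorder(include_self=False):
            length = node.length or 0.0
            row = np.zeros(len(otu_ids), dtype=bool)
            tips = [node] if node.is_tip() else node.tips()
            for t in tips:
                j = otu_pos.get(t.name)
                if j is not None:
                    row[j] = True
            if row.any():
                lens.append(length)
                member_rows.append(row)
        self.branch_lengths = np.asarray(lens)
        self.membership = np.asarray(member_rows)  # (n_branches, p)
        self.otu_ids = list(otu_ids)

    @property
    def n_branches(self) -> int:
        return len(self.branch_lengths)

    def branch_abundance(self, Z: np.ndarray) -> np.ndarray:
        """Per-sample total abundance below each branch, (n, n_branches)."""
        return Z @ self.membership.T


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def bray_curtis(Z: CommunityMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on relative abundances."""
    vals = Z.values
    if np.any(vals < 0):
        raise ValidationError("abundances must be non-negative")
    with np.errstate(invalid="ignore", divide="ignore"):
        D = squareform(pdist(vals, metric="braycurtis"))
    if np.isnan(D).any():
        warnings.warn("sample pairs with no abundance at all: distance set to 0")
        D = np.nan_to_num(D, nan=0.0)
    return DistanceMatrix(D, "bray-curtis", list(Z.sample_ids))


def _pairwise_unifrac(P: np.ndarray, lens: np.ndarray, variant: str,
                      theta: float | None) -> np.ndarray:
    """Pairwise UniFrac from branch abundances P (n, n_branches).

    Unweighted and weighted (theta = 1) decompose into a Manhattan
    distance on length-scaled branch profiles plus rank-one / Gram terms,
    so they run through pdist and BLAS. General theta needs genuinely
    pairwise branch sums and is evaluated over the upper triangle.
    """
    n = P.shape[0]
    if variant == "unweighted":
        pres = (P > 0).astype(float)
        L = pres * lens
        num = squareform(pdist(L, metric="cityblock"))
        tot = L.sum(axis=1)
        # sum_b l_b max(a,b) = sum_b l_b (a + b - a*b) for 0/1 indicators
        den = tot[:, None] + tot[None, :] - L @ pres.T
    elif variant == "weighted" or (theta is not None and theta == 1.0):
        L = P * lens
        num = squareform(pdist(L, metric="cityblock"))
        tot = L.sum(axis=1)
        den = tot[:, None] + tot[None, :]
    else:
        num = np.zeros((n, n))
        den = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        chunk = max(1, int(2e6 // max(P.shape[1], 1)))
        for start in range(0, len(iu), chunk):
            a = P[iu[start:start + chunk]]
            b = P[ju[start:start + chunk]]
            s = a + b
            s_safe = s + (s == 0)
            w = lens * (np.sqrt(s) if theta == 0.5 else s_safe ** theta * (s > 0))
            num[iu[start:start + chunk], ju[start:start + chunk]] = \
                (w * (np.abs(a - b) / s_safe)).sum(axis=1)
            den[iu[start:start + chunk], ju[start:start + chunk]] = w.sum(axis=1)
        num += num.T
        den += den.T
        den[np.diag_indices(n)] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(D, 0.0)
    return 0.5 * (D + D.T)


def unifrac(Z: CommunityMatrix, tree: skbio.TreeNode | TreeIndex,
            variant: str = "unweighted", theta: float = 0.5) -> DistanceMatrix:
    """UniFrac distance matrix; ``variant`` is one of unweighted, weighted,
    generalized. ``theta`` applies to the generalized variant only."""
    if variant not in ("unweighted", "weighted", "generalized"):
        raise ParameterError(f"unknown UniFrac variant: {variant!r}")
    if variant == "generalized" and not 0.0 <= theta <= 1.0:
        raise ParameterError("theta must lie in [0, 1]")
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree, Z.otu_ids)
    if idx.otu_ids != list(Z.otu_ids):
        raise ValidationError("TreeIndex OTU order does not match community matrix")
    P = idx.branch_abundance(Z.values)
    D = _pairwise_unifrac(P, idx.branch_lengths, variant,
                          theta if variant == "generalized" else None)
    name = {"unweighted": "unweighted-unifrac", "weighted": "weighted-unifrac",
            "generalized": f"generalized-unifrac({theta:g})"}[variant]
    return DistanceMatrix(D, name, list(Z.sample_ids))


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def distance_to_kernel(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower-center the squared distances and clamp negative eigenvalues.

    K = -(1/2) (I - 11'/n) D∘D (I - 11'/n); the eigendecomposition repair
    keeps the result positive semi-definite for non-Euclidean distances.
    """
    mat = D.data if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValidationError("distance matrix is not symmetric")
    n = mat.shape[0]
    D2 = mat * mat
    J = np.eye(n) - np.ones((n, n)) / n
    K = -0.5 * (J @ D2 @ J)
    K = 0.5 * (K + K.T)
    evals, evecs = np.linalg.eigh(K)
    if evals[0] < -PSD_TOL:
        evals = np.clip(evals, 0.0, None)
        K = (evecs * evals) @ evecs.T
        K = 0.5 * (K + K.T)
    return K


def misaln_correlation(Z: CommunityMatrix | np.ndarray, gamma: float) -> np.ndarray:
    """Powered-composition correlation R = Z^gamma (Z^gamma)^T, with
    0^gamma = 0. gamma < 1 up-weights rare OTUs, gamma = 1 is the linear
    kernel on the original scale."""
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    vals = Z.values if isinstance(Z, CommunityMatrix) else np.asarray(Z, dtype=float)
    if np.any(vals < 0) or np.any(vals > 1 + 1e-12):
        raise ValidationError("composition entries must lie in [0, 1]")
    Zg = np.power(vals, gamma)
    R = Zg @ Zg.T
    return 0.5 * (R + R.T)


def build_kernel_bank(Z: CommunityMatrix,
                      tree: skbio.TreeNode | TreeIndex | None = None,
                      gammas=GAMMA_DEFAULT,
                      kernels=PSI_DEFAULT) -> KernelBank:
    """Assemble the candidate matrices for the adaptive tests.

    ``gammas`` gives the MiSALN powers; ``kernels`` names the distance
    kernels ('u', 'g<theta>', 'w', 'bc'). Defaults are the paper-standard
    Gamma = {1/4, 1/3, 1/2, 1} and Psi = {K_U, K_0.5, K_W, K_BC}.
    """
    bank = KernelBank()
    for g in gammas:
        lab = gamma_label(g)
        bank.matrices[lab] = misaln_correlation(Z, g)
        bank.misaln_labels.append(lab)
    needs_tree = [k for k in kernels if k != "bc"]
    idx: TreeIndex | None = None
    if needs_tree:
        if tree is None:
            raise ConfigurationError(
                f"kernels {needs_tree} require a phylogenetic tree"
            )
        idx = tree if isinstance(tree, TreeIndex) else TreeIndex(tree, Z.otu_ids)
    for k in kernels:
        if k == "bc":
            D = bray_curtis(Z)
            lab = KERNEL_LABELS["bc"]
        elif k == "u":
            D = unifrac(Z, idx, "unweighted")
            lab = KERNEL_LABELS["u"]
        elif k == "w":
            D = unifrac(Z, idx, "weighted")
            lab = KERNEL_LABELS["w"]
        elif k.startswith("g"):
            theta = float(k[1:])
            D = unifrac(Z, idx, "generalized", theta=theta)
            lab = KERNEL_LABELS.get(k, f"MiRKAT-S(K{theta:g})")
        else:
            raise ParameterError(f"unknown kernel spec: {k!r}")
        bank.matrices[lab] = distance_to_kernel(D)
        bank.mirkats_labels.append(lab)
    return bank
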