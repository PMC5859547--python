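"""Variance-component score tests and the adaptive min-p machinery.

Every candidate test takes the quadratic form U = r' M r of the martingale
residuals r with one candidate matrix M: the powered-composition
correlations give the MiSALN(gamma) statistics, the distance kernels the
MiRKAT-S(k) statistics. p-values come from a single shared set of B
residual permutations ("no double permutations"):

* candidate p:  p_c = (1 + #{b : U_c(b) >= U_c(obs)}) / (B + 1)
* within each permutation b, a rank-based pseudo p-value
  p_c(b) = #{b' : U_c(b') >= U_c(b)} / B is computed for every candidate,
  and the per-permutation minimum over a candidate set plays the role of
  the adaptive statistic under the null;
* adaptive p:  (1 + #{b : min_c p_c(b) <= Q_obs}) / (B + 1) where
  Q_obs = min_c p_c is the observed minimum p-value.

OMiSALN minimises over the gamma candidates, OMiRKAT-S over the kernel
candidates, and OMiSA over all of them. The add-one convention keeps every
p-value strictly positive, and ties are resolved in the conservative
direction (>= for statistics, <= for minima).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import skbio

from .community_metrics import (GAMMA_DEFAULT, PSI_DEFAULT, KernelBank,
                                TreeIndex, build_kernel_bank)
from .cox_null import NullFit, fit_null_model
from .exceptions import ParameterError, ValidationError
from .io_formats import CommunityMatrix, SurvivalData

ADAPTIVE_LABELS = ("OMiSALN", "OMiRKAT-S", "OMiSA")


@dataclass
class TestResult:
    """Per-candidate statistics/p-values plus the three adaptive tests."""

    statistics: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    min_p: dict[str, float] = field(default_factory=dict)       # Q statistics
    adaptive_p: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None

    def all_p_values(self) -> dict[str, float]:
        return {**self.p_values, **self.adaptive_p}

    def to_frame(self):
        import pandas as pd

        rows = [{"test": lab, "statistic": self.statistics[lab],
                 "p_value": self.p_values[lab]} for lab in self.p_values]
        rows += [{"test": lab, "statistic": self.min_p[lab],
                  "p_value": self.adaptive_p[lab]} for lab in self.adaptive_p]
        return pd.DataFrame(rows)


def score_statistic(residuals: np.ndarray, M: np.ndarray) -> float:
    """Quadratic-form score statistic U = r' M r (non-negative for PSD M)."""
    r = np.asarray(residuals, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.shape != (r.size, r.size):
        raise ValidationError(
            f"matrix shape {M.shape} does not match residual length {r.size}"
        )
    return float(r @ M @ r)


def _pseudo_p(U_perm: np.ndarray) -> np.ndarray:
    """Rank-based pseudo p-values of each permuted statistic within the
    ensemble: p(b) = #{b' : U(b') >= U(b)} / B, conservative under ties."""
    B = U_perm.size
    order = np.argsort(U_perm, kind="stable")
    # count of values >= U(b); handle ties by ranking against sorted values
    sorted_vals = U_perm[order]
    # index of first occurrence of each value in sorted order
    first_ge = np.searchsorted(sorted_vals, U_perm, side="left")
    return (B - first_ge) / B


def permutation_engine(residuals: np.ndarray, bank: KernelBank, B: int,
                       seed: int | np.random.Generator | None = None) -> TestResult:
    """Run all candidate tests and the three adaptive tests off one shared
    permutation ensemble of the residual vector."""
    if B < 1:
        raise ParameterError("number of permutations B must be >= 1")
    if len(bank) == 0:
        raise ParameterError("kernel bank is empty")
    r = np.asarray(residuals, dtype=float)
    n = r.size
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    labels = bank.labels
    mats = [np.asarray(bank.matrices[lab], dtype=float) for lab in labels]
    for lab, M in zip(labels, mats):
        if M.shape != (n, n):
            raise ValidationError(f"candidate {lab!r} has shape {M.shape}")

    # one shared permutation set (Fisher-Yates shuffles of r)
    P = np.tile(r, (B, 1))
    rng.permuted(P, axis=1, out=P)

    U_obs = np.array([float(r @ M @ r) for M in mats])
    U_perm = np.empty((len(labels), B))
    for c, M in enumerate(mats):
        PM = P @ M
        U_perm[c] = np.einsum("bi,bi->b", PM, P)

    p_obs = (1.0 + (U_perm >= U_obs[:, None]).sum(axis=1)) / (B + 1.0)
    pseudo = np.vstack([_pseudo_p(U_perm[c]) for c in range(len(labels))])

    res = TestResult(n_permutations=B,
                     seed=seed if isinstance(seed, int) else None)
    for c, lab in enumerate(labels):
        res.statistics[lab] = U_obs[c]
        res.p_values[lab] = float(p_obs[c])

    groups = {}
    if bank.misaln_labels:
        groups["OMiSALN"] = bank.misaln_labels
    if bank.mirkats_labels:
        groups["OMiRKAT-S"] = bank.mirkats_labels
    groups["OMiSA"] = labels
    idx_of = {lab: c for c, lab in enumerate(labels)}
    for name, members in groups.items():
        sel = [idx_of[lab] for lab in members]
        Q_obs = float(p_obs[sel].min())
        min_pseudo = pseudo[sel].min(axis=0)
        res.min_p[name] = Q_obs
        res.adaptive_p[name] = float(
            (1.0 + np.sum(min_pseudo <= Q_obs)) / (B + 1.0)
        )
    return res


def omisa_test(surv: SurvivalData, Z: CommunityMatrix,
               tree: skbio.TreeNode | TreeIndex | None = None,
               gammas=GAMMA_DEFAULT, kernels=PSI_DEFAULT,
               B: int = 5000,
               seed: int | np.random.Generator | None = None,
               null_fit: NullFit | None = None,
               ties: str = "efron") -> TestResult:
    """Full adaptive association test for one microbial group.

    Fits the covariate-only Cox null model, builds the candidate matrices
    from the community matrix (and tree when UniFrac kernels are requested),
    and estimates all candidate and adaptive p-values from one shared
    residual-permutation ensemble.
    """
    if surv.n != Z.n_samples:
        raise ValidationError("survival data and community matrix sizes differ")
    if (surv.sample_ids is not None
            and list(surv.sample_ids) != list(Z.sample_ids)):
        raise ValidationError(
            "sample order mismatch between survival data and community matrix; "
            "align inputs first"
        )
    fit = null_fit if null_fit is not None else fit_null_model(surv, ties=ties)
    bank = build_kernel_bank(Z, tree=tree, gammas=gammas, kernels=kernels)
    return permutation_engine(fit.residuals, bank, B=B, seed=seed)
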