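"""Hierarchical application of the association tests across taxonomic ranks.

The scan tests the entire community once, then every taxon at each rank
(phylum..genus). A taxon's abundance sub-matrix keeps the community-total
normalisation (rows are not re-closed to one) and the tree is pruned to
the taxon's tips, so rare taxa are not artificially inflated. Taxa with a
single member OTU fall back to a univariate Cox Wald test. Raw p-values
are corrected within each rank (Benjamini-Hochberg by default; the
procedure is pluggable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import skbio
from statsmodels.stats.multitest import multipletests

from .assoc_tests import TestResult, omisa_test
from .community_metrics import GAMMA_DEFAULT, PSI_DEFAULT
from .exceptions import DegenerateDataError, ParameterError, ValidationError
from .io_formats import (TAXONOMIC_RANKS, CommunityMatrix, CountTable,
                         SurvivalData, TaxonomyTable, to_composition)

logger = logging.getLogger(__name__)


@dataclass
class TaxonResult:
    rank: str
    taxon: str
    n_otus: int
    test: str                 # "OMiSA" or "univariate-Cox"
    p_value: float
    p_adjusted: float | None = None
    detail: TestResult | None = None


def filter_otus(counts: CountTable, threshold: float = 1e-4) -> CountTable:
    """Keep OTUs whose mean relative abundance across samples exceeds the
    threshold (the proportional-mean filter)."""
    if not 0 <= threshold < 1:
        raise ParameterError("threshold must lie in [0, 1)")
    totals = counts.counts.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise DegenerateDataError("samples with zero total count")
    mean_prop = (counts.counts / totals).mean(axis=0)
    keep = mean_prop > threshold
    if not keep.any():
        raise DegenerateDataError(
            f"no OTU passes the mean-proportion filter at {threshold:g}"
        )
    logger.info("proportion-mean filter at %g: kept %d of %d OTUs",
                threshold, int(keep.sum()), counts.n_otus)
    return CountTable(counts.counts[:, keep], counts.sample_ids,
                      [o for o, k in zip(counts.otu_ids, keep) if k])


def taxon_subsets(taxonomy: TaxonomyTable, rank: str,
                  otu_ids: list[str] | None = None) -> list[tuple[str, list[str]]]:
    """Group OTUs by their label at ``rank``, dropping unassigned OTUs."""
    if rank not in TAXONOMIC_RANKS:
        raise ParameterError(f"unknown rank {rank!r}; use one of {TAXONOMIC_RANKS}")
    universe = taxonomy.otu_ids if otu_ids is None else list(otu_ids)
    groups: dict[str, list[str]] = {}
    for otu in universe:
        if otu not in taxonomy.lineages:
            raise ValidationError(f"OTU {otu!r} missing from taxonomy table")
        label = taxonomy.label(otu, rank)
        if label is None:
            continue
        groups.setdefault(label, []).append(otu)
    if not groups:
        warnings.warn(f"no OTU carries a {rank}-level assignment")
    for label, members in groups.items():
        logger.debug("%s %s: %d member OTUs", rank, label, len(members))
    return sorted(groups.items())


def taxon_composition(Z_community: CommunityMatrix,
                      members: list[str]) -> CommunityMatrix:
    """Column subset of the community matrix for one taxon.

    Rows are deliberately NOT renormalised: abundances stay on the
    community-total scale, so the taxon's share of the whole community is
    preserved in the test.
    """
    if not members:
        raise ValidationError("empty taxon member set")
    pos = {o: j for j, o in enumerate(Z_community.otu_ids)}
    missing = [m for m in members if m not in pos]
    if missing:
        raise ValidationError(f"members not in community matrix: {missing}")
    cols = [pos[m] for m in members]
    sub = Z_community.values[:, cols]
    community_level = len(members) == Z_community.n_otus
    return CommunityMatrix(sub, Z_community.sample_ids, list(members),
                           community_level=community_level)


def univariate_cox_test(surv: SurvivalData, abundance: np.ndarray,
                        covariates: np.ndarray | None = None) -> float:
    """Wald p-value for a single OTU's abundance in a Cox model."""
    from lifelines import CoxPHFitter

    z = np.asarray(abundance, dtype=float)
    if np.std(z) == 0:
        raise DegenerateDataError("abundance has zero variance across samples")
    if surv.n_events < 2:
        raise DegenerateDataError("at least 2 events are required")
    df = pd.DataFrame({"time": surv.time, "event": surv.event, "z": z})
    if covariates is None:
        covariates = surv.covariates
    if covariates is not None:
        for k in range(covariates.shape[1]):
            df[f"x{k}"] = covariates[:, k]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(cph.summary.loc["z", "p"])


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(p_values, method="fdr_bh")[1]


def scan_taxa(surv: SurvivalData, counts: CountTable,
              tree: skbio.TreeNode | None, taxonomy: TaxonomyTable,
              ranks=TAXONOMIC_RANKS, gammas=GAMMA_DEFAULT, kernels=PSI_DEFAULT,
              B: int = 5000, seed: int | None = None,
              filter_threshold: float | None = 1e-4,
              adjust=bh_adjust) -> tuple[TaxonResult, list[TaxonResult]]:
    """Community-level test plus per-rank taxon scan with within-rank
    multiple-testing correction.

    Returns ``(community_result, taxon_results)``; the community-level
    p-value is reported raw (it is a single test), taxon results carry
    BH-adjusted p-values computed within each rank.
    """
    if filter_threshold is not None:
        counts = filter_otus(counts, filter_threshold)
    Z = to_composition(counts)
    ss = np.random.SeedSequence(seed)

    def next_seed():
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))

    community = omisa_test(surv, Z, tree=tree, gammas=gammas, kernels=kernels,
                           B=B, seed=next_seed())
    community_result = TaxonResult(
        rank="community", taxon="entire community", n_otus=Z.n_otus,
        test="OMiSA", p_value=community.adaptive_p["OMiSA"],
        p_adjusted=None, detail=community,
    )

    results: list[TaxonResult] = []
    for rank in ranks:
        rank_results: list[TaxonResult] = []
        for label, members in taxon_subsets(taxonomy, rank, Z.otu_ids):
            if len(members) >= 2:
                sub = taxon_composition(Z, members)
                subtree = tree.shear(members) if tree is not None else None
                res = omisa_test(surv, sub, tree=subtree, gammas=gammas,
                                 kernels=kernels, B=B, seed=next_seed())
                rank_results.append(TaxonResult(
                    rank=rank, taxon=label, n_otus=len(members),
                    test="OMiSA", p_value=res.adaptive_p["OMiSA"], detail=res,
                ))
            else:
                sub = taxon_composition(Z, members)
                try:
                    p = univariate_cox_test(surv, sub.values[:, 0])
                except DegenerateDataError:
                    warnings.warn(f"skipping degenerate singleton taxon {label!r}")
                    continue
                rank_results.append(TaxonResult(
                    rank=rank, taxon=label, n_otus=1,
                    test="univariate-Cox", p_value=p,
                ))
        if rank_results:
            adj = adjust(np.array([t.p_value for t in rank_results]))
            rank_results = [replace(t, p_adjusted=float(a))
                            for t, a in zip(rank_results, adj)]
        results.extend(rank_results)
    return community_result, results


def results_to_frame(community: TaxonResult,
                     taxa: list[TaxonResult]) -> pd.DataFrame:
    rows = [{"rank": t.rank, "taxon": t.taxon, "n_otus": t.n_otus,
             "test": t.test, "p": t.p_value, "p_adj": t.p_adjusted}
            for t in [community, *taxa]]
    return pd.DataFrame(rows)
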