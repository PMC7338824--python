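"""Conserved-protein candidate funnel.

Genes are prioritized on two summary statistics: the between-site coefficient
of variation (CV) of transcript expression (low CV = expression conserved
between primary tumor and metastases) and the transcript-protein Spearman
correlation across patients (high rho = protein abundance tracks the
transcript).  Each statistic's distribution is Box-Cox normalized (MLE
lambda after a positivity shift) and genes in the selected-side tail of the
fitted normal at p < 0.1 are kept; the final candidates are the intersection
of the two arms, optionally narrowed by a user-supplied gene set standing in
for a pathway-membership filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsMatrix
from .errors import DegenerateDataError, MergeError, ParameterError

logger = logging.getLogger("radioprot")

MEAN_EPSILON = 1e-8  #: |mean| below this leaves the CV undefined


def between_site_cv(site_matrix: OmicsMatrix, eps: float = MEAN_EPSILON) -> pd.Series:
    """Per-gene coefficient of variation across site columns.

    cv = sample SD (ddof=1) / |mean| over the non-missing site values; genes
    with fewer than 2 values or |mean| < eps come back NaN (excluded
    downstream, with a logged count).
    """
    df = site_matrix.values
    if df.shape[1] < 2:
        raise ParameterError("between-site CV needs >= 2 site columns")
    mean = df.mean(axis=1, skipna=True)
    sd = df.std(axis=1, ddof=1, skipna=True)
    n = df.notna().sum(axis=1)
    cv = sd / mean.abs()
    cv[(n < 2) | (mean.abs() < eps)] = np.nan
    n_undef = int(cv.isna().sum())
    if n_undef:
        logger.info("between_site_cv: %d gene(s) undefined (near-zero mean or <2 values)",
                    n_undef)
    return cv.rename("cv")


def transcript_protein_rho(transcripts: OmicsMatrix, proteins: OmicsMatrix,
                           min_pairs: int = 3) -> pd.Series:
    """Per-gene Spearman correlation between transcript and protein profiles.

    Matrices are merged on shared gene ids and shared patient columns;
    correlations use pairwise-complete observations with average ranks for
    ties.  Genes with fewer than ``min_pairs`` complete pairs come back NaN.
    """
    genes = transcripts.gene_ids.intersection(proteins.gene_ids)
    if len(genes) == 0:
        raise MergeError("no shared gene ids between transcript and protein matrices")
    samples = transcripts.sample_ids.intersection(proteins.sample_ids)
    if len(samples) == 0:
        raise MergeError("no shared patient columns between transcript and protein matrices")
    T = transcripts.values.loc[genes, samples].to_numpy(dtype=float)
    P = proteins.values.loc[genes, samples].to_numpy(dtype=float)
    out = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        ok = np.isfinite(T[i]) & np.isfinite(P[i])
        if ok.sum() < min_pairs:
            continue
        res = stats.spearmanr(T[i, ok], P[i, ok])
        out[i] = res.statistic
    return pd.Series(out, index=genes, name="rho")


@dataclass
class TailSelection:
    """Result of one Box-Cox tail-selection arm."""

    transformed: pd.Series
    lam: float
    shift: float
    p_values: pd.Series
    selected: set
    side: str
    p_threshold: float


def boxcox_tail_select(values: pd.Series, side: str, p_threshold: float,
                       shift_epsilon: float = 1e-6) -> TailSelection:
    """Box-Cox normalize ``values`` and select the genes in the chosen tail.

    A shift of max(0, eps - min) makes the inputs positive; lambda is chosen
    by maximum likelihood; each gene's p is the one-sided tail probability of
    its transformed value under the normal with the transformed sample's mean
    and SD (lower tail for the conserved/CV arm, upper for the correlated/rho
    arm).  Selected = {gene : p < p_threshold}.
    """
    if side not in ("lower", "upper"):
        raise ParameterError(f"side must be 'lower' or 'upper', got {side!r}")
    if not (0 < p_threshold <= 1):
        raise ParameterError(f"p_threshold must lie in (0, 1], got {p_threshold}")
    defined = values.dropna()
    if len(defined) < 10:
        raise ParameterError(f"need >= 10 defined values, got {len(defined)}")
    x = defined.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant input: Box-Cox fit is degenerate")
    shift = max(0.0, shift_epsilon - float(x.min()))
    y, lam = stats.boxcox(x + shift)
    mu, sd = y.mean(), y.std(ddof=1)
    z = (y - mu) / sd
    p = stats.norm.cdf(z) if side == "lower" else stats.norm.sf(z)
    p_ser = pd.Series(np.nan, index=values.index, name="p")
    p_ser.loc[defined.index] = p
    t_ser = pd.Series(np.nan, index=values.index, name="transformed")
    t_ser.loc[defined.index] = y
    selected = set(defined.index[p < p_threshold])
    return TailSelection(transformed=t_ser, lam=float(lam), shift=shift,
                         p_values=p_ser, selected=selected, side=side,
                         p_threshold=p_threshold)


def intersect_and_filter(conserved: set, correlated: set,
                         gene_set_filter: set | None = None
                         ) -> tuple[set, pd.DataFrame]:
    """Intersect the two funnel arms, optionally narrowed by a gene set.

    Returns (final candidates, provenance frame recording which filters each
    surviving gene passed).  An empty result is valid and logged.
    """
    final = set(conserved) & set(correlated)
    if gene_set_filter is not None:
        final &= set(gene_set_filter)
    rows = [{"gene": g, "in_conserved": True, "in_correlated": True,
             "in_gene_set": (gene_set_filter is None) or (g in gene_set_filter)}
            for g in sorted(final)]
    prov = pd.DataFrame(rows, columns=["gene", "in_conserved", "in_correlated",
                                       "in_gene_set"]).set_index("gene") if rows else \
        pd.DataFrame(columns=["in_conserved", "in_correlated", "in_gene_set"])
    if not final:
        logger.warning("candidate intersection is empty")
    return final, prov


@dataclass
class CandidateSelection:
    """Full record of the prioritization funnel for one dataset."""

    table: pd.DataFrame           # per gene: cv, rho, transformed values, p values
    lambda_cv: float
    lambda_rho: float
    shift_cv: float
    shift_rho: float
    selected_conserved: set
    selected_correlated: set
    intersection: set
    p_threshold: float


def prioritize(site_transcripts: OmicsMatrix, patient_transcripts: OmicsMatrix,
               proteins: OmicsMatrix, p_threshold: float = 0.1,
               gene_set_filter: set | None = None, cv_side: str = "lower",
               rho_side: str = "upper", shift_epsilon: float = 1e-6) -> CandidateSelection:
    """Run the whole funnel: CV arm, rho arm, tail selection, intersection."""
    cv = between_site_cv(site_transcripts)
    rho = transcript_protein_rho(patient_transcripts, proteins)
    cv_sel = boxcox_tail_select(cv, cv_side, p_threshold, shift_epsilon)
    rho_sel = boxcox_tail_select(rho.reindex(cv.index), rho_side, p_threshold, shift_epsilon)
    final, prov = intersect_and_filter(cv_sel.selected, rho_sel.selected, gene_set_filter)
    table = pd.DataFrame({
        "cv": cv, "rho": rho.reindex(cv.index),
        "cv_transformed": cv_sel.transformed, "rho_transformed": rho_sel.transformed,
        "p_cv": cv_sel.p_values, "p_rho": rho_sel.p_values,
        "selected_conserved": cv.index.isin(list(cv_sel.selected)),
        "selected_correlated": cv.index.isin(list(rho_sel.selected)),
        "in_intersection": cv.index.isin(list(final)),
    })
    return CandidateSelection(
        table=table, lambda_cv=cv_sel.lam, lambda_rho=rho_sel.lam,
        shift_cv=cv_sel.shift, shift_rho=rho_sel.shift,
        selected_conserved=cv_sel.selected, selected_correlated=rho_sel.selected,
        intersection=final, p_threshold=p_threshold,
    )
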