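"""Reader consolidation, agreement statistics, and the association layer.

Binary imaging traits are tested against protein abundance with the
Mann-Whitney U test; the effect is reported as the AUC = U / (n1 * n2), with
AUC > 0.5 meaning higher abundance when the trait is present.  Ordinal/count
traits and the quantitative texture heterogeneity metrics use the Kendall
tau-b rank correlation.  Small untied samples get exact p-values (full null
enumeration via scipy); otherwise the normal approximation with tie and
continuity corrections is used.  Benjamini-Hochberg adjustment is applied
within a declared family (default: all proteins within one feature).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.multitest import multipletests

from .datatypes import CATEGORICAL_KINDS, OmicsMatrix, TraitTable
from .errors import MergeError, ParameterError, UnresolvedConflictError

logger = logging.getLogger("radioprot")


# ---------------------------------------------------------------------------
# reader consolidation & agreement

def consolidate_readers(trait_table: TraitTable, arbitration: pd.DataFrame) -> TraitTable:
    """Fill the consolidated column from the two readers.

    Categorical traits (binary/ordinal/count): the shared value when the
    readers agree, otherwise the arbitrator's value from ``arbitration``
    (patients x traits).  Quantitative traits: the mean of the two readers.
    Missing arbitration for a disagreement raises, listing (patient, trait).
    """
    data = trait_table.data.copy()
    unresolved = []
    for trait in trait_table.traits:
        kind = trait_table.schema[trait].kind
        r1 = data[(trait, "reader1")]
        r2 = data[(trait, "reader2")]
        if kind == "quantitative":
            cons = (r1 + r2) / 2.0
        else:
            cons = r1.copy()
            disagree = r1 != r2
            for patient in data.index[disagree]:
                if trait in arbitration.columns and pd.notna(arbitration.loc[patient, trait]):
                    cons.loc[patient] = arbitration.loc[patient, trait]
                else:
                    unresolved.append((patient, trait))
        data[(trait, "consolidated")] = cons
    if unresolved:
        raise UnresolvedConflictError(f"no arbitration value for: {unresolved}")
    return TraitTable(data, trait_table.schema)


def agreement(trait_table: TraitTable) -> pd.DataFrame:
    """Percent agreement and Cohen's kappa between the two readers, per trait.

    kappa (and, for quantitative traits, the percent agreement too) is NaN
    when it cannot be computed — in particular whenever either reader scored
    every case the same value.
    """
    rows = []
    for trait in trait_table.traits:
        kind = trait_table.schema[trait].kind
        r1 = trait_table.data[(trait, "reader1")]
        r2 = trait_table.data[(trait, "reader2")]
        ok = r1.notna() & r2.notna()
        n = int(ok.sum())
        if n == 0:
            raise ParameterError(f"trait {trait!r} has no complete reader pairs")
        if kind == "quantitative":
            rows.append({"trait": trait, "n": n, "percent_agreement": np.nan, "kappa": np.nan})
            continue
        a, b = r1[ok].to_numpy(), r2[ok].to_numpy()
        pct = 100.0 * float((a == b).mean())
        if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
            kappa = np.nan  # a constant reader leaves chance agreement undefined
        else:
            kappa = float(cohen_kappa_score(a, b))
        rows.append({"trait": trait, "n": n, "percent_agreement": pct, "kappa": kappa})
    return pd.DataFrame(rows).set_index("trait")


# ---------------------------------------------------------------------------
# the two rank tests

@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    auc: float
    p: float
    method: str
    n1: int
    n2: int


def mann_whitney_auc(values_present, values_absent, exact_max_n: int = 25) -> MannWhitneyResult:
    """Mann-Whitney U of trait-present vs trait-absent protein values.

    U counts pairs where the trait-present value exceeds the trait-absent
    value (ties 0.5); AUC = U / (n1 n2), so AUC > 0.5 means higher abundance
    with the trait present.  The two-sided p is exact (full null enumeration)
    when n1 + n2 <= exact_max_n and the pooled sample is untied, otherwise a
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(values_present, dtype=float)
    y = np.asarray(values_absent, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size) <= exact_max_n and not ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    U = float(res.statistic)
    return MannWhitneyResult(U=U, auc=U / (x.size * y.size), p=float(res.pvalue),
                             method="exact" if exact else "asymptotic",
                             n1=int(x.size), n2=int(y.size))


@dataclass(frozen=True)
class KendallResult:
    S: int
    tau: float
    p: float
    method: str
    n: int


def kendall_s(x: np.ndarray, y: np.ndarray) -> int:
    """Kendall numerator S = #concordant - #discordant pairs (ties count 0)."""
    n = len(x)
    s = 0
    for i in range(n - 1):
        s += int(np.sum(np.sign(x[i + 1:] - x[i]) * np.sign(y[i + 1:] - y[i])))
    return s


def kendall_tau(x, y, exact_max_n: int = 25) -> KendallResult:
    """Kendall tau-b with exact small-sample inference.

    For untied samples of n <= exact_max_n the two-sided p comes from the
    exact null distribution of S (inversion-count recurrence, via scipy);
    otherwise the normal approximation with var(S) = n(n-1)(2n+5)/18 plus tie
    adjustment.  Constant x or y leaves tau undefined (NaN result).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must be paired")
    n = x.size
    if n < 3:
        raise ParameterError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return KendallResult(S=0, tau=float("nan"), p=float("nan"),
                             method="undefined", n=n)
    ties = (np.unique(x).size < n) or (np.unique(y).size < n)
    exact = n <= exact_max_n and not ties
    res = stats.kendalltau(x, y, method="exact" if exact else "asymptotic")
    return KendallResult(S=kendall_s(x, y), tau=float(res.statistic),
                         p=float(res.pvalue),
                         method="exact" if exact else "asymptotic", n=n)


# ---------------------------------------------------------------------------
# multiple testing

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ParameterError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the association grid

@dataclass(frozen=True)
class AssociationResult:
    """One protein x feature test."""

    protein: str
    feature: str
    feature_kind: str       # binary | ordinal | count | quantitative | texture
    statistic: float        # U for binary features, Kendall S otherwise
    effect: float           # AUC in [0,1] or tau in [-1,1]
    effect_name: str        # "AUC" | "tau"
    p_raw: float
    p_adjusted: float
    method: str
    n1: int | None
    n2: int | None
    n: int


def run_associations(proteins: OmicsMatrix, features: pd.DataFrame,
                     feature_kinds: dict[str, str], alpha: float = 0.05,
                     exact_max_n: int = 25, bh_family: str = "per_feature"
                     ) -> list[AssociationResult]:
    """Univariate protein-feature association tests with BH adjustment.

    ``features`` is a patients x features frame (consolidated traits plus
    texture metrics); ``feature_kinds`` declares each column binary /
    ordinal / count / quantitative / texture.  Binary features use
    Mann-Whitney + AUC; everything else Kendall tau.  BH families: all
    proteins within one feature (default) or the whole grid (``"global"``).
    Tests whose inputs are degenerate (an empty trait group, a constant
    vector) are skipped with a log message.
    """
    if bh_family not in ("per_feature", "global"):
        raise ParameterError(f"unknown bh_family {bh_family!r}")
    missing = [c for c in feature_kinds if c not in features.columns]
    if missing:
        raise ParameterError(f"features absent from the table: {missing}")
    shared = proteins.sample_ids.intersection(features.index)
    if len(shared) == 0:
        raise MergeError(
            f"no shared patients (proteins: {list(proteins.sample_ids[:3])}..., "
            f"features: {list(features.index[:3])}...)")
    if len(shared) < len(features.index) or len(shared) < len(proteins.sample_ids):
        logger.warning("patient alignment keeps %d of %d/%d ids", len(shared),
                       len(proteins.sample_ids), len(features.index))
    prot = proteins.values[shared]
    feat = features.loc[shared]

    partial: list[dict] = []
    for feature, kind in feature_kinds.items():
        fvals = feat[feature].to_numpy(dtype=float)
        for gene in prot.index:
            pvals = prot.loc[gene].to_numpy(dtype=float)
            ok = np.isfinite(pvals) & np.isfinite(fvals)
            if kind == "binary":
                x = pvals[ok & (fvals > 0)]
                y = pvals[ok & (fvals <= 0)]
                if x.size == 0 or y.size == 0:
                    logger.info("skipping %s/%s: empty trait group", feature, gene)
                    continue
                r = mann_whitney_auc(x, y, exact_max_n)
                partial.append(dict(protein=gene, feature=feature, feature_kind=kind,
                                    statistic=r.U, effect=r.auc, effect_name="AUC",
                                    p_raw=r.p, method=r.method, n1=r.n1, n2=r.n2,
                                    n=r.n1 + r.n2))
            else:
                if ok.sum() < 3:
                    continue
                r = kendall_tau(fvals[ok], pvals[ok], exact_max_n)
                if r.method == "undefined" or not np.isfinite(r.p):
                    logger.info("skipping %s/%s: constant input", feature, gene)
                    continue
                partial.append(dict(protein=gene, feature=feature, feature_kind=kind,
                                    statistic=r.S, effect=r.tau, effect_name="tau",
                                    p_raw=r.p, method=r.method, n1=None, n2=None, n=r.n))

    if not partial:
        return []
    df = pd.DataFrame(partial)
    df["p_adjusted"] = np.nan
    if bh_family == "global":
        df["p_adjusted"] = bh_adjust(df["p_raw"].to_numpy())
    else:
        for feature in df["feature"].unique():
            sel = df["feature"] == feature
            df.loc[sel, "p_adjusted"] = bh_adjust(df.loc[sel, "p_raw"].to_numpy())
    return [AssociationResult(**row) for row in df.to_dict("records")]
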