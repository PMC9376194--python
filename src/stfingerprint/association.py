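"""Brain-behaviour association: Spearman correlation with FDR control.

Each subject's fingerprint is reduced to one scalar per region (the
temporal mean of the signed attribution); within each group, every
region's score is correlated (Spearman) against every symptom-domain
score, and the resulting p-values are Benjamini-Hochberg corrected across
all regions x domains tested within that group. The per-subject region
score entering the primary correlation is the average across the k fold
models; per-fold-model consistency (fraction of fold models whose own
corrected q falls below alpha) is reported alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import Cohort, CohortValidationError

MIN_PAIRS = 4


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties receive mid-ranks; rho is the Pearson correlation of the ranks.
    Either input constant -> (nan, nan): rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < MIN_PAIRS:
        raise CohortValidationError(
            f"need equal-length vectors with >= {MIN_PAIRS} pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved.

    NaN p-values (undefined correlations) pass through as NaN and do not
    count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise CohortValidationError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _pairwise(scores: np.ndarray, symptoms: np.ndarray):
    keep = ~np.isnan(symptoms)
    return scores[keep], symptoms[keep]


def associate(cohort: Cohort, region_scores: dict[int, np.ndarray],
              domains: list[str], group: int,
              alpha: float = 0.01) -> pd.DataFrame:
    """Region x domain Spearman association table within one group.

    Parameters
    ----------
    region_scores : {fold index: (n_subjects, n_regions) array}
        Per-subject region scores under each fold model, rows in cohort
        order (all subjects; only the group's rows are used).
    domains : symptom-domain names to test (must exist on the subjects).
    group : class label defining the subject subset.
    alpha : per-test q threshold used for the fold-consistency column.

    Returns a DataFrame with columns group, domain, region, rho, p_raw,
    q_fdr, n, fold_consistency; q values are BH-corrected across all
    regions x domains within the group.
    """
    members = np.flatnonzero(cohort.labels == group)
    if members.size == 0:
        raise CohortValidationError(f"no subjects in group {group}")
    folds = sorted(region_scores)
    stacked = np.stack([region_scores[f] for f in folds])   # (k, n, R)
    mean_scores = stacked.mean(axis=0)

    rows = []
    fold_p: dict[int, list[float]] = {f: [] for f in folds}
    for domain in domains:
        symptoms = np.array([
            cohort.subjects[i].symptom_scores.get(domain, np.nan)
            for i in members])
        for r in range(cohort.n_regions):
            xs, ys = _pairwise(mean_scores[members, r], symptoms)
            if xs.size < MIN_PAIRS:
                raise CohortValidationError(
                    f"fewer than {MIN_PAIRS} scored subjects in group "
                    f"{group} for domain {domain!r}")
            rho, p = spearman(xs, ys)
            rows.append({"group": group, "domain": domain,
                         "region": cohort.region_names[r],
                         "rho": rho, "p_raw": p, "n": int(xs.size)})
            for f in folds:
                xf, yf = _pairwise(stacked[f][members, r], symptoms)
                fold_p[f].append(spearman(xf, yf)[1])

    table = pd.DataFrame(rows)
    table["q_fdr"] = bh_fdr(table["p_raw"].to_numpy())
    fold_sig = np.stack([
        bh_fdr(np.asarray(fold_p[f])) < alpha for f in folds])
    table["fold_consistency"] = fold_sig.mean(axis=0)
    return table[["group", "domain", "region", "rho", "p_raw",
                  "q_fdr", "n", "fold_consistency"]]
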