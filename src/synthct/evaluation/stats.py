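"""Statistical tests for the evaluation: one-way ANOVA, Tukey HSD,
proportional-odds ordinal regression.

ANOVA compares the SSIM distributions of the three model sets; Tukey's
post-hoc test attributes the difference to specific pairs; ordinal
regression tests whether the 1-4 reader scores rank with the set an
image came from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ..errors import DataError, DegenerateStatisticError, ParameterError


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(gs) < 2:
        raise ParameterError("need at least 2 groups")
    for g in gs:
        if len(g) < 2:
            raise ParameterError("every group needs at least 2 values")
        if not np.all(np.isfinite(g)):
            raise DataError("groups contain non-finite values")
    if all(np.ptp(g) == 0 for g in gs):
        raise DegenerateStatisticError(
            "zero within-group variance in every group; F is undefined"
        )
    return gs


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA; returns (F, p)."""
    gs = _check_groups(groups)
    res = sps.f_oneway(*gs)
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(groups) -> np.ndarray:
    """Tukey's honestly-significant-difference post-hoc test.

    Returns the symmetric matrix of family-wise adjusted pairwise
    p-values (diagonal 1).
    """
    gs = _check_groups(groups)
    res = sps.tukey_hsd(*gs)
    p = np.asarray(res.pvalue, dtype=float)
    np.fill_diagonal(p, 1.0)
    return p


@dataclass
class OrdinalFit:
    """Proportional-odds fit: per-set effects relative to a reference."""

    reference: str
    coefficients: dict[str, float]
    p_values: dict[str, float]
    thresholds: np.ndarray
    converged: bool


def ordinal_fit(scores, set_labels) -> OrdinalFit:
    """Fit a cumulative-logit (proportional odds) model of score ~ set.

    ``scores`` are ordinal (e.g. 1..4), ``set_labels`` categorical.  The
    first set in sorted order is the reference; positive coefficients
    mean higher scores than the reference.  Complete separation is
    flagged with an explicit diagnostic instead of returning garbage.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y = np.asarray(scores)
    labs = np.asarray(set_labels)
    if y.shape != labs.shape:
        raise DataError("scores and set_labels must align")
    uniq_sets = sorted(set(labs.tolist()))
    if len(uniq_sets) < 2:
        raise ParameterError("need at least 2 distinct sets")
    if len(set(y.tolist())) < 2:
        raise ParameterError("need at least 2 distinct score values")

    exog = pd.get_dummies(pd.Series(labs), drop_first=True, dtype=float)
    endog = pd.Categorical(y, ordered=True)
    model = OrderedModel(endog, exog, distr="logit")
    with np.errstate(all="ignore"):
        res = model.fit(method="bfgs", disp=False, maxiter=200)
    k = exog.shape[1]
    coefs = {c: float(res.params.iloc[i]) for i, c in enumerate(exog.columns)}
    pvals = {c: float(res.pvalues.iloc[i]) for i, c in enumerate(exog.columns)}
    converged = bool(res.mle_retvals.get("converged", True))
    if not converged or any(abs(v) > 30 for v in coefs.values()):
        raise DegenerateStatisticError(
            "ordinal fit did not converge or produced extreme effects - "
            "likely complete separation between sets and scores; "
            f"coefficients: {coefs}"
        )
    return OrdinalFit(
        reference=str(uniq_sets[0]),
        coefficients=coefs,
        p_values=pvals,
        thresholds=np.asarray(res.params.iloc[k:], dtype=float),
        converged=converged,
    )
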