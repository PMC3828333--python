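"""Minimal logistic marker models for predicting patient subgroups.

Reduces the full analyte panel to a small logistic model (one-vs-rest,
in-the-subgroup vs not) by greedy forward selection: terms are added only
while every non-intercept coefficient stays Wald-significant.  When no
single analyte yields an all-significant model, pairwise concentration
products (pM^2) join the candidate set — a product may coexist with its
factors.  Concentrations enter in raw pM; columns are rescaled internally
for numerical stability and coefficients are reported on the raw scale, so
slopes can be of order 1e12 and larger.  Model discrimination is summarised
by the ROC AUC with a label-permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .panel_io import MolarMatrix
from .subgrouping import SubgroupAssignment

logger = logging.getLogger(__name__)

PRODUCT_SEP = "*"


@dataclass
class ModelTerm:
    term_id: str  # analyte id or "A*B" product
    coefficient: float
    std_error: float
    wald_p: float


@dataclass
class MarkerModel:
    target_label: str
    terms: list[ModelTerm]
    intercept: float
    intercept_se: float
    intercept_p: float
    auc: float
    converged: bool
    log_likelihood: float = np.nan

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    def all_terms_significant(self, alpha: float = 0.05) -> bool:
        return bool(self.terms) and all(t.wald_p < alpha for t in self.terms)


def term_column(matrix: MolarMatrix, term_id: str) -> np.ndarray:
    """Concentration column for a term: pM, or pM^2 for a product."""
    factors = term_id.split(PRODUCT_SEP)
    col = np.ones(len(matrix.patient_ids))
    for f in factors:
        if f not in matrix.values.columns:
            raise KeyError(f"term factor {f!r} not in panel")
        col = col * matrix.values[f].to_numpy(float)
    return col


def build_design(matrix: MolarMatrix, term_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {t: term_column(matrix, t) for t in term_ids},
        index=matrix.values.index,
    )


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC; ties count one half."""
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def fit_logistic(design: pd.DataFrame, outcome, target_label: str = "") -> MarkerModel:
    """Maximum-likelihood logistic fit with Wald inference.

    ``design`` holds concentration columns (pM, or pM^2 products); an
    intercept is added here.  Columns are divided by their maximum absolute
    value before fitting and coefficients mapped back to the raw scale.
    Non-convergence or quasi-separation is reported via ``converged=False``
    rather than raising.
    """
    y = np.asarray(outcome, int)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must contain both classes")
    X = design.to_numpy(float)
    n, p = X.shape
    scales = np.ones(p)
    if p:
        scales = np.abs(X).max(axis=0)
        if (scales == 0).any():
            raise ValueError("constant zero column in design")
        X = X / scales

    Xc = sm.add_constant(X, has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=100, method="newton")
        except Exception:
            try:  # newton fails hard on separation/singularity; lbfgs is robust
                res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, method="lbfgs")
                converged = False
            except Exception:
                res = None
                converged = False
    if res is None:
        return MarkerModel(target_label, [], np.nan, np.nan, np.nan, np.nan, False)

    params = np.asarray(res.params, float)
    bse = np.asarray(res.bse, float)
    pvals = np.asarray(res.pvalues, float)
    if not np.isfinite(params).all() or not np.isfinite(bse).all():
        converged = False
    # quasi-separation: the likelihood approaches its supremum of 0
    if res.llf / n > -1e-4:
        converged = False

    terms = [
        ModelTerm(
            term_id=c,
            coefficient=float(params[i + 1] / scales[i]),
            std_error=float(bse[i + 1] / scales[i]),
            wald_p=float(pvals[i + 1]),
        )
        for i, c in enumerate(design.columns)
    ]
    scores = Xc @ params
    auc = roc_auc(scores, y) if p else 0.5
    return MarkerModel(
        target_label=target_label,
        terms=terms,
        intercept=float(params[0]),
        intercept_se=float(bse[0]),
        intercept_p=float(pvals[0]),
        auc=auc,
        converged=converged,
        log_likelihood=float(res.llf),
    )


def _candidate_products(analytes: list[str]) -> list[str]:
    return [
        f"{a}{PRODUCT_SEP}{b}"
        for i, a in enumerate(analytes)
        for b in analytes[i + 1 :]
    ]


def _adequate(model: MarkerModel, alpha: float) -> bool:
    return model.converged and model.all_terms_significant(alpha)


def forward_select(
    matrix: MolarMatrix,
    assignment: SubgroupAssignment,
    target_label: str,
    allow_products: bool = True,
    alpha: float = 0.05,
    max_terms: int = 5,
) -> MarkerModel:
    """Greedy forward selection of a minimal all-significant marker model.

    The first term is the best single analyte by likelihood; it is accepted
    only if the one-term model converges with a Wald-significant slope.  If
    no single analyte is adequate and ``allow_products``, pairwise products
    enter the candidate pool and the search restarts over the enlarged set.
    Further candidates are added (never dropped) while the refit model keeps
    every non-intercept coefficient significant at ``alpha``.  If nothing is
    admissible, the intercept-only model is returned with a warning.
    """
    if target_label not in assignment.label_order:
        raise ValueError(f"unknown target label {target_label!r}")
    y = (assignment.labels.loc[matrix.patient_ids] == target_label).astype(int).to_numpy()
    analytes = matrix.analyte_ids

    def fit_terms(term_ids: list[str]) -> MarkerModel:
        return fit_logistic(build_design(matrix, term_ids), y, target_label)

    def best_first(cands: list[str]) -> tuple[str | None, MarkerModel | None]:
        fits = {c: fit_terms([c]) for c in cands}
        ok = {c: m for c, m in fits.items() if m.converged and np.isfinite(m.log_likelihood)}
        if not ok:
            return None, None
        best = max(ok, key=lambda c: ok[c].log_likelihood)
        if _adequate(ok[best], alpha):
            return best, ok[best]
        # fall back to the best-likelihood adequate single-term model, if any
        adequate = {c: m for c, m in ok.items() if _adequate(m, alpha)}
        if adequate:
            best = max(adequate, key=lambda c: adequate[c].log_likelihood)
            return best, adequate[best]
        return None, None

    candidates = list(analytes)
    first, model = best_first(candidates)
    if first is None and allow_products:
        candidates = list(analytes) + _candidate_products(analytes)
        first, model = best_first(candidates)
    if first is None:
        logger.warning(
            "no admissible marker model for %s; returning intercept-only", target_label
        )
        empty = fit_logistic(build_design(matrix, []), y, target_label)
        empty.converged = False
        return empty

    selected = [first]
    while len(selected) < max_terms:
        best_add: tuple[float, str, MarkerModel] | None = None
        for cand in candidates:
            if cand in selected:
                continue
            trial = fit_terms(selected + [cand])
            if not _adequate(trial, alpha):
                continue
            if best_add is None or trial.log_likelihood > best_add[0]:
                best_add = (trial.log_likelihood, cand, trial)
        if best_add is None:
            break
        selected.append(best_add[1])
        model = best_add[2]
    return model


@dataclass
class PermutationAUCResult:
    observed_auc: float
    null_aucs: np.ndarray
    p_empirical: float
    n_redrawn: int

    @property
    def null_mean(self) -> float:
        return float(self.null_aucs.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_aucs.std(ddof=1)) if self.null_aucs.size > 1 else 0.0

    @property
    def null_max(self) -> float:
        return float(self.null_aucs.max())


def permutation_auc_test(
    matrix: MolarMatrix,
    assignment: SubgroupAssignment,
    target_label: str,
    model_terms: list[str],
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationAUCResult:
    """Permutation null for the training AUC of a fixed-term logistic model.

    Subgroup labels are permuted uniformly; the model (same terms) is refit
    on each permuted outcome and its training AUC recorded.  The empirical
    p-value is (1 + #{null AUC >= observed}) / (n_perm + 1).  Permutations on
    which the refit fails outright are redrawn and counted.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = (assignment.labels.loc[matrix.patient_ids] == target_label).astype(int).to_numpy()
    design = build_design(matrix, model_terms)
    observed = fit_logistic(design, y, target_label).auc

    nulls = []
    redrawn = 0
    attempts_cap = 10 * n_perm
    attempts = 0
    while len(nulls) < n_perm and attempts < attempts_cap:
        attempts += 1
        perm = rng.permutation(y)
        m = fit_logistic(design, perm, target_label)
        if not np.isfinite(m.auc):
            redrawn += 1
            continue
        nulls.append(m.auc)
    if len(nulls) < n_perm:
        raise RuntimeError("too many failed permutation refits")
    if redrawn:
        logger.info("permutation test: %d permutations redrawn", redrawn)
    null_aucs = np.asarray(nulls)
    p = (1.0 + float((null_aucs >= observed).sum())) / (n_perm + 1.0)
    return PermutationAUCResult(observed, null_aucs, p, redrawn)
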