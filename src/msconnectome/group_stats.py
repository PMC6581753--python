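"""Per-node longitudinal group comparison with linear mixed-effects models.

For every (node, metric, variant) the model

    value_ij = b0 + b1 * clinical_group_i + b2 * session_ij + u_i + e_ij

is fitted, where ``u_i`` is a subject-level random intercept.  The clinical
group enters as a treatment-coded factor with a configurable reference level.
Fixed effects are tested with Wald statistics (large-sample z/chi-square);
when the omnibus group test is significant, pairwise contrasts of the
estimated marginal group means are extracted with a Tukey studentized-range
adjustment within the node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm, studentized_range

from .connectome import binarize, threshold_graph
from .graph_metrics import METRIC_ORDER, all_local_metrics
from .synthetic_data import SubjectRecord

__all__ = [
    "build_metric_table",
    "NodeMetricLMM",
    "NodeLMMResults",
    "fit_node_lmm",
    "posthoc_contrasts",
    "fit_all_nodes",
]


def build_metric_table(cohort: list[SubjectRecord], tau: float) -> pd.DataFrame:
    """Long-format table of all 4 metrics x 2 variants per node per scan.

    Columns: subject_id, group, session, node, metric, weighted, value.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    rows = []
    for rec in cohort:
        weighted_graph = threshold_graph(rec.matrix, tau)
        binary_graph = binarize(weighted_graph)
        for weighted, graph in ((True, weighted_graph), (False, binary_graph)):
            metrics = all_local_metrics(graph, weighted)
            for name in METRIC_ORDER:
                values = metrics[name].values
                for node, value in enumerate(values):
                    rows.append((rec.subject_id, rec.group, rec.session,
                                 node, name, weighted, float(value)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "session",
                                       "node", "metric", "weighted", "value"])


@dataclass
class NodeLMMResults:
    """Fitted mixed-model results for one (node, metric, variant) slice."""

    intercept: float
    group_effects: dict[str, float]       # treatment contrasts vs reference
    group_pvalues: dict[str, float]
    session_effect: float
    session_pvalue: float
    group_omnibus_pvalue: float
    random_intercept_var: float
    residual_var: float
    converged: bool
    reference: str
    groups: tuple[str, ...]
    n_obs: int
    n_fixed: int
    _cov: np.ndarray = field(repr=False, default=None)
    _coef_index: dict[str, int] = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            "Linear mixed model (subject random intercept)",
            f"  observations        : {self.n_obs}",
            f"  reference group     : {self.reference}",
            f"  intercept           : {self.intercept:.4f}",
        ]
        for grp, est in self.group_effects.items():
            lines.append(f"  group[{grp}]         : {est:+.4f}  (p={self.group_pvalues[grp]:.3g})")
        lines += [
            f"  session             : {self.session_effect:+.4f}  (p={self.session_pvalue:.3g})",
            f"  group omnibus p     : {self.group_omnibus_pvalue:.3g}",
            f"  subject variance    : {self.random_intercept_var:.4f}",
            f"  residual variance   : {self.residual_var:.4f}",
            f"  converged           : {self.converged}",
        ]
        return "\n".join(lines)


class NodeMetricLMM:
    """Mixed-effects model for one node's metric across subjects and sessions.

    Parameters
    ----------
    data : DataFrame
        Must carry columns ``subject_id``, ``group``, ``session`` and a value
        column (default ``value``).
    reference : str, optional
        Reference level for the treatment-coded group factor; defaults to the
        first group in sorted order.
    """

    def __init__(self, data: pd.DataFrame, reference: str | None = None,
                 value_col: str = "value"):
        required = {"subject_id", "group", "session", value_col}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns {sorted(missing)}")
        groups = sorted(data["group"].unique())
        if len(groups) < 2:
            raise ValueError("need at least 2 groups to compare")
        counts = data.groupby("group")["subject_id"].nunique()
        if (counts < 2).any():
            raise ValueError("every group needs at least 2 subjects")
        self.data = data
        self.value_col = value_col
        self.groups = tuple(groups)
        self.reference = reference if reference is not None else groups[0]
        if self.reference not in groups:
            raise ValueError(f"reference {self.reference!r} is not a group level")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "NodeMetricLMM":
        return cls(data, **kwargs)

    def fit(self) -> NodeLMMResults:
        formula = (f"{self.value_col} ~ "
                   f"C(group, Treatment(reference='{self.reference}')) + session")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, self.data, groups=self.data["subject_id"])
            try:
                fit = model.fit(reml=True)
                converged = bool(getattr(fit, "converged", True))
            except Exception:
                fit = model.fit(reml=True, method="powell", maxiter=2000)
                converged = False

        params = fit.params
        pvalues = fit.pvalues
        prefix = f"C(group, Treatment(reference='{self.reference}'))[T."
        group_effects, group_pvalues, coef_index = {}, {}, {}
        names = list(fit.model.exog_names)
        for grp in self.groups:
            if grp == self.reference:
                continue
            name = f"{prefix}{grp}]"
            group_effects[grp] = float(params[name])
            group_pvalues[grp] = float(pvalues[name])
            coef_index[grp] = names.index(name)

        # Wald chi-square omnibus test over all group coefficients; the
        # contrast spans the full parameter vector (incl. variance terms)
        if len(group_effects) == 1:
            omnibus_p = next(iter(group_pvalues.values()))
        else:
            contrast = np.zeros((len(group_effects), len(fit.params)))
            for row, grp in enumerate(group_effects):
                contrast[row, coef_index[grp]] = 1.0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                omnibus_p = float(fit.wald_test(contrast, scalar=True).pvalue)

        cov = np.asarray(fit.cov_params())[:len(names), :len(names)]
        return NodeLMMResults(
            intercept=float(params["Intercept"]),
            group_effects=group_effects,
            group_pvalues=group_pvalues,
            session_effect=float(params["session"]),
            session_pvalue=float(pvalues["session"]),
            group_omnibus_pvalue=float(omnibus_p),
            random_intercept_var=float(fit.cov_re.iloc[0, 0]),
            residual_var=float(fit.scale),
            converged=converged,
            reference=self.reference,
            groups=self.groups,
            n_obs=len(self.data),
            n_fixed=len(names),
            _cov=cov,
            _coef_index=coef_index,
        )


def fit_node_lmm(data: pd.DataFrame, reference: str | None = None,
                 value_col: str = "value") -> NodeLMMResults:
    """Fit the per-node mixed model on one long-table slice."""
    return NodeMetricLMM(data, reference=reference, value_col=value_col).fit()


def posthoc_contrasts(fit: NodeLMMResults, alpha: float = 0.05,
                      force: bool = False) -> pd.DataFrame:
    """All pairwise group contrasts with Tukey-adjusted p-values.

    Contrasts are computed only when the omnibus group test is significant at
    ``alpha`` (set ``force=True`` to compute regardless); otherwise an empty
    table is returned.  Estimates are differences of estimated marginal group
    means, positive when the first-named group is larger.
    """
    if len(fit.groups) < 2:
        raise ValueError("need at least two groups for contrasts")
    if fit.group_omnibus_pvalue >= alpha and not force:
        return pd.DataFrame(columns=["group_a", "group_b", "estimate", "se",
                                     "statistic", "p_adjusted"])
    n_coef = fit._cov.shape[0]
    effect_vec: dict[str, np.ndarray] = {}
    for grp in fit.groups:
        vec = np.zeros(n_coef)
        if grp != fit.reference:
            vec[fit._coef_index[grp]] = 1.0
        effect_vec[grp] = vec

    k = len(fit.groups)
    df = max(fit.n_obs - fit.n_fixed, 2)
    rows = []
    for ga, gb in combinations(fit.groups, 2):
        c = effect_vec[ga] - effect_vec[gb]
        est = float(_contrast_estimate(fit, ga) - _contrast_estimate(fit, gb))
        se = float(np.sqrt(c @ fit._cov @ c))
        stat = est / se if se > 0 else np.inf * np.sign(est)
        p_adj = float(studentized_range.sf(abs(stat) * np.sqrt(2.0), k, df)) \
            if np.isfinite(stat) else 0.0
        rows.append((ga, gb, est, se, stat, min(1.0, p_adj)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "estimate", "se",
                                       "statistic", "p_adjusted"])


def _contrast_estimate(fit: NodeLMMResults, group: str) -> float:
    return 0.0 if group == fit.reference else fit.group_effects[group]


def fit_all_nodes(table: pd.DataFrame, metric: str, weighted: bool,
                  reference: str | None = None,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Fit the mixed model for every node of one metric/variant.

    Returns one row per node with the omnibus p-value, session effect and the
    per-group estimates; non-convergent fits are flagged, not fatal.
    """
    sel = table[(table["metric"] == metric) & (table["weighted"] == weighted)]
    rows = []
    for node, node_df in sel.groupby("node"):
        try:
            fit = fit_node_lmm(node_df, reference=reference)
        except (ValueError, np.linalg.LinAlgError):
            continue
        row = {"node": node, "metric": metric, "weighted": weighted,
               "group_omnibus_pvalue": fit.group_omnibus_pvalue,
               "session_effect": fit.session_effect,
               "session_pvalue": fit.session_pvalue,
               "converged": fit.converged}
        for grp, est in fit.group_effects.items():
            row[f"effect_{grp}"] = est
            row[f"pvalue_{grp}"] = fit.group_pvalues[grp]
        rows.append(row)
    return pd.DataFrame(rows)
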