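"""The critical mixed-effects comparisons over the long ISC table.

Three analyses, all on Fisher-z ISC values:

* ``fit_interaction`` — network × condition-type crossover (e.g., language
  vs. ToM crossed with linguistic vs. non-linguistic conditions), with
  maximal random effects: by-participant intercepts and slopes for the two
  main effects and their interaction, plus crossed random intercepts for
  fROI and condition.
* ``fit_condition_contrast`` — a two-level comparison within a subset (e.g.,
  ToM > language restricted to non-linguistic conditions).
* ``test_against_baseline`` — intercept-only test of mean Fisher-z > 0
  (one-tailed), per cell family, FDR-corrected.

Both factors are coded −1/2, +1/2 (sum-to-zero), so a main-effect beta is
the difference between level means (second minus first level) and the
interaction beta is the difference-of-differences
``(net2: type2 − type1) − (net1: type2 − type1)`` — symmetric in factor
ordering up to sign.

If the maximal model fails to converge, random terms are dropped one at a
time — interaction slope, then condition-type slope, then network slope,
then the condition intercept, then the fROI intercept — and the structure
actually fitted is recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .lmm import MixedModelResult, RandomTerm, fit_mixed_model, indicator_matrix, slope_matrix
from .null_inference import fdr_bh

logger = logging.getLogger(__name__)

#: default grouping of the design's condition types into the two-level
#: "linguistic vs non-linguistic" factor of the headline interaction
LINGUISTIC_GROUPS: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("linguistic", ("+Lang+ToM", "+Lang-ToM")),
    ("nonlinguistic", ("-Lang+ToM",)),
)


@dataclass
class ContrastResult:
    """One fixed-effect test from a mixed-effects fit."""

    term: str
    beta: float
    se: float
    t: float
    df: float
    p: float
    converged: bool
    re_structure: str
    model: Optional[MixedModelResult] = None

    def to_dict(self) -> Dict:
        return {
            "term": self.term, "beta": self.beta, "se": self.se, "t": self.t,
            "df": self.df, "p": self.p, "converged": self.converged,
            "re_structure": self.re_structure,
        }


def _coded(values: pd.Series, levels: Tuple[str, str]) -> np.ndarray:
    """Sum-to-zero ±1/2 coding; beta on this column = mean(level2) − mean(level1)."""
    vals = values.to_numpy()
    unknown = set(vals) - set(levels)
    if unknown:
        raise ValueError(f"values {unknown} not in levels {levels}")
    return np.where(vals == levels[1], 0.5, -0.5)


def _group_column(table: pd.DataFrame, groups) -> pd.Series:
    """Map condition_type values into two named groups; rows outside are dropped
    by the caller.  ``groups`` is ((label, (ctypes...)), (label, (ctypes...)))
    or a plain pair of condition_type strings."""
    if isinstance(groups[0], str):
        groups = ((groups[0], (groups[0],)), (groups[1], (groups[1],)))
    mapping = {}
    for label, ctypes in groups:
        for ct in ctypes:
            mapping[ct] = label
    return table["condition_type"].map(mapping)


def _fit_with_ladder(
    y: np.ndarray,
    X: np.ndarray,
    xnames: List[str],
    terms: List[Tuple[str, np.ndarray]],
    drop_order: List[str],
) -> MixedModelResult:
    """Fit with the maximal structure; on non-convergence drop random terms in
    ``drop_order`` until the fit converges (or nothing is left)."""
    remaining = list(terms)
    while True:
        result = fit_mixed_model(y, X, [RandomTerm(n, Z) for n, Z in remaining], xnames)
        if result.converged or result.degenerate or not remaining:
            return result
        for name in drop_order:
            if any(n == name for n, _ in remaining):
                logger.info("mixed model did not converge; dropping random term %r", name)
                remaining = [(n, Z) for n, Z in remaining if n != name]
                break
        else:
            return result


def _check_min_participants(table: pd.DataFrame) -> None:
    if table["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")


def fit_interaction(
    table: pd.DataFrame,
    networks: Tuple[str, str] = ("language", "tom"),
    condition_types=LINGUISTIC_GROUPS,
) -> ContrastResult:
    """Network × condition-type interaction with maximal random effects.

    Rows are restricted to the two networks and to conditions whose type falls
    in one of the two groups.  A positive beta means the second network's
    advantage for the second condition-type level exceeds the first
    network's (see module docstring for the coding).
    """
    sub = table[table["network"].isin(networks)].copy()
    sub["ctype2"] = _group_column(sub, condition_types)
    sub = sub.dropna(subset=["ctype2"])
    labels = tuple(g[0] if not isinstance(g, str) else g for g in condition_types)
    for col, levels in (("network", networks), ("ctype2", labels)):
        present = set(sub[col])
        if set(levels) - present:
            raise ValueError(f"levels {set(levels) - present} of {col} absent from table")
    _check_min_participants(sub)

    x_net = _coded(sub["network"], networks)
    x_typ = _coded(sub["ctype2"], labels)
    x_int = x_net * x_typ
    X = np.column_stack([np.ones(len(sub)), x_net, x_typ, x_int])
    xnames = ["intercept", "network", "condition_type", "network:condition_type"]

    part = sub["participant"]
    terms = [
        ("participant", indicator_matrix(part)),
        ("participant_slope_network", slope_matrix(part, x_net)),
        ("participant_slope_ctype", slope_matrix(part, x_typ)),
        ("participant_slope_interaction", slope_matrix(part, x_int)),
        ("froi", indicator_matrix(sub["froi"])),
        ("condition", indicator_matrix(sub["condition"])),
    ]
    drop_order = [
        "participant_slope_interaction",
        "participant_slope_ctype",
        "participant_slope_network",
        "condition",
        "froi",
        "participant",
    ]
    fit = _fit_with_ladder(sub["z"].to_numpy(), X, xnames, terms, drop_order)
    c = np.array([0.0, 0.0, 0.0, 1.0])
    test = fit.contrast(c, one_tailed=False)
    return ContrastResult(
        term=f"{networks[1]}:{labels[1]} crossover",
        beta=test["estimate"], se=test["se"], t=test["t"], df=test["df"], p=test["p"],
        converged=fit.converged, re_structure=fit.re_structure, model=fit,
    )


def fit_condition_contrast(
    table: pd.DataFrame,
    factor: str,
    levels: Tuple[str, str],
) -> ContrastResult:
    """Two-level mixed-effects contrast (level 2 minus level 1) on a table
    subset, with by-participant intercept and slope plus whichever crossed
    intercepts (fROI, condition) have more than one level in the subset."""
    sub = table[table[factor].isin(levels)]
    if set(levels) - set(sub[factor]):
        raise ValueError(f"both levels {levels} must be present in the table")
    _check_min_participants(sub)
    x = _coded(sub[factor], levels)
    X = np.column_stack([np.ones(len(sub)), x])
    xnames = ["intercept", factor]
    part = sub["participant"]
    terms = [
        ("participant", indicator_matrix(part)),
        ("participant_slope", slope_matrix(part, x)),
    ]
    for group_col in ("froi", "condition"):
        if group_col != factor and sub[group_col].nunique() > 1:
            terms.append((group_col, indicator_matrix(sub[group_col])))
    drop_order = ["participant_slope", "condition", "froi", "participant"]
    fit = _fit_with_ladder(sub["z"].to_numpy(), X, xnames, terms, drop_order)
    test = fit.contrast(np.array([0.0, 1.0]), one_tailed=False)
    return ContrastResult(
        term=f"{factor}: {levels[1]} - {levels[0]}",
        beta=test["estimate"], se=test["se"], t=test["t"], df=test["df"], p=test["p"],
        converged=fit.converged, re_structure=fit.re_structure, model=fit,
    )


def test_against_baseline(table: pd.DataFrame) -> ContrastResult:
    """One-tailed intercept test of mean Fisher-z > 0 on a table subset, with
    participant random intercepts plus crossed fROI/condition intercepts
    where applicable."""
    _check_min_participants(table)
    n = len(table)
    X = np.ones((n, 1))
    terms = [("participant", indicator_matrix(table["participant"]))]
    for group_col in ("froi", "condition"):
        if table[group_col].nunique() > 1:
            terms.append((group_col, indicator_matrix(table[group_col])))
    drop_order = ["condition", "froi", "participant"]
    fit = _fit_with_ladder(table["z"].to_numpy(), X, ["intercept"], terms, drop_order)
    test = fit.contrast(np.array([1.0]), one_tailed=True)
    return ContrastResult(
        term="intercept > 0",
        beta=test["estimate"], se=test["se"], t=test["t"], df=test["df"], p=test["p"],
        converged=fit.converged, re_structure=fit.re_structure, model=fit,
    )


def baseline_tests(
    table: pd.DataFrame,
    by: Sequence[str] = ("network", "condition"),
    q: float = 0.05,
) -> pd.DataFrame:
    """Baseline (intercept) tests for every cell of ``by``, FDR-corrected
    across the family."""
    rows = []
    for keys, sub in table.groupby(list(by)):
        if sub["participant"].nunique() < 2:
            continue
        res = test_against_baseline(sub)
        row = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        row.update(res.to_dict())
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        reject, p_adj = fdr_bh(out["p"].to_numpy(), q=q)
        out["p_fdr"] = p_adj
        out["significant_fdr"] = reject
    return out
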