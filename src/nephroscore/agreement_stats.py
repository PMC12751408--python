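"""Agreement and stratified-outcome statistics.

Two validation tools accompany the scoring pipeline:

* :func:`weighted_kappa` — chance-corrected ordinal agreement between
  two raters/methods with linear (default) or quadratic disagreement
  weights, the Fleiss–Cohen–Everitt large-sample standard error and a
  normal-approximation 95% CI.
* :func:`compare_groups` / :func:`outcome_table` — nonparametric
  comparison of an outcome across score strata: Mann–Whitney U for two
  groups, Kruskal–Wallis plus Dunn's pairwise post hoc (Holm-adjusted by
  default) for three or more, with median (IQR) summaries.

Quartiles use linear interpolation so reported IQRs are reproducible
across implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .csa import stratify_csa
from .renal_score import stratify_renal

__all__ = [
    "AgreementResult",
    "GroupComparison",
    "weighted_kappa",
    "dunn_posthoc",
    "compare_groups",
    "outcome_table",
]


@dataclass
class AgreementResult:
    kappa: float
    se: float
    ci95: tuple[float, float]
    weighting: str
    n: int
    categories: list

    def as_dict(self) -> dict:
        return {"kappa": self.kappa, "se": self.se,
                "ci95": list(self.ci95), "weighting": self.weighting,
                "n": self.n, "categories": list(self.categories)}


@dataclass
class GroupComparison:
    groups: list
    medians: dict
    iqrs: dict
    ns: dict
    test: str
    statistic: float
    p_value: float
    posthoc: list = field(default_factory=list)  # (group_i, group_j, adjusted p)
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "groups": list(self.groups), "n": dict(self.ns),
            "medians": dict(self.medians),
            "iqrs": {k: list(v) for k, v in self.iqrs.items()},
            "test": self.test, "statistic": self.statistic,
            "p_value": self.p_value,
            "posthoc": [[a, b, p] for a, b, p in self.posthoc],
            "flags": list(self.flags),
        }


def _agreement_weights(k: int, weighting: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if k == 1:
        return np.ones((1, 1))
    d = np.abs(i - j) / (k - 1)
    if weighting == "linear":
        return 1.0 - d
    if weighting == "quadratic":
        return 1.0 - d ** 2
    raise ValueError(f"unknown weighting {weighting!r}")


def weighted_kappa(x: Sequence, y: Sequence, categories: Sequence | None = None,
                   weighting: str = "linear") -> AgreementResult:
    """Weighted Cohen's kappa with SE and 95% CI.

    ``categories`` fixes the ordered level set (defaults to the sorted
    union of observed values).  Raises when chance agreement is perfect
    (both raters constant on the same category), where kappa is undefined.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 rating pairs")
    if categories is None:
        categories = sorted(set(x.tolist()) | set(y.tolist()))
    categories = list(categories)
    k = len(categories)
    index = {c: i for i, c in enumerate(categories)}
    try:
        xi = np.array([index[v] for v in x.tolist()])
        yi = np.array([index[v] for v in y.tolist()])
    except KeyError as exc:
        raise ValueError(f"rating {exc.args[0]!r} not in categories") from None

    counts = np.zeros((k, k))
    np.add.at(counts, (xi, yi), 1)
    p = counts / n
    w = _agreement_weights(k, weighting)
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float((w * p).sum())
    p_e = float((w * np.outer(row, col)).sum())
    if 1.0 - p_e < 1e-12:
        raise ValueError("kappa undefined (no variance in ratings)")
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss, Cohen & Everitt large-sample variance for weighted kappa
    wbar_i = w @ col          # row-conditional expected weight
    wbar_j = row @ w          # column-conditional expected weight
    term = w * (1 - p_e) - (wbar_i[:, None] + wbar_j[None, :]) * (1 - p_o)
    var = ((p * term ** 2).sum() - (p_o * p_e - 2 * p_e + p_o) ** 2) \
        / (n * (1 - p_e) ** 4)
    se = math.sqrt(max(var, 0.0))
    lo = max(-1.0, kappa - 1.96 * se)
    hi = min(1.0, kappa + 1.96 * se)
    return AgreementResult(float(kappa), se, (lo, hi), weighting, n, categories)


def _median_iqr(v: np.ndarray) -> tuple[float, tuple[float, float]]:
    q1, q2, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation (type 7)
    return float(q2), (float(q1), float(q3))


def dunn_posthoc(values: np.ndarray, labels: np.ndarray, groups: list,
                 correction: str = "holm") -> list[tuple]:
    """Dunn's pairwise rank-sum z tests after Kruskal–Wallis, tie-corrected."""
    N = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1))
    mean_ranks = {g: ranks[labels == g].mean() for g in groups}
    ns = {g: int((labels == g).sum()) for g in groups}
    pairs, raw = [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi, gj = groups[i], groups[j]
            var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / ns[gi] + 1.0 / ns[gj])
            if var <= 0:
                z = 0.0
            else:
                z = (mean_ranks[gi] - mean_ranks[gj]) / math.sqrt(var)
            pairs.append((gi, gj))
            raw.append(2.0 * stats.norm.sf(abs(z)))
    if not pairs:
        return []
    if correction is None or correction == "none":
        adjusted = raw
    else:
        method = {"holm": "holm", "bonferroni": "bonferroni"}[correction]
        adjusted = multipletests(raw, method=method)[1]
    return [(a, b, float(p)) for (a, b), p in zip(pairs, adjusted)]


def compare_groups(values: Sequence[float], strata: Sequence,
                   posthoc_correction: str = "holm") -> GroupComparison:
    """Rank-based comparison of an outcome across score strata.

    Two strata: two-sided Mann–Whitney U (normal approximation with tie
    correction).  Three or more: Kruskal–Wallis plus Dunn's post hoc.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(strata)
    if values.shape != labels.shape:
        raise ValueError("values and strata must have equal length")
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    per = {g: values[labels == g] for g in groups}
    for g, v in per.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
    medians, iqrs, ns = {}, {}, {}
    for g, v in per.items():
        medians[g], iqrs[g] = _median_iqr(v)
        ns[g] = len(v)

    flags: list[str] = []
    if np.ptp(values) == 0:
        test = "kruskal-wallis" if len(groups) > 2 else "mann-whitney-u"
        flags.append("DEGENERATE_ALL_IDENTICAL")
        return GroupComparison(groups, medians, iqrs, ns, test, 0.0, 1.0,
                               [], flags)

    if len(groups) == 2:
        res = stats.mannwhitneyu(per[groups[0]], per[groups[1]],
                                 alternative="two-sided", method="asymptotic")
        return GroupComparison(groups, medians, iqrs, ns, "mann-whitney-u",
                               float(res.statistic), float(res.pvalue), [], flags)
    res = stats.kruskal(*[per[g] for g in groups])
    posthoc = dunn_posthoc(values, labels, groups, posthoc_correction)
    return GroupComparison(groups, medians, iqrs, ns, "kruskal-wallis",
                           float(res.statistic), float(res.pvalue),
                           posthoc, flags)


def outcome_table(scores: pd.DataFrame, outcomes: pd.DataFrame,
                  mode: str, posthoc_correction: str = "holm") -> dict:
    """Stratified perioperative-outcome summary, one test per outcome column.

    ``scores`` needs columns ``case_id`` and ``score`` (R.E.N.A.L. total
    in ``mode="renal"``, CSA in cm^2 in ``mode="csa"``); ``outcomes``
    needs ``case_id`` plus numeric outcome columns.  Missing outcome
    values are dropped per column (complete-case), with exclusion counts
    reported.
    """
    if mode == "renal":
        assign = lambda s: stratify_renal(int(s))
        order = ["low", "moderate", "high"]
    elif mode == "csa":
        assign = stratify_csa
        order = ["low", "high"]
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'renal' or 'csa'")

    df = scores.merge(outcomes, on="case_id", how="inner")
    if df.empty:
        raise ValueError("no case ids shared between scores and outcomes")
    df["stratum"] = [assign(s) for s in df["score"]]
    present = [g for g in order if g in set(df["stratum"])]
    n_total = len(df)
    counts = {g: int((df["stratum"] == g).sum()) for g in present}

    table: dict = {
        "mode": mode,
        "n_total": n_total,
        "strata": present,
        "n": counts,
        "n_pct": {g: f"{counts[g]}({100.0 * counts[g] / n_total:.0f}%)"
                  for g in present},
        "outcomes": {},
        "flags": [],
    }
    if len(present) < 2:
        table["flags"].append("ONLY_ONE_STRATUM")

    outcome_cols = [c for c in outcomes.columns if c != "case_id"]
    for col in outcome_cols:
        sub = df[["stratum", col]].dropna()
        excluded = n_total - len(sub)
        entry: dict = {"n_excluded_missing": excluded, "per_stratum": {}}
        for g in present:
            v = sub.loc[sub["stratum"] == g, col].to_numpy(float)
            if len(v):
                med, iqr = _median_iqr(v)
                entry["per_stratum"][g] = {"n": len(v), "median": med,
                                           "iqr": list(iqr)}
            else:
                entry["per_stratum"][g] = {"n": 0, "median": None, "iqr": None}
        groups_here = [g for g in present
                       if entry["per_stratum"][g]["n"] > 0]
        if len(groups_here) >= 2:
            cmpres = compare_groups(
                sub[col].to_numpy(float), sub["stratum"].to_numpy(),
                posthoc_correction=posthoc_correction)
            entry["test"] = cmpres.test
            entry["statistic"] = cmpres.statistic
            entry["p_value"] = cmpres.p_value
            entry["posthoc"] = [[a, b, p] for a, b, p in cmpres.posthoc]
            entry["test_flags"] = cmpres.flags
        else:
            entry["test"] = None
        table["outcomes"][col] = entry
    return table


def outcome_table_frame(table: dict) -> pd.DataFrame:
    """Flatten an :func:`outcome_table` result into a tidy DataFrame (CSV-ready)."""
    rows = []
    for col, entry in table["outcomes"].items():
        row = {"outcome": col, "test": entry.get("test"),
               "statistic": entry.get("statistic"),
               "p_value": entry.get("p_value"),
               "n_excluded_missing": entry["n_excluded_missing"]}
        for g, cell in entry["per_stratum"].items():
            row[f"{g}_n"] = cell["n"]
            row[f"{g}_median"] = cell["median"]
            if cell["iqr"]:
                row[f"{g}_iqr"] = f"{cell['iqr'][0]:g}-{cell['iqr'][1]:g}"
        rows.append(row)
    return pd.DataFrame(rows)
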