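"""Group-level statistics and reporting for per-ROI fit results.

Multi-group comparison follows the workflow typical of FLIM-FRET papers:
a Kruskal-Wallis omnibus test on BINDING (or efficiency), a protected
Fisher's-LSD post hoc on the rank means (Conover style) summarized as a
compact letter display, cut-off-filtered summary tables (efficiency
statistics only over ROIs whose BINDING passed the 10% cut-off), an exact
Wilcoxon signed-rank test for acceptor-photobleaching pairs, and a
Spearman correlation of BINDING against acceptor-channel photon counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import DEFAULT_CUTOFF, OPAFitResult, apply_fret_cutoff
from .exceptions import InvalidInputError

__all__ = [
    "SampleGroup",
    "ComparisonReport",
    "kruskal_wallis",
    "lsd_letters",
    "summary_table",
    "compare_groups",
    "paired_bleach_test",
    "binding_acceptor_correlation",
]


@dataclass(frozen=True)
class SampleGroup:
    """Named collection of per-ROI fit results (one experimental sample)."""

    name: str
    results: tuple[OPAFitResult, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidInputError("group name must be nonempty")
        object.__setattr__(self, "results", tuple(self.results))

    def values(self, variable: str) -> np.ndarray:
        """Converged values of ``binding`` or ``efficiency``.

        Efficiency values are restricted to results whose BINDING passed
        the cut-off (``valid_efficiency``): below it the efficiency is
        unidentifiable and excluded from every statistic.
        """
        if variable == "binding":
            vals = [r.binding_hat for r in self.results if r.converged]
        elif variable == "efficiency":
            vals = [
                r.efficiency_hat
                for r in self.results
                if r.converged and r.valid_efficiency
            ]
        else:
            raise InvalidInputError(f"unknown variable {variable!r}")
        return np.array([v for v in vals if math.isfinite(v)], dtype=float)


@dataclass(frozen=True)
class ComparisonReport:
    """Kruskal-Wallis omnibus + LSD letters + per-group summary rows."""

    variable: str
    alpha: float
    kw_statistic: float
    kw_pvalue: float
    pairwise: pd.DataFrame  # significant-difference matrix (bool) + rank-mean diffs
    letters: dict
    summaries: pd.DataFrame


def _group_values(groups: Sequence[SampleGroup], variable: str) -> list[np.ndarray]:
    data = [g.values(variable) for g in groups]
    nonempty = [d for d in data if len(d) > 0]
    if len(nonempty) < 2:
        raise InvalidInputError("need at least 2 nonempty groups")
    return data


def kruskal_wallis(
    groups: Sequence[SampleGroup], variable: str = "binding"
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value.

    Efficiency comparisons use only results whose BINDING passed the
    cut-off (``valid_efficiency``).  Groups whose values are all identical
    across the board give H = 0, p = 1.
    """
    data = [d for d in _group_values(groups, variable) if len(d) > 0]
    pooled = np.concatenate(data)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*data)
    return float(h), float(p)


def _rank_statistics(data: list[np.ndarray]):
    pooled = np.concatenate(data)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    rank_means, sizes = [], []
    pos = 0
    for d in data:
        sizes.append(len(d))
        rank_means.append(ranks[pos : pos + len(d)].mean() if len(d) else np.nan)
        pos += len(d)
    # variance of the pooled ranks; reduces to N(N+1)/12 without ties
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4) / (n_total - 1)
    return np.array(rank_means), np.array(sizes), n_total, s2


def _pairwise_lsd(
    data: list[np.ndarray], h: float, alpha: float, protected_significant: bool
) -> np.ndarray:
    """Boolean significant-difference matrix from Fisher's LSD on rank means."""
    rank_means, sizes, n_total, s2 = _rank_statistics(data)
    k = len(data)
    sig = np.zeros((k, k), dtype=bool)
    if not protected_significant:
        return sig
    dof = n_total - k
    if dof <= 0:
        return sig
    tcrit = sps.t.ppf(1 - alpha / 2, dof)
    scale = s2 * (n_total - 1 - h) / dof
    for i in range(k):
        for j in range(i + 1, k):
            if sizes[i] == 0 or sizes[j] == 0:
                continue
            lsd = tcrit * np.sqrt(scale * (1 / sizes[i] + 1 / sizes[j]))
            if abs(rank_means[i] - rank_means[j]) > lsd:
                sig[i, j] = sig[j, i] = True
    return sig


def _letters_from_matrix(names: list[str], sig: np.ndarray) -> dict:
    """Compact letter display via maximal cliques of the not-different graph.

    Groups share a letter iff they are not significantly different, which
    the clique construction guarantees in both directions.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if not sig[i, j]:
                g.add_edge(i, j)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    cliques.sort()  # deterministic given input order
    letters = {name: "" for name in names}
    for idx, clique in enumerate(cliques):
        letter = chr(ord("a") + idx) if idx < 26 else f"z{idx}"
        for member in clique:
            letters[names[member]] += letter
    return {name: "".join(sorted(s)) for name, s in letters.items()}


def lsd_letters(
    groups: Sequence[SampleGroup],
    variable: str = "binding",
    alpha: float = 0.05,
) -> dict:
    """Protected Fisher's-LSD letter groups on Kruskal-Wallis rank means.

    When the omnibus test is not significant at ``alpha`` every group
    shares the single letter "a".
    """
    data = _group_values(groups, variable)
    h, p = kruskal_wallis(groups, variable)
    sig = _pairwise_lsd([d for d in data], h, alpha, protected_significant=p < alpha)
    return _letters_from_matrix([g.name for g in groups], sig)


def summary_table(
    groups: Sequence[SampleGroup], cutoff: float | None = None
) -> pd.DataFrame:
    """Per-group summary rows in the style of a supplementary results table.

    BINDING statistics run over all converged results; efficiency
    statistics only over results flagged ``valid_efficiency`` (by default
    the flags carried on the results are trusted; pass ``cutoff`` to
    re-apply the threshold first).  SE = SD / sqrt(n) with the n-1 sample
    SD.  Groups with no valid efficiencies report NaN ("absent"), never 0.
    """
    rows = []
    for g in groups:
        results = [
            apply_fret_cutoff(r, cutoff) if cutoff is not None else r
            for r in g.results
        ]
        b = np.array(
            [r.binding_hat for r in results if r.converged and math.isfinite(r.binding_hat)]
        )
        e = np.array(
            [
                r.efficiency_hat
                for r in results
                if r.converged and r.valid_efficiency and math.isfinite(r.efficiency_hat)
            ]
        )
        def _stats(x: np.ndarray):
            if len(x) == 0:
                return (np.nan, np.nan, np.nan)
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else np.nan
            return float(np.mean(x)), sd, (sd / np.sqrt(len(x)) if len(x) > 1 else np.nan)

        mb, sb, seb = _stats(b)
        me, se_, see = _stats(e)
        rows.append(
            {
                "group": g.name,
                "n": len(results),
                "n_above_cutoff": int(len(e)),
                "mean_B": mb,
                "sd_B": sb,
                "se_B": seb,
                "mean_E": me,
                "sd_E": se_,
                "se_E": see,
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    groups: Sequence[SampleGroup],
    variable: str = "binding",
    alpha: float = 0.05,
    cutoff: float = DEFAULT_CUTOFF,
) -> ComparisonReport:
    """Full comparison: omnibus test, pairwise LSD matrix, letters, summaries."""
    data = _group_values(groups, variable)
    h, p = kruskal_wallis(groups, variable)
    sig = _pairwise_lsd(data, h, alpha, protected_significant=p < alpha)
    names = [g.name for g in groups]
    letters = _letters_from_matrix(names, sig)
    pairwise = pd.DataFrame(sig, index=names, columns=names)
    return ComparisonReport(
        variable=variable,
        alpha=alpha,
        kw_statistic=h,
        kw_pvalue=p,
        pairwise=pairwise,
        letters=letters,
        summaries=summary_table(groups),
    )


def paired_bleach_test(
    before: SampleGroup, after: SampleGroup, alternative: str = "less"
) -> tuple[float, float, pd.DataFrame]:
    """Wilcoxon signed-rank on per-ROI BINDING deltas (after - before).

    ROIs are matched by ``roi_id``; any orphan on either side is an error.
    The exact null distribution is used for n <= 25.  The default
    one-sided alternative tests for the BINDING drop expected after
    acceptor photobleaching.  All-zero deltas degenerate to "no change"
    (statistic 0, p = 1).
    """
    before_map = {r.roi_id: r for r in before.results}
    after_map = {r.roi_id: r for r in after.results}
    orphans = sorted(
        set(before_map) ^ set(after_map), key=repr
    )
    if orphans:
        raise InvalidInputError(f"unmatched roi_ids between groups: {orphans}")
    ids = sorted(before_map, key=repr)
    deltas = np.array(
        [after_map[i].binding_hat - before_map[i].binding_hat for i in ids]
    )
    table = pd.DataFrame(
        {
            "roi_id": ids,
            "binding_before": [before_map[i].binding_hat for i in ids],
            "binding_after": [after_map[i].binding_hat for i in ids],
            "delta": deltas,
        }
    )
    if np.all(deltas == 0):
        return 0.0, 1.0, table
    method = "exact" if len(deltas) <= 25 else "approx"
    stat, p = sps.wilcoxon(deltas, alternative=alternative, method=method)
    return float(stat), float(p), table


def binding_acceptor_correlation(
    results: Sequence[OPAFitResult], method: str = "spearman"
) -> tuple[float, float, int]:
    """Rank correlation of BINDING against acceptor-channel photon counts.

    Results lacking ``acceptor_photons`` are skipped; fewer than 3 usable
    points is an error.  Returns ``(rho, p, n_used)``.
    """
    pairs = [
        (r.binding_hat, r.acceptor_photons)
        for r in results
        if r.acceptor_photons is not None and math.isfinite(r.binding_hat)
    ]
    if len(pairs) < 3:
        raise InvalidInputError(
            f"need at least 3 results with acceptor_photons, got {len(pairs)}"
        )
    b, a = map(np.array, zip(*pairs))
    if method == "spearman":
        rho, p = sps.spearmanr(b, a)
    elif method == "pearson":
        rho, p = sps.pearsonr(b, a)
    else:
        raise InvalidInputError(f"unknown correlation method {method!r}")
    return float(rho), float(p), len(pairs)
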