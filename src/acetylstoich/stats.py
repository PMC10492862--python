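"""Per-site group comparison and model-vs-model overlap summaries.

Significance of a stoichiometry change at a lysine site is assessed in two
steps: a one-way ANOVA across groups for every peptidoform that covers the
site (fragments within a peptidoform are not independent, peptidoforms
approximately are), then Fisher's method to combine the per-peptidoform
p-values into one site-level p. Sites are flagged at unadjusted p < 0.05 by
default, with Benjamini-Hochberg adjusted values always reported alongside.
Distribution shifts between two sets of stoichiometry changes are compared
with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "anova_oneway",
    "fisher_combine",
    "ks_two_sample",
    "bh_fdr",
    "group_comparison",
    "compare_models",
    "site_presence",
    "OverlapSummary",
]

_TINY_P = float(np.finfo(float).tiny)


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: F statistic and upper-tail p.

    Requires at least two groups with at least two values each. With zero
    between-group variance the test returns F = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    res = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    f = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(f):  # all values identical: no variance anywhere
        return 0.0, 1.0
    return f, p


def fisher_combine(pvalues: Iterable[float]) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square with 2k df.

    p-values of exactly 0 are floored at the smallest positive float (and
    logged); combining a single p-value returns it unchanged.
    """
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        raise ValueError("cannot combine an empty list of p-values")
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (ps == 0).any():
        logger.warning("flooring %d zero p-values at %g", int((ps == 0).sum()), _TINY_P)
        ps = np.maximum(ps, _TINY_P)
    x = -2.0 * np.log(ps).sum()
    return float(sps.chi2.sf(x, df=2 * ps.size))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample KS test: D = sup |ECDF_x - ECDF_y| and its p-value.

    Uses the exact null distribution when both samples have n <= 10,
    otherwise the asymptotic approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (x.size <= 10 and y.size <= 10) else "asymp"
    res = sps.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        return np.array([])
    return multipletests(ps, method="fdr_bh")[1]


def group_comparison(
    peptidoforms: pd.DataFrame,
    sites: pd.DataFrame,
    groups: Sequence[str],
    reference: str,
    alpha: float = 0.05,
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Per-site stoichiometry comparison across groups.

    Parameters
    ----------
    peptidoforms:
        Peptidoform-level table (protein_id, site_position, peptidoform_id,
        group, replicate_id, stoichiometry) from the quantification step.
    sites:
        Site-level table used for group means and presence filtering.
    groups:
        Group labels entering the one-way ANOVA (>= 2, including
        ``reference``). Two groups gives the model-vs-reference volcano; the
        same machinery runs a direct model-vs-model test or a three-group
        global test.
    reference:
        Baseline group; ``delta`` is (other mean - reference mean) when
        exactly two groups are compared, NaN otherwise.
    min_replicates:
        A site must be quantified in at least this many replicates of every
        group to be tested; sites detected in only some groups are excluded
        here and belong in the presence/absence table (:func:`site_presence`).

    Returns one row per testable site with per-group means, delta,
    ``p_anova_min`` (smallest per-peptidoform ANOVA p), Fisher-combined
    ``p_site``, BH-adjusted ``q_bh`` and a ``significant`` flag
    (p_site < alpha).
    """
    groups = list(groups)
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not in groups {groups}")
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    others = [g for g in groups if g != reference]

    pf = peptidoforms[peptidoforms["group"].isin(groups)]
    st = sites[sites["group"].isin(groups)]

    # presence filter: >= min_replicates site-level rows in every group
    counts = (
        st.groupby(["protein_id", "site_position", "group"])["replicate_id"]
        .nunique()
        .unstack("group")
        .reindex(columns=groups)
    )
    testable = counts.dropna()
    testable_keys = set(testable[(testable >= min_replicates).all(axis=1)].index)

    means = (
        st.groupby(["protein_id", "site_position", "group"])["stoichiometry"]
        .mean()
        .unstack("group")
        .reindex(columns=groups)
    )

    rows = []
    skipped = 0
    for (protein_id, site_position), site_pf in pf.groupby(
        ["protein_id", "site_position"], sort=True
    ):
        if (protein_id, site_position) not in testable_keys:
            continue
        p_values = []
        for _, pf_rows in site_pf.groupby("peptidoform_id"):
            samples = [
                pf_rows.loc[pf_rows["group"] == g, "stoichiometry"].to_numpy()
                for g in groups
            ]
            if any(len(s) < 2 for s in samples):
                continue
            _, p = anova_oneway(samples)
            p_values.append(p)
        if not p_values:
            skipped += 1
            continue
        p_site = fisher_combine(p_values)
        mu = means.loc[(protein_id, site_position)]
        delta = (
            float(mu[others[0]] - mu[reference]) if len(others) == 1 else float("nan")
        )
        row = {
            "protein_id": protein_id,
            "site_position": int(site_position),
            **{f"mean_{g}": float(mu[g]) for g in groups},
            "delta": delta,
            "n_peptidoforms": len(p_values),
            "p_anova_min": float(min(p_values)),
            "p_site": p_site,
        }
        rows.append(row)
    if skipped:
        logger.info("skipped %d sites with insufficient replication", skipped)

    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["q_bh"] = bh_fdr(result["p_site"])
    result["significant"] = result["p_site"] < alpha
    result["neg_log10_p"] = -np.log10(np.maximum(result["p_site"], _TINY_P))
    return result


def site_presence(
    sites: pd.DataFrame, groups: Sequence[str], min_replicates: int = 3
) -> pd.DataFrame:
    """Per-site boolean detection table across groups.

    Sites quantified in only some genotypes cannot enter the stoichiometry
    test; this table reports where each site met the replication threshold.
    """
    counts = (
        sites[sites["group"].isin(groups)]
        .groupby(["protein_id", "site_position", "group"])["replicate_id"]
        .nunique()
        .unstack("group")
        .reindex(columns=list(groups))
        .fillna(0)
    )
    return (counts >= min_replicates).reset_index()


@dataclass(frozen=True)
class OverlapSummary:
    """Shared/unique counts of significant sites and proteins for two models."""

    sites_shared: int
    sites_unique_a: int
    sites_unique_b: int
    proteins_shared: int
    proteins_unique_a: int
    proteins_unique_b: int

    @property
    def sites_total_a(self) -> int:
        return self.sites_shared + self.sites_unique_a

    @property
    def sites_total_b(self) -> int:
        return self.sites_shared + self.sites_unique_b

    def to_dict(self) -> dict:
        return {
            "sites": {
                "shared": self.sites_shared,
                "unique_a": self.sites_unique_a,
                "unique_b": self.sites_unique_b,
                "total_a": self.sites_total_a,
                "total_b": self.sites_total_b,
            },
            "proteins": {
                "shared": self.proteins_shared,
                "unique_a": self.proteins_unique_a,
                "unique_b": self.proteins_unique_b,
                "total_a": self.proteins_shared + self.proteins_unique_a,
                "total_b": self.proteins_shared + self.proteins_unique_b,
            },
        }


def compare_models(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    reference: str | None = None,
) -> OverlapSummary:
    """Venn-style overlap of significant sites/proteins between two models.

    Both tables must come from :func:`group_comparison` against the same
    reference group (pass ``reference`` to assert it: each table must carry
    the corresponding ``mean_<reference>`` column).
    """
    if reference is not None:
        col = f"mean_{reference}"
        if col not in table_a.columns or col not in table_b.columns:
            raise ValueError(
                f"both comparison tables must share the reference group {reference!r}"
            )

    def sig_sets(table: pd.DataFrame):
        if table.empty:
            return set(), set()
        sig = table[table["p_site"] < alpha]
        sites = set(zip(sig["protein_id"], sig["site_position"]))
        proteins = set(sig["protein_id"])
        return sites, proteins

    sites_a, prot_a = sig_sets(table_a)
    sites_b, prot_b = sig_sets(table_b)
    return OverlapSummary(
        sites_shared=len(sites_a & sites_b),
        sites_unique_a=len(sites_a - sites_b),
        sites_unique_b=len(sites_b - sites_a),
        proteins_shared=len(prot_a & prot_b),
        proteins_unique_a=len(prot_a - prot_b),
        proteins_unique_b=len(prot_b - prot_a),
    )
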