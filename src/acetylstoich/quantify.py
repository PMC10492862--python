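"""Envelope-corrected acetylation stoichiometry from paired peak areas.

For each fragment pair the endogenous-acetyl fraction of a lysine site is

    s = L / (L + H_corr),      H_corr = max(0, H_obs - L * r)

where ``L`` is the light (endogenous acetyl) fragment peak area, ``H_obs``
the observed heavy (chemical acetyl) area, and ``r = a_{3k}/a_0`` the natural
+3k isotopologue leakage ratio of the light fragment envelope. Subtracting
``L * r`` removes the natural-isotope contribution of the light species from
the heavy channel; over-corrected areas are clamped at zero (and flagged)
because negative peak areas are physically meaningless.

Site-level values use only *site-informative* fragments -- those covering
exactly one lysine -- and aggregate them with the median across fragments,
peptidoforms and charges (robust to a single interfered fragment).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .peptides import build_pair_table, pairs_to_frame, parse_peptidoform_id

logger = logging.getLogger(__name__)

__all__ = [
    "correct_heavy",
    "fragment_stoichiometry",
    "fragment_table",
    "aggregate_site",
    "quantify_study",
    "qc_labeling",
    "QuantifyResult",
    "SITE_TABLE_COLUMNS",
]

SITE_TABLE_COLUMNS = [
    "protein_id",
    "site_position",
    "group",
    "replicate_id",
    "stoichiometry",
    "n_fragments_used",
    "clamped_flag",
]


def correct_heavy(L: float, H_obs: float, r: float) -> tuple[float, bool]:
    """Strip light-envelope leakage from the heavy area.

    Returns ``(H_corr, clamped)`` with ``H_corr = max(0, H_obs - L*r)``;
    ``clamped`` records that the subtraction went below zero.
    """
    if L < 0 or H_obs < 0 or r < 0:
        raise ValueError("areas and correction ratio must be non-negative")
    raw = H_obs - L * r
    if raw < 0:
        return 0.0, True
    return raw, False


def fragment_stoichiometry(L: float, H_corr: float) -> float:
    """Endogenous fraction s = L / (L + H_corr); NaN when both areas are 0."""
    if L < 0 or H_corr < 0:
        raise ValueError("areas must be non-negative")
    total = L + H_corr
    if total == 0:
        logger.debug("zero total area; measurement dropped")
        return float("nan")
    return L / total


def _vector_correct(light: np.ndarray, heavy: np.ndarray, ratio: np.ndarray):
    raw = heavy - light * ratio
    clamped = raw < 0
    h_corr = np.where(clamped, 0.0, raw)
    total = light + h_corr
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(total > 0, light / total, np.nan)
    return h_corr, clamped, s


def fragment_table(
    quant: pd.DataFrame,
    sequences: Mapping[str, str],
    apply_correction: bool = True,
) -> pd.DataFrame:
    """Per-fragment stoichiometries from a raw light/heavy quant table.

    The quant table carries no correction ratios; they are recomputed from
    the protein sequences by rebuilding each peptidoform and its in-silico
    pair table, then joining on (peptidoform_id, charge, kind, index).
    Setting ``apply_correction=False`` skips the envelope correction (used to
    demonstrate the bias it removes).
    """
    if quant.empty:
        raise ValueError("empty quant table")
    if (quant["light_area"] < 0).any() or (quant["heavy_area"] < 0).any():
        raise ValueError("peak areas must be non-negative")

    keys = quant[["peptidoform_id", "charge"]].drop_duplicates()
    peptidoforms = {}
    for pid, charge in keys.itertuples(index=False):
        peptidoforms[(pid, int(charge))] = parse_peptidoform_id(
            pid, sequences, charge=int(charge)
        )
    # one pair table per charge set actually observed
    frames = []
    by_charge: dict[int, list] = {}
    for (pid, charge), p in peptidoforms.items():
        by_charge.setdefault(charge, []).append(p)
    for charge, pfs in by_charge.items():
        frames.append(pairs_to_frame(build_pair_table(pfs, charges=(charge,))))
    pair_df = pd.concat(frames, ignore_index=True)

    join_keys = ["peptidoform_id", "charge", "fragment_kind", "fragment_index"]
    merged = quant.merge(
        pair_df[join_keys + ["k_acetyl", "site_position", "correction_ratio"]],
        on=join_keys,
        how="left",
        suffixes=("", "_pair"),
        validate="many_to_one",
    )
    unmatched = merged["correction_ratio"].isna()
    if unmatched.any():
        bad = merged.loc[unmatched, join_keys].head()
        raise ValueError(
            f"{int(unmatched.sum())} quant rows reference fragments with no "
            f"in-silico pair (first offenders:\n{bad})"
        )
    if "k_acetyl_pair" in merged.columns:
        mismatch = merged["k_acetyl"] != merged["k_acetyl_pair"]
        if mismatch.any():
            raise ValueError(
                f"{int(mismatch.sum())} quant rows disagree with the in-silico "
                "pair table on k_acetyl"
            )
        merged = merged.drop(columns=["k_acetyl_pair"])
    if "site_position_pair" in merged.columns:
        merged["site_position"] = merged["site_position_pair"]
        merged = merged.drop(columns=["site_position_pair"])

    light = merged["light_area"].to_numpy(float)
    heavy = merged["heavy_area"].to_numpy(float)
    ratio = merged["correction_ratio"].to_numpy(float)
    if not apply_correction:
        ratio = np.zeros_like(ratio)
    h_corr, clamped, s = _vector_correct(light, heavy, ratio)
    merged["heavy_corrected"] = h_corr
    merged["clamped_flag"] = clamped
    merged["stoichiometry"] = s
    n_dropped = int(np.isnan(s).sum())
    if n_dropped:
        logger.info("dropped %d fragments with zero total area", n_dropped)
    return merged[~merged["stoichiometry"].isna()].reset_index(drop=True)


def aggregate_site(
    fragments: pd.DataFrame,
    min_fragments: int = 3,
    statistic: str = "median",
) -> pd.DataFrame:
    """Site x group x replicate stoichiometry from informative fragments.

    Only fragments covering exactly one lysine (``k_acetyl == 1``) localize
    the measurement to a site; fragments spanning two or more acetyl-lysines
    are discarded. A row is emitted only when at least ``min_fragments``
    informative fragments contributed.
    """
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    informative = fragments[fragments["k_acetyl"] == 1]
    if informative.empty:
        return pd.DataFrame(columns=SITE_TABLE_COLUMNS)
    grouped = informative.groupby(
        ["protein_id", "site_position", "group", "replicate_id"], sort=True
    )
    agg = grouped.agg(
        stoichiometry=("stoichiometry", statistic),
        n_fragments_used=("stoichiometry", "size"),
        clamped_flag=("clamped_flag", "any"),
    ).reset_index()
    agg["site_position"] = agg["site_position"].astype(int)
    agg = agg[agg["n_fragments_used"] >= min_fragments]
    return agg.reset_index(drop=True)[SITE_TABLE_COLUMNS]


def aggregate_peptidoform(
    fragments: pd.DataFrame, statistic: str = "median"
) -> pd.DataFrame:
    """Peptidoform-level stoichiometries (inputs to per-site testing).

    Fragments of one peptidoform share chromatographic context and are not
    independent, so downstream statistics first reduce them to a single value
    per peptidoform x replicate and only then treat peptidoforms as
    approximately independent measurements of their site.
    """
    informative = fragments[fragments["k_acetyl"] == 1]
    grouped = informative.groupby(
        ["protein_id", "site_position", "peptidoform_id", "group", "replicate_id"],
        sort=True,
    )
    agg = grouped.agg(
        stoichiometry=("stoichiometry", statistic),
        n_fragments_used=("stoichiometry", "size"),
    ).reset_index()
    agg["site_position"] = agg["site_position"].astype(int)
    return agg


@dataclass
class QuantifyResult:
    """Pipeline output: fragment, peptidoform and site tables plus QC."""

    fragments: pd.DataFrame
    peptidoforms: pd.DataFrame
    sites: pd.DataFrame
    qc: dict = field(default_factory=dict)


def quantify_study(
    quant: pd.DataFrame,
    sequences: Mapping[str, str],
    min_fragments: int = 3,
    statistic: str = "median",
    apply_correction: bool = True,
) -> QuantifyResult:
    """Full quant-table -> site-stoichiometry pipeline with QC counters."""
    frags = fragment_table(quant, sequences, apply_correction=apply_correction)
    sites = aggregate_site(frags, min_fragments=min_fragments, statistic=statistic)
    pforms = aggregate_peptidoform(frags, statistic=statistic)
    qc = {
        "n_quant_rows": int(len(quant)),
        "n_fragments_scored": int(len(frags)),
        "n_clamped": int(frags["clamped_flag"].sum()),
        "clamp_rate": float(frags["clamped_flag"].mean()),
        "n_site_rows": int(len(sites)),
        "n_sites": int(
            sites.groupby(["protein_id", "site_position"]).ngroups if len(sites) else 0
        ),
    }
    return QuantifyResult(frags, pforms, sites, qc)


def qc_labeling(peptidoform_table: pd.DataFrame, threshold: float = 0.99) -> float:
    """Fraction of lysines carrying either acetyl form.

    Expects one row per observed lysine with a ``state`` column in
    {'acetyl-light', 'acetyl-heavy', 'unmodified'}. The chemistry targets
    >99% labeling; a warning is emitted below ``threshold`` because residual
    unmodified lysine is indistinguishable from endogenous (light) signal and
    biases stoichiometry upward by at most 1 - efficiency.
    """
    if peptidoform_table is None or len(peptidoform_table) == 0:
        raise ValueError("empty labeling table")
    states = peptidoform_table["state"]
    bad = ~states.isin(["acetyl-light", "acetyl-heavy", "unmodified"])
    if bad.any():
        raise ValueError(f"unknown lysine states: {sorted(states[bad].unique())}")
    fraction = float((states != "unmodified").mean())
    if fraction < threshold:
        warnings.warn(
            f"labeling efficiency {fraction:.4f} below {threshold:.2f}; "
            "stoichiometries will be biased upward",
            UserWarning,
            stacklevel=2,
        )
    return fraction
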