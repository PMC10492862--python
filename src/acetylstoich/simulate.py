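"""Ground-truthed synthetic study generator.

Stands in for a deposited DIA acetylome experiment: random protein
sequences, their digest and in-silico fragment pair table, per-site true
acetylation stoichiometries for a wild-type group and two overexpression
models, and noisy light/heavy fragment peak areas with

* chemical labeling efficiency eta (default 0.995, i.e. >99% of lysines
  labeled; the unlabeled remainder is booked as light signal -- the
  conservative worst case for bias),
* natural-isotope leakage of the light species into the heavy channel,
  injected with the true envelope ratio of each fragment,
* independent multiplicative log-normal noise on both channels
  (parameterized by CV),
* completely-at-random missingness.

Effect structure: a fixed number of sites per model receives a stoichiometry
shift |delta| ~ Uniform(0.05, 0.3) with random sign (clipped to [0.01,
0.99]); a configurable fraction of affected sites is shared between the two
models (default 30%). Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .peptides import (
    ACETYL_LIGHT,
    Peptidoform,
    build_pair_table,
    digest,
    pairs_to_frame,
)

__all__ = [
    "StudyConfig",
    "StudyBundle",
    "DEFAULT_RESIDUE_FREQUENCIES",
    "simulate_proteome",
    "assign_truth",
    "simulate_quant",
    "simulate_labeling",
    "simulate_enrichment_study",
    "make_study",
    "QUANT_COLUMNS",
]

#: Residue frequencies tuned so trypsin(R)+GluC(E) digestion with
#: acetyl-blocked K yields many 6-30mer peptides carrying a single lysine.
DEFAULT_RESIDUE_FREQUENCIES: dict[str, float] = {
    "A": 0.07, "C": 0.02, "D": 0.05, "E": 0.08, "F": 0.04,
    "G": 0.08, "H": 0.02, "I": 0.05, "K": 0.08, "L": 0.09,
    "M": 0.02, "N": 0.04, "P": 0.04, "Q": 0.04, "R": 0.06,
    "S": 0.07, "T": 0.05, "V": 0.06, "W": 0.01, "Y": 0.03,
}

QUANT_COLUMNS = [
    "protein_id",
    "site_position",
    "peptidoform_id",
    "charge",
    "fragment_kind",
    "fragment_index",
    "k_acetyl",
    "group",
    "replicate_id",
    "light_area",
    "heavy_area",
]


@dataclass
class StudyConfig:
    """Study conditions for the synthetic acetylome.

    Defaults model the design the analysis assumes: three groups (wild type
    plus two overexpression models) with five replicates each, >99% chemical
    labeling, 10% multiplicative noise per channel and modest random
    missingness. ``n_sites`` sites are retained; per model,
    ``affected_fraction`` of sites carries a true shift, of which
    ``shared_fraction`` are common to both models.
    """

    n_proteins: int = 60
    length_range: tuple[int, int] = (250, 450)
    n_sites: int = 200
    groups: tuple[str, ...] = ("WT", "sTgA", "sTgB")
    n_replicates: int = 5
    cv: float = 0.10
    labeling_efficiency: float = 0.995
    missing_rate: float = 0.05
    affected_fraction: float = 0.25
    shared_fraction: float = 0.30
    effect_low: float = 0.05
    effect_high: float = 0.30
    baseline_range: tuple[float, float] = (0.05, 0.95)
    charges: tuple[int, ...] = (2,)
    max_missed: int = 1
    length_bounds: tuple[int, int] = (6, 30)
    min_fragments_per_site: int = 3
    total_abundance: float = 1e5
    abundance_sigma: float = 0.5  # log-scale spread of latent fragment totals
    n_categories: int = 20
    category_size_range: tuple[int, int] = (6, 15)
    seed: int = 20230909

    def validate(self) -> None:
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling_efficiency must lie in (0, 1]")
        for name in ("shared_fraction", "affected_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if len(self.groups) != 3:
            raise ValueError("expected three groups: reference plus two models")
        if self.n_proteins < 1 or self.n_sites < 1 or self.n_replicates < 1:
            raise ValueError("sizes must be positive")
        if not 0 < self.effect_low <= self.effect_high:
            raise ValueError("effect bounds must satisfy 0 < low <= high")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (250, 450),
    seed: int | np.random.Generator = 0,
    frequencies: dict[str, float] | None = None,
) -> list[tuple[str, str]]:
    """Random protein records ``(id, sequence)``; deterministic given seed."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = frequencies or DEFAULT_RESIDUE_FREQUENCIES
    letters = np.array(sorted(freqs))
    probs = np.array([freqs[aa] for aa in letters], dtype=float)
    probs = probs / probs.sum()
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        records.append((f"SYNP{i + 1:04d}", seq))
    return records


def _study_peptidoforms(records, cfg: StudyConfig) -> list[Peptidoform]:
    """Digest all proteins and build light-state peptidoforms with >= 1 K.

    Fixed carbamidomethylation is applied at every cysteine and every lysine
    carries a light acetyl (the endogenous state of the in-silico library).
    """
    peptidoforms = []
    for protein_id, seq in records:
        for start, end in digest(
            seq, max_missed=cfg.max_missed, length_bounds=cfg.length_bounds
        ):
            pep = seq[start - 1 : end]
            if "K" not in pep:
                continue
            mods = [
                (i, ACETYL_LIGHT) for i, aa in enumerate(pep, start=1) if aa == "K"
            ]
            mods += [
                (i, "carbamidomethyl")
                for i, aa in enumerate(pep, start=1)
                if aa == "C"
            ]
            peptidoforms.append(
                Peptidoform(protein_id, start, end, pep, tuple(sorted(mods)))
            )
    return peptidoforms


def build_informative_pairs(records, cfg: StudyConfig) -> pd.DataFrame:
    """Site-informative fragment pair table (k_acetyl == 1) for the study."""
    pairs = build_pair_table(_study_peptidoforms(records, cfg), charges=cfg.charges)
    df = pairs_to_frame(pairs)
    df = df[df["k_acetyl"] == 1].copy()
    df["site_position"] = df["site_position"].astype(int)
    return df.reset_index(drop=True)


def select_sites(
    pair_df: pd.DataFrame, cfg: StudyConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Keep cfg.n_sites sites with enough informative fragments each."""
    per_site = pair_df.groupby(["protein_id", "site_position"]).size()
    eligible = per_site[per_site >= cfg.min_fragments_per_site].index.to_list()
    if len(eligible) < cfg.n_sites:
        raise ValueError(
            f"only {len(eligible)} quantifiable sites available; "
            f"raise n_proteins to reach n_sites={cfg.n_sites}"
        )
    chosen_idx = rng.choice(len(eligible), size=cfg.n_sites, replace=False)
    chosen = {eligible[i] for i in chosen_idx}
    mask = [
        (p, s) in chosen
        for p, s in zip(pair_df["protein_id"], pair_df["site_position"])
    ]
    return pair_df[mask].reset_index(drop=True)


def assign_truth(
    sites: Sequence[tuple[str, int]], cfg: StudyConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """True per-group stoichiometries and effect flags for each site.

    Exact counts: per model, round(affected_fraction * n_sites) sites are
    affected, of which round(shared_fraction * affected) are shared between
    models; the rest of the sites are null (identical across groups).
    """
    n = len(sites)
    n_aff = int(round(cfg.affected_fraction * n))
    n_shared = int(round(cfg.shared_fraction * n_aff))
    n_unique = n_aff - n_shared
    if n_shared + 2 * n_unique > n:
        raise ValueError("affected/shared fractions exceed the available sites")
    flags = np.array(
        ["shared"] * n_shared
        + ["model_a_only"] * n_unique
        + ["model_b_only"] * n_unique
        + ["no_effect"] * (n - n_shared - 2 * n_unique)
    )
    rng.shuffle(flags)

    ref, model_a, model_b = cfg.groups
    s_ref = rng.uniform(*cfg.baseline_range, size=n)

    def shifted(mask: np.ndarray) -> np.ndarray:
        out = s_ref.copy()
        k = int(mask.sum())
        delta = rng.uniform(cfg.effect_low, cfg.effect_high, size=k)
        sign = rng.choice([-1.0, 1.0], size=k)
        out[mask] = np.clip(s_ref[mask] + sign * delta, 0.01, 0.99)
        return out

    affected_a = np.isin(flags, ["shared", "model_a_only"])
    affected_b = np.isin(flags, ["shared", "model_b_only"])
    truth = pd.DataFrame(
        {
            "protein_id": [p for p, _ in sites],
            "site_position": [s for _, s in sites],
            "effect_flag": flags,
            f"s_{ref}": s_ref,
            f"s_{model_a}": shifted(affected_a),
            f"s_{model_b}": shifted(affected_b),
        }
    )
    return truth


def simulate_quant(
    truth: pd.DataFrame,
    pair_df: pd.DataFrame,
    cfg: StudyConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Noisy light/heavy areas for every fragment x group x replicate.

    Per fragment and replicate a latent total T is drawn log-normally, then
    light = T * (s*eta + (1-eta)), heavy = T * (1-s) * eta + light * r with r
    the fragment's true envelope leakage ratio, and both channels receive
    independent mean-1 log-normal noise with the configured CV before rows
    drop out at the missing rate.
    """
    cfg.validate()
    eta = cfg.labeling_efficiency
    merged = pair_df.merge(truth, on=["protein_id", "site_position"], how="inner")
    n_pairs = len(merged)
    if n_pairs == 0:
        raise ValueError("no fragments map to the truth sites")

    n_rep = cfg.n_replicates
    sigma_noise = float(np.sqrt(np.log1p(cfg.cv**2)))
    frames = []
    for group in cfg.groups:
        s = merged[f"s_{group}"].to_numpy()
        r = merged["correction_ratio"].to_numpy()
        for rep in range(1, n_rep + 1):
            T = cfg.total_abundance * np.exp(
                rng.normal(0.0, cfg.abundance_sigma, size=n_pairs)
            )
            light = T * (s * eta + (1.0 - eta))
            heavy = T * (1.0 - s) * eta + light * r
            if cfg.cv > 0:
                light = light * np.exp(
                    rng.normal(-0.5 * sigma_noise**2, sigma_noise, size=n_pairs)
                )
                heavy = heavy * np.exp(
                    rng.normal(-0.5 * sigma_noise**2, sigma_noise, size=n_pairs)
                )
            block = merged[
                [
                    "protein_id",
                    "site_position",
                    "peptidoform_id",
                    "charge",
                    "fragment_kind",
                    "fragment_index",
                    "k_acetyl",
                ]
            ].copy()
            block["group"] = group
            block["replicate_id"] = f"{group}_r{rep}"
            block["light_area"] = light
            block["heavy_area"] = heavy
            if cfg.missing_rate > 0:
                keep = rng.random(n_pairs) >= cfg.missing_rate
                block = block[keep]
            frames.append(block)
    return pd.concat(frames, ignore_index=True)[QUANT_COLUMNS]


def simulate_labeling(
    truth: pd.DataFrame,
    cfg: StudyConfig,
    rng: np.random.Generator,
    n_molecules: int = 200,
) -> pd.DataFrame:
    """Per-lysine modification states for labeling-efficiency QC.

    For each site and replicate of the reference group, ``n_molecules``
    molecule observations are drawn: endogenous acetyl with probability s,
    otherwise chemically labeled with probability eta, otherwise unmodified.
    Returned long-format with one row per (site, replicate, state) count
    expanded into a ``state`` column summary table.
    """
    ref = cfg.groups[0]
    s = truth[f"s_{ref}"].to_numpy()
    eta = cfg.labeling_efficiency
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        n_light = rng.binomial(n_molecules, s)
        n_heavy = rng.binomial(n_molecules - n_light, eta)
        n_unmod = n_molecules - n_light - n_heavy
        for (protein_id, site_position), nl, nh, nu in zip(
            zip(truth["protein_id"], truth["site_position"]), n_light, n_heavy, n_unmod
        ):
            rows.append((protein_id, site_position, f"{ref}_r{rep}", "acetyl-light", nl))
            rows.append((protein_id, site_position, f"{ref}_r{rep}", "acetyl-heavy", nh))
            rows.append((protein_id, site_position, f"{ref}_r{rep}", "unmodified", nu))
    counts = pd.DataFrame(
        rows, columns=["protein_id", "site_position", "replicate_id", "state", "count"]
    )
    # expand to one row per observed lysine for qc_labeling
    expanded = counts.loc[counts.index.repeat(counts["count"])].drop(columns="count")
    return expanded.reset_index(drop=True)


def simulate_enrichment_study(
    seed: int,
    n_universe: int = 800,
    n_sig: int = 120,
    n_categories: int = 25,
    category_size_range: tuple[int, int] = (15, 40),
    planted_size: int = 40,
    planted_fold: float = 5.0,
) -> dict:
    """A planted over-representation problem for the enrichment module.

    One category of ``planted_size`` proteins is constructed so its expected
    fold enrichment in the significant list equals ``planted_fold``; the
    remaining categories sample the universe uniformly (expected fold 1).
    Returns the universe, significant set, long-format annotations and the
    planted category id.
    """
    rng = np.random.default_rng(seed)
    universe = [f"BGP{i:05d}" for i in range(n_universe)]
    sig = set(rng.choice(universe, size=n_sig, replace=False))
    non_sig = [p for p in universe if p not in sig]

    hit_prob = min(1.0, planted_fold * n_sig / n_universe)
    k = rng.binomial(planted_size, hit_prob)
    k = min(k, n_sig, planted_size)
    planted = list(rng.choice(sorted(sig), size=k, replace=False)) + list(
        rng.choice(non_sig, size=planted_size - k, replace=False)
    )

    rows = [("CAT_PLANTED", p) for p in planted]
    for i in range(n_categories - 1):
        size = int(rng.integers(category_size_range[0], category_size_range[1] + 1))
        members = rng.choice(universe, size=size, replace=False)
        rows.extend((f"CAT{i:03d}", p) for p in members)
    annotations = pd.DataFrame(rows, columns=["category_id", "protein_id"])
    return {
        "universe": set(universe),
        "sig_proteins": sig,
        "annotations": annotations,
        "planted_category": "CAT_PLANTED",
    }


def _make_annotations(
    truth: pd.DataFrame, universe: list, cfg: StudyConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Random categories over the study proteins plus one planted category.

    The planted category collects proteins ranked by their number of affected
    sites, so it concentrates true signal; with a detectability-conditioned
    universe of this size its attainable fold enrichment is modest (bounded
    by N / n_significant), which mirrors real stoichiometry studies.
    """
    affected = truth[truth["effect_flag"] != "no_effect"]
    ranked = (
        affected.groupby("protein_id")
        .size()
        .sort_values(ascending=False)
        .index.to_list()
    )
    lo, hi = cfg.category_size_range
    planted_size = min(max(lo, len(ranked) // 3), hi, len(ranked))
    rows = [("CAT_PLANTED", p) for p in ranked[:planted_size]]
    for i in range(cfg.n_categories - 1):
        size = int(rng.integers(lo, min(hi, len(universe)) + 1))
        members = rng.choice(universe, size=size, replace=False)
        rows.extend((f"CAT{i:03d}", p) for p in members)
    return pd.DataFrame(rows, columns=["category_id", "protein_id"])


@dataclass
class StudyBundle:
    """Everything one synthetic study produces, in memory."""

    config: StudyConfig
    proteins: list  # [(protein_id, sequence)]
    pair_table: pd.DataFrame
    truth: pd.DataFrame
    quant: pd.DataFrame
    labeling: pd.DataFrame
    annotations: pd.DataFrame

    @property
    def sequences(self) -> dict:
        return dict(self.proteins)


def make_study(cfg: StudyConfig | None = None) -> StudyBundle:
    """One-call synthetic study: proteome, truth, quant, labeling, categories."""
    cfg = cfg or StudyConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    records = simulate_proteome(cfg.n_proteins, cfg.length_range, rng)
    pair_df = build_informative_pairs(records, cfg)
    pair_df = select_sites(pair_df, cfg, rng)
    sites = sorted(
        set(zip(pair_df["protein_id"], pair_df["site_position"].astype(int)))
    )
    truth = assign_truth(sites, cfg, rng)
    quant = simulate_quant(truth, pair_df, cfg, rng)
    labeling = simulate_labeling(truth, cfg, rng)
    universe = sorted({p for p, _ in sites})
    annotations = _make_annotations(truth, universe, cfg, rng)
    return StudyBundle(cfg, records, pair_df, truth, quant, labeling, annotations)
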