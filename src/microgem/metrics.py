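"""Individualized microbiome metabolism metrics.

From a pool of species GEMs and an MSP x sample abundance table:

* reaction richness — how many pool reactions are present in at least
  one detected species of a sample;
* relative reaction abundance — abundance-weighted reaction profiles,
  normalized to sum 1 per sample;
* reactobiome — reactions per 500 bacteria (CPF): the expected number of
  carriers of each reaction among 500 cells drawn by abundance;
* iRSE — individualized reaction-set enrichment: one-sided hypergeometric
  overrepresentation of pathway reaction sets in a sample's binary
  reaction vector, BH-adjusted;
* differential testing — per-reaction rank tests between sample groups
  with BH FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import GEM

#: The reactobiome normalization base: profiles are expressed per this
#: many bacterial cells.
CPF_SCALE = 500.0


@dataclass
class ReactionPool:
    """Ordered union of reaction ids over a GEM pool, with membership."""

    reactions: list[str]
    membership: pd.DataFrame  # reactions x models, int8 0/1

    @property
    def model_ids(self) -> list[str]:
        return list(self.membership.columns)

    def __len__(self) -> int:
        return len(self.reactions)


def build_reaction_pool(gems) -> ReactionPool:
    """Union the reaction sets of a GEM collection.

    Accepts GEMs, SpeciesGEMs, or a mapping model_id -> iterable of
    reaction ids. Duplicate model ids are an error.
    """
    items: list[tuple[str, list[str]]] = []
    if isinstance(gems, dict):
        items = [(mid, list(rxns)) for mid, rxns in gems.items()]
    else:
        for g in gems:
            gem: GEM = getattr(g, "gem", g)
            mid = getattr(g, "msp_id", None) or gem.model_id
            items.append((mid, gem.reaction_ids))
    if not items:
        raise ValueError("empty GEM pool")
    seen = set()
    for mid, _ in items:
        if mid in seen:
            raise ValueError(f"duplicate model id in pool: {mid!r}")
        seen.add(mid)
    pool: list[str] = []
    pool_set: set[str] = set()
    for _, rxns in items:
        for r in rxns:
            if r not in pool_set:
                pool.append(r)
                pool_set.add(r)
    membership = pd.DataFrame(0, index=pool, columns=[m for m, _ in items], dtype=np.int8)
    for mid, rxns in items:
        membership.loc[list(set(rxns)), mid] = 1
    return ReactionPool(reactions=pool, membership=membership)


def _detected(pool: ReactionPool, abundance: pd.DataFrame, detection: float) -> pd.DataFrame:
    missing = [m for m in abundance.index if m not in set(pool.model_ids)]
    if missing:
        raise KeyError(f"abundance rows without a pool model: {missing[:5]}")
    if (abundance.values < 0).any():
        raise ValueError("negative abundances")
    return abundance > detection


def reaction_richness(
    pool: ReactionPool, abundance: pd.DataFrame, detection: float = 0.0
) -> pd.Series:
    """Per-sample count of pool reactions carried by >= 1 detected MSP.

    Detection is abundance strictly above ``detection`` (default 0, no
    minimum-abundance filter). Richness is invariant under abundance
    rescaling and monotone under adding detected MSPs.
    """
    det = _detected(pool, abundance, detection)
    M = pool.membership[abundance.index.tolist()].values  # reactions x msps
    present = (M @ det.values) > 0
    return pd.Series(present.sum(axis=0), index=abundance.columns, name="reaction_richness")


def _weighted_profile(
    pool: ReactionPool, abundance: pd.DataFrame, detection: float
) -> pd.DataFrame:
    """M @ A' where A' renormalizes detected abundances to sum 1 per sample."""
    det = _detected(pool, abundance, detection)
    A = abundance.values * det.values
    colsum = A.sum(axis=0)
    empty = colsum <= 0
    if empty.any():
        warnings.warn(
            f"samples with no detected MSP: {list(abundance.columns[empty])}",
            stacklevel=3,
        )
    A = np.divide(A, np.where(empty, 1.0, colsum), where=~empty, out=np.zeros_like(A, dtype=float))
    M = pool.membership[abundance.index.tolist()].values
    return pd.DataFrame(M @ A, index=pool.reactions, columns=abundance.columns)


def reaction_abundance(
    pool: ReactionPool, abundance: pd.DataFrame, detection: float = 0.0
) -> pd.DataFrame:
    """Relative reaction-abundance profiles (columns sum to 1).

    Each detected MSP contributes its (per-sample renormalized)
    abundance to every reaction it carries; the column is then
    normalized to sum 1. Empty samples yield an all-zero column and a
    warning.
    """
    raw = _weighted_profile(pool, abundance, detection)
    colsum = raw.values.sum(axis=0)
    safe = np.where(colsum > 0, colsum, 1.0)
    return raw / safe


def reactobiome(
    pool: ReactionPool, abundance: pd.DataFrame, detection: float = 0.0
) -> pd.DataFrame:
    """Reactions per 500 bacteria (CPF) for each sample.

    ``CPF(r, s) = 500 * sum_i a'(i, s) * member(i, r)`` with a'(., s) the
    detected abundances renormalized to sum 1 — the expected number of
    carriers of reaction r among 500 cells drawn by abundance. Values lie
    in [0, 500]; a reaction carried by every detected MSP scores exactly
    500.
    """
    return CPF_SCALE * _weighted_profile(pool, abundance, detection)


# ---------------------------------------------------------------------------
# iRSE
# ---------------------------------------------------------------------------

def sample_presence(
    pool: ReactionPool, abundance: pd.DataFrame, detection: float = 0.0
) -> pd.DataFrame:
    """Binary reactions x samples presence matrix (the iRSE input vectors)."""
    det = _detected(pool, abundance, detection)
    M = pool.membership[abundance.index.tolist()].values
    return pd.DataFrame(
        ((M @ det.values) > 0).astype(np.int8), index=pool.reactions, columns=abundance.columns
    )


def irse(
    presence: pd.Series | np.ndarray,
    pathways: dict[str, set[str]],
    universe: list[str] | None = None,
) -> pd.DataFrame:
    """Individualized reaction-set enrichment for one sample.

    ``presence`` is a binary vector over the reaction universe (the pool;
    taken from the Series index unless ``universe`` is given). For each
    pathway with K universe reactions, n sample hits and overlap k, the
    one-sided upper-tail hypergeometric p-value P(X >= k),
    X ~ Hypergeom(N, K, n), is computed and BH-adjusted across tested
    pathways. Pathways with K = 0 are skipped and reported in the result
    attrs.
    """
    if isinstance(presence, pd.Series):
        universe = list(presence.index)
        vec = presence.values.astype(bool)
    else:
        if universe is None:
            raise ValueError("universe required when presence is a bare array")
        vec = np.asarray(presence, dtype=bool)
    uni = set(universe)
    N = len(universe)
    hits = {r for r, p in zip(universe, vec) if p}
    n = len(hits)
    rows, skipped = [], []
    for pid, members in pathways.items():
        in_uni = members & uni
        K = len(in_uni)
        if K == 0:
            skipped.append(pid)
            continue
        k = len(in_uni & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((pid, K, n, k, N, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["pathway_id", "K", "n", "k", "N", "p_value"]
    ).set_index("pathway_id")
    if len(out):
        out["q_value"] = stats.false_discovery_control(out["p_value"].values, method="bh")
    else:
        out["q_value"] = pd.Series(dtype=float)
    out.attrs["skipped_pathways"] = skipped
    return out


# ---------------------------------------------------------------------------
# group differences
# ---------------------------------------------------------------------------

def differential_reactions(
    cpf: pd.DataFrame,
    groups: pd.Series,
    case: str = "case",
    control: str = "control",
    paired: bool = False,
) -> pd.DataFrame:
    """Per-reaction rank test of CPF values between two sample groups.

    Default is the unpaired two-sample rank-sum (Mann-Whitney U)
    comparison between independent case and control samples; a paired
    signed-rank mode is available for matched designs (requires equal
    group sizes in pairing order). P-values are BH-adjusted; direction is
    the sign of (case median - control median). Reactions constant across
    all samples are flagged and assigned p = 1.
    """
    case_ids = [s for s in cpf.columns if groups.get(s) == case]
    ctrl_ids = [s for s in cpf.columns if groups.get(s) == control]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("need at least 2 samples per group")
    X = cpf[case_ids].values
    Y = cpf[ctrl_ids].values
    constant = (np.ptp(cpf[case_ids + ctrl_ids].values, axis=1) == 0)

    pvals = np.ones(len(cpf))
    statistic = np.full(len(cpf), np.nan)
    active = ~constant
    if active.any():
        if paired:
            if X.shape[1] != Y.shape[1]:
                raise ValueError("paired mode requires equal group sizes")
            res = stats.wilcoxon(X[active], Y[active], axis=1, zero_method="zsplit")
        else:
            res = stats.mannwhitneyu(X[active], Y[active], axis=1, alternative="two-sided")
        pvals[active] = res.pvalue
        statistic[active] = res.statistic
    med_case = np.median(X, axis=1)
    med_ctrl = np.median(Y, axis=1)
    out = pd.DataFrame(
        {
            "statistic": statistic,
            "p_value": np.clip(pvals, 0.0, 1.0),
            "q_value": stats.false_discovery_control(np.clip(pvals, 0.0, 1.0), method="bh"),
            "direction": np.sign(med_case - med_ctrl),
            "median_case": med_case,
            "median_control": med_ctrl,
            "constant": constant,
        },
        index=cpf.index,
    )
    return out
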