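"""Outlier exclusion and nonparametric stage comparison (Kruskal–Wallis + Dunn).

RPKM values across developmental stages are not normally distributed, so stage
effects are tested per bait with the tie-corrected Kruskal–Wallis H statistic
(chi-square with k−1 degrees of freedom); when the omnibus test rejects at
``alpha``, Dunn's rank-sum post-hoc compares every stage pair.  Before testing,
samples whose RPKM is extreme for several distinct baits at once — the
signature of an anomalously large initial RNA amount rather than a splicing
effect — are excluded by a robust median + c·MAD rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    posthoc_adjustment: str = "none"  # none | bonferroni | holm
    outlier_c: float = 5.0            # robust-deviation multiplier
    outlier_min_baits: int = 3        # distinct elevated baits needed to flag a sample

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.posthoc_adjustment not in {"none", "bonferroni", "holm"}:
            raise ValueError("posthoc_adjustment must be none, bonferroni or holm")


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float
    tie_correction: float  # divisor 1 − Σ(t³−t)/(N³−N)


def _ranks_and_ties(groups: Sequence[Sequence[float]]):
    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = sps.rankdata(values)  # midranks
    sizes = np.array([len(g) for g in groups])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rank_groups = [ranks[bounds[i] : bounds[i + 1]] for i in range(len(groups))]
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    return rank_groups, sizes, tie_sum


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    method: str = "chi2",
    n_resamples: int = 9999,
    seed: int = 0,
) -> KWResult:
    """Tie-corrected Kruskal–Wallis H over k groups.

    H = [12/(N(N+1)) Σ R_i²/n_i − 3(N+1)] / [1 − Σ(t³−t)/(N³−N)], with midranks
    for ties; p from the chi-square distribution with k−1 degrees of freedom
    (``method="chi2"``), or from a seeded permutation null (``"permutation"``,
    useful for the very small per-group sizes typical of this design).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    rank_groups, sizes, tie_sum = _ranks_and_ties(groups)
    n_total = int(sizes.sum())
    df = len(groups) - 1
    correction = 1.0 - tie_sum / (n_total**3 - n_total)
    if correction <= 0:  # every observation identical
        return KWResult(H=0.0, df=df, p=1.0, tie_correction=0.0)
    raw = (
        12.0 / (n_total * (n_total + 1))
        * sum(rg.sum() ** 2 / n for rg, n in zip(rank_groups, sizes))
        - 3.0 * (n_total + 1)
    )
    h = raw / correction
    if method == "chi2":
        p = float(sps.chi2.sf(h, df))
    elif method == "permutation":
        # permuting observations permutes their midranks, and the tie pattern
        # of the pooled sample is fixed, so the null is built directly from
        # permuted rank rows (fully vectorized)
        rng = np.random.default_rng(seed)
        ranks = np.concatenate(rank_groups)
        perms = rng.permuted(
            np.broadcast_to(ranks, (n_resamples, n_total)).copy(), axis=1
        )
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        stat = np.zeros(n_resamples)
        for i, n in enumerate(sizes):
            stat += perms[:, bounds[i] : bounds[i + 1]].sum(axis=1) ** 2 / n
        h_null = (12.0 / (n_total * (n_total + 1)) * stat - 3.0 * (n_total + 1))
        h_null /= correction
        p = float((np.sum(h_null >= h - 1e-12) + 1) / (n_resamples + 1))
    else:
        raise ValueError("method must be 'chi2' or 'permutation'")
    return KWResult(H=float(max(h, 0.0)), df=df, p=p, tie_correction=correction)


def _adjust(p_raw: np.ndarray, how: str) -> np.ndarray:
    m = p_raw.size
    if how == "none":
        return p_raw.copy()
    if how == "bonferroni":
        return np.minimum(p_raw * m, 1.0)
    # Holm step-down
    order = np.argsort(p_raw)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_raw[i])
        adj[i] = min(running, 1.0)
    return adj


@dataclass
class DunnResult:
    """Pairwise rank comparisons; one row per stage pair."""

    table: pd.DataFrame  # group_i, group_j, mean_rank_diff, z, p_raw, p_adj, significant

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.table[self.table["significant"]]
        return list(zip(sig["group_i"], sig["group_j"]))


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    cfg: StatConfig = StatConfig(),
    labels: Sequence[str] | None = None,
) -> DunnResult:
    """Dunn's z tests on all k(k−1)/2 group pairs using the pooled midranks.

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) · (1/n_i + 1/n_j)],
    two-sided p from the standard normal, adjusted per ``cfg``.
    """
    if any(len(g) == 0 for g in groups):
        raise ValueError("Dunn's test requires non-empty groups")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(groups))]
    rank_groups, sizes, tie_sum = _ranks_and_ties(groups)
    n_total = int(sizes.sum())
    mean_ranks = np.array([rg.mean() for rg in rank_groups])
    var_core = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            diff = mean_ranks[i] - mean_ranks[j]
            se = np.sqrt(var_core * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = diff / se if se > 0 else 0.0
            p = 2.0 * float(sps.norm.sf(abs(z)))
            rows.append((labels[i], labels[j], diff, z, p))
    df = pd.DataFrame(
        rows, columns=["group_i", "group_j", "mean_rank_diff", "z", "p_raw"]
    )
    df["p_adj"] = _adjust(df["p_raw"].to_numpy(), cfg.posthoc_adjustment)
    df["significant"] = df["p_adj"] < cfg.alpha
    return DunnResult(table=df)


def detect_outliers(
    table: pd.DataFrame, cfg: StatConfig = StatConfig()
) -> tuple[list[str], pd.DataFrame]:
    """Samples with anomalously high RPKM for several baits at once.

    Within each (structure, stage) group, a sample is flagged when its RPKM
    exceeds the group median + ``outlier_c``·MAD for at least
    ``outlier_min_baits`` distinct baits.  Groups with fewer than 3 samples are
    skipped (a warning row appears in the report).  The rule is deterministic
    and invariant to sample order.
    """
    required = {"sample_id", "structure", "stage", "bait_id", "rpkm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"RPKM table lacks columns: {sorted(missing)}")
    report_rows = []
    excluded = []
    for (structure, stage), grp in table.groupby(["structure", "stage"], sort=True):
        n_samples = grp["sample_id"].nunique()
        if n_samples < 3:
            report_rows.append(
                {"structure": structure, "stage": stage, "sample_id": "",
                 "n_elevated_baits": 0, "flagged": False,
                 "note": f"group skipped ({n_samples} samples < 3)"}
            )
            continue
        wide = grp.pivot_table(index="sample_id", columns="bait_id", values="rpkm")
        med = wide.median(axis=0)
        mad = (wide - med).abs().median(axis=0)
        elevated = wide.gt(med + cfg.outlier_c * mad, axis=1)
        counts = elevated.sum(axis=1)
        for sample_id in sorted(wide.index):
            n_elev = int(counts[sample_id])
            flagged = n_elev >= cfg.outlier_min_baits
            report_rows.append(
                {"structure": structure, "stage": stage, "sample_id": sample_id,
                 "n_elevated_baits": n_elev, "flagged": flagged, "note": ""}
            )
            if flagged:
                excluded.append(sample_id)
    return sorted(excluded), pd.DataFrame(report_rows)


@dataclass
class StageComparison:
    bait_id: str
    stages: list[str]
    group_sizes: list[int]
    kw: KWResult
    dunn: DunnResult | None  # None when the omnibus gate stayed closed


def compare_stages(
    table: pd.DataFrame,
    bait_id: str,
    cfg: StatConfig = StatConfig(),
    stage_order: Sequence[str] | None = None,
) -> StageComparison:
    """Omnibus + gated post-hoc for one bait across stages of one structure.

    Mirrors the study procedure: Kruskal–Wallis first, Dunn's pairwise tests
    only when the omnibus p falls below ``alpha``.  The table must already be
    restricted to a single structure with outliers removed.
    """
    if table["structure"].nunique() > 1:
        raise ValueError("restrict the table to one structure before comparing stages")
    sub = table[table["bait_id"] == bait_id]
    stages = (
        [s for s in stage_order if s in set(sub["stage"])]
        if stage_order is not None
        else sorted(sub["stage"].unique())
    )
    if len(stages) < 2:
        raise ValueError(f"bait {bait_id}: need >=2 stages, found {len(stages)}")
    groups = [sub.loc[sub["stage"] == s, "rpkm"].to_numpy() for s in stages]
    kw = kruskal_wallis(groups)
    dunn = dunn_posthoc(groups, cfg, labels=stages) if kw.p < cfg.alpha else None
    return StageComparison(
        bait_id=bait_id,
        stages=stages,
        group_sizes=[len(g) for g in groups],
        kw=kw,
        dunn=dunn,
    )
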