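"""TFBS over-representation against random control gene sets.

Per-gene site counts for the cluster are compared with counts for each of
``n`` random control gene sets (default 17) by a one-sided Mann-Whitney U
test (alternative: cluster counts stochastically greater). A matrix is
flagged over-represented only if p <= alpha against *every* control set —
a conjunction that makes the call conservative. The summary mirrors the
site / genes-with-site / percent reporting of the source analysis style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import GeneScanStatus, SiteHit

EXACT_MAX_N = 12  # pooled size at or below which the exact permutation law is used


def build_count_table(
    hits: Sequence[SiteHit],
    statuses: Sequence[GeneScanStatus],
    matrix_ids: Sequence[str],
) -> pd.DataFrame:
    """Gene x matrix site-count table over analysis-ready genes.

    Explicit zeros are kept for analysis-ready genes without hits for a
    matrix. A hit attributed to a non-analysis-ready gene is an error.
    """
    ready = [s.gene_id for s in statuses if s.status == "analysis_ready"]
    ready_set = set(ready)
    table = pd.DataFrame(0, index=ready, columns=list(matrix_ids), dtype=int)
    for hit in hits:
        if hit.gene_id not in ready_set:
            raise ValueError(
                f"hit for gene {hit.gene_id!r} which is not analysis-ready"
            )
        if hit.matrix_id not in table.columns:
            raise ValueError(f"hit for unknown matrix {hit.matrix_id!r}")
        table.loc[hit.gene_id, hit.matrix_id] += 1
    return table


@dataclass(frozen=True)
class ControlSets:
    """Random control gene sets, disjoint from the cluster."""

    sets: tuple[tuple[str, ...], ...]
    seed: int
    universe_size: int


def sample_control_sets(
    universe: Sequence[str],
    cluster_genes: Sequence[str],
    n_sets: int = 17,
    set_size: int | None = None,
    seed: int = 0,
) -> ControlSets:
    """Sample ``n_sets`` control sets uniformly from universe minus cluster.

    Each set is drawn without replacement (no duplicates within a set);
    different sets may overlap. ``set_size`` defaults to the cluster size.
    """
    cluster = set(cluster_genes)
    pool = [g for g in universe if g not in cluster]
    if set_size is None:
        set_size = len(cluster)
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    if len(pool) < set_size:
        raise ValueError(
            f"universe minus cluster has {len(pool)} genes, need {set_size}"
        )
    rng = np.random.default_rng(seed)
    sets = tuple(
        tuple(rng.choice(len(pool), size=set_size, replace=False))
        for _ in range(n_sets)
    )
    return ControlSets(
        sets=tuple(tuple(pool[i] for i in s) for s in sets),
        seed=seed,
        universe_size=len(universe),
    )


def mann_whitney_greater(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test: is x stochastically greater than y?

    U counts pairs with x_i > y_j plus half the ties. When the pooled size is
    at most 12 the p-value is exact (enumeration of all labelings, valid
    under ties); otherwise a normal approximation with tie-corrected variance
    and a 0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    u = _u_statistic(x, y)
    if nx + ny <= EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        idx = range(nx + ny)
        count = total = 0
        for chosen in combinations(idx, nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(chosen)] = True
            if _u_statistic(pooled[mask], pooled[~mask]) >= u - 1e-12:
                count += 1
            total += 1
        return u, count / total
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = nx + ny
    mean = nx * ny / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0 if u <= mean else 0.0
    z = (u - mean - 0.5) / math.sqrt(var)
    return u, float(stats.norm.sf(z))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


@dataclass
class OverrepResult:
    """Mann-Whitney outcomes for one matrix against every control set."""

    matrix_id: str
    u_stats: tuple[float, ...]
    p_values: tuple[float, ...]
    max_p: float
    over_represented: bool
    n_sites: int
    n_genes_with_site: int
    pct_genes: int


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded half-up to an integer (35/39 -> 90, 15/39 -> 38)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def test_overrepresentation(
    cluster_table: pd.DataFrame,
    control_tables: Sequence[pd.DataFrame],
    alpha: float = 0.05,
) -> list[OverrepResult]:
    """Flag matrices over-represented in the cluster versus every control set.

    For each matrix, per-gene cluster counts are tested against each control
    set's per-gene counts; the flag requires p <= alpha for all sets.
    Results are sorted by max p ascending (strongest conjunction first).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    results = []
    n_ready = len(cluster_table)
    for matrix_id in cluster_table.columns:
        x = cluster_table[matrix_id].to_numpy()
        us, ps = [], []
        for ctrl in control_tables:
            if matrix_id not in ctrl.columns:
                raise ValueError(f"matrix {matrix_id!r} missing from a control table")
            u, p = mann_whitney_greater(x, ctrl[matrix_id].to_numpy())
            us.append(u)
            ps.append(p)
        max_p = max(ps) if ps else 1.0
        n_with = int((x > 0).sum())
        results.append(
            OverrepResult(
                matrix_id=str(matrix_id),
                u_stats=tuple(us),
                p_values=tuple(ps),
                max_p=max_p,
                over_represented=bool(ps) and max_p <= alpha,
                n_sites=int(x.sum()),
                n_genes_with_site=n_with,
                pct_genes=round_half_up_percent(n_with, n_ready) if n_ready else 0,
            )
        )
    results.sort(key=lambda r: (r.max_p, r.matrix_id))
    return results


def summarize_tf_table(
    cluster_table: pd.DataFrame,
    results: Sequence[OverrepResult],
    only_flagged: bool = True,
) -> pd.DataFrame:
    """Summary rows per (flagged) matrix: sites, genes with sites, percent.

    Columns: matrix, n_sites, n_genes_with_site, pct_genes, genes (comma-
    separated analysis-ready genes with at least one site).
    """
    rows = []
    for res in results:
        if only_flagged and not res.over_represented:
            continue
        col = cluster_table[res.matrix_id]
        genes = list(col.index[col > 0])
        rows.append(
            {
                "matrix": res.matrix_id,
                "n_sites": res.n_sites,
                "n_genes_with_site": res.n_genes_with_site,
                "pct_genes": res.pct_genes,
                "max_p": res.max_p,
                "genes": ",".join(genes),
            }
        )
    return pd.DataFrame(
        rows, columns=["matrix", "n_sites", "n_genes_with_site", "pct_genes", "max_p", "genes"]
    )
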