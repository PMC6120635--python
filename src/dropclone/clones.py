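"""Clone enumeration, dropout explainability, and longitudinal comparison.

A clone is the set of cells sharing an identical genotype vector over the
analysis variant sites.  Allele dropout leaks cells from heterozygous
clones into spurious homozygous derivatives; ``ado_explainability`` tests
whether an observed small clone is consistent with pure dropout from a
parent clone, and ``deconvolve_ado`` inverts the per-site dropout channel
to produce dropout-corrected clone frequencies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype import GenotypeMatrix

DEFAULT_ALPHA = 0.05


@dataclass
class CloneTable:
    """Distinct genotype vectors with cell counts and frequencies.

    ``table`` is indexed by genotype tuple (dosage per analysis site, in
    site order) with columns label, count, frequency.  Frequencies are
    relative to genotyped, non-spike-in cells with no missing call at any
    analysis site; the excluded tallies are kept for reporting.
    """

    table: pd.DataFrame
    site_ids: list[str]
    n_excluded_missing: int = 0
    n_excluded_spikein: int = 0
    warning: str | None = None

    @property
    def n_cells(self) -> int:
        return int(self.table["count"].sum())

    def frequency_of(self, genotype: Sequence[int]) -> float:
        key = tuple(int(g) for g in genotype)
        if key in self.table.index:
            return float(self.table.loc[[key], "frequency"].iloc[0])
        return 0.0

    def count_of(self, genotype: Sequence[int]) -> int:
        key = tuple(int(g) for g in genotype)
        if key in self.table.index:
            return int(self.table.loc[[key], "count"].iloc[0])
        return 0


def clone_label(genotype: Sequence[int], site_ids: Sequence[str]) -> str:
    """Human-readable label: mutated sites joined by '+', '(hom)' for dosage 2."""
    parts = []
    for dose, sid in zip(genotype, site_ids):
        if dose == 1:
            parts.append(sid)
        elif dose == 2:
            parts.append(f"{sid}(hom)")
    return "+".join(parts) if parts else "WT"


def enumerate_clones(
    genotypes: GenotypeMatrix,
    analysis_site_ids: Sequence[str],
    spikein_cells: Sequence[str] = (),
) -> CloneTable:
    """Partition genotyped cells into clones by exact genotype vector.

    Spike-in cells are removed first; cells with a missing call at any
    analysis site are excluded and tallied.  Rows are ordered by
    descending count, ties broken by genotype vector.
    """
    site_ids = list(analysis_site_ids)
    calls = genotypes.calls[site_ids]
    spike = set(spikein_cells)
    keep = [c for c in calls.index if c not in spike]
    n_spike_excluded = len(calls) - len(keep)
    calls = calls.loc[keep]
    complete = calls.notna().all(axis=1)
    n_missing = int((~complete).sum())
    calls = calls[complete].astype(int)
    if calls.empty:
        table = pd.DataFrame(columns=["label", "count", "frequency"])
        table.index = pd.MultiIndex.from_tuples([], names=site_ids)
        return CloneTable(
            table, site_ids, n_missing, n_spike_excluded,
            warning="no genotyped cells after exclusions",
        )
    grouped = calls.groupby(site_ids).size()
    total = int(grouped.sum())
    keys = (
        [(k,) for k in grouped.index]
        if len(site_ids) == 1
        else list(grouped.index)
    )
    table = pd.DataFrame(
        {
            "label": [clone_label(k, site_ids) for k in keys],
            "count": grouped.to_numpy(),
            "frequency": grouped.to_numpy() / total,
        },
        index=pd.MultiIndex.from_tuples(keys, names=site_ids),
    )
    table = table.sort_values("count", ascending=False, kind="stable")
    return CloneTable(table, site_ids, n_missing, n_spike_excluded)


@dataclass
class ExplainabilityResult:
    """Binomial test of a candidate clone against dropout from a parent."""

    candidate: tuple[int, ...]
    parent: tuple[int, ...]
    converted_sites: list[str]
    per_cell_prob: float
    expected_count: float
    observed_count: int
    p_value: float
    explainable: bool


def ado_explainability(
    table: CloneTable,
    candidate: Sequence[int],
    parent: Sequence[int],
    locus_rates: Mapping[str, float] | float,
    alpha: float = DEFAULT_ALPHA,
) -> ExplainabilityResult:
    """Can the candidate clone be explained as dropout from the parent?

    The candidate must equal the parent except at k >= 1 sites where a
    parental het became hom; each such conversion has per-cell probability
    (locus rate)/2 for its specific direction (het->hom-ref and
    het->hom-alt split the locus-level rate evenly).  The candidate's
    observed count is tested against Binomial(parent count, q) with q the
    product over converted sites; p = P(X >= observed), and the clone is
    "explainable" when p >= alpha.
    """
    cand = tuple(int(g) for g in candidate)
    par = tuple(int(g) for g in parent)
    converted = []
    for sid, c, p in zip(table.site_ids, cand, par):
        if c == p:
            continue
        if p != 1 or c not in (0, 2):
            raise ValueError(
                f"candidate not derivable from parent by het->hom dropout at {sid}"
            )
        converted.append(sid)
    if not converted:
        raise ValueError("candidate genotype equals parent genotype")
    q = 1.0
    for sid in converted:
        rate = locus_rates[sid] if isinstance(locus_rates, Mapping) else locus_rates
        q *= rate / 2.0
    n_parent = table.count_of(par)
    observed = table.count_of(cand)
    expected = n_parent * q
    p_value = float(stats.binom.sf(observed - 1, n_parent, q)) if observed > 0 else 1.0
    return ExplainabilityResult(
        cand, par, converted, q, expected, observed, p_value, p_value >= alpha
    )


def largest_dominating_parent(
    table: CloneTable, candidate: Sequence[int]
) -> tuple[int, ...] | None:
    """Default parent: the largest clone derivable to the candidate by dropout."""
    cand = tuple(int(g) for g in candidate)
    best, best_count = None, -1
    for key in table.table.index:
        par = tuple(key) if isinstance(key, tuple) else (key,)
        if par == cand:
            continue
        ok = all(
            c == p or (p == 1 and c in (0, 2)) for c, p in zip(cand, par)
        )
        if ok and table.count_of(par) > best_count:
            best, best_count = par, table.count_of(par)
    return best


def _dropout_channel(rate: float) -> np.ndarray:
    """Per-site observation channel M[obs, true] under locus-level ADO ``rate``.

    True hom calls are unaffected; a true het is observed het with
    probability 1-r and hom-ref / hom-alt with probability r/2 each.
    """
    r = rate
    return np.array(
        [
            [1.0, r / 2.0, 0.0],
            [0.0, 1.0 - r, 0.0],
            [0.0, r / 2.0, 1.0],
        ]
    )


def _channel_matrix(rate: float, k: int) -> np.ndarray:
    channel = _dropout_channel(rate)
    M = np.array([[1.0]])
    for _ in range(k):
        M = np.kron(M, channel)
    return M


def _observed_vector(table: CloneTable) -> tuple[np.ndarray, dict[tuple, int]]:
    space = list(itertools.product((0, 1, 2), repeat=len(table.site_ids)))
    index_of = {g: i for i, g in enumerate(space)}
    observed = np.zeros(len(space))
    for key in table.table.index:
        g = tuple(key) if isinstance(key, tuple) else (key,)
        observed[index_of[g]] = table.count_of(g)
    return observed, index_of


def fit_ado_rate(table: CloneTable, bounds: tuple[float, float] = (0.0, 0.3)) -> float:
    """Locus-level dropout rate fitted from the clone table itself.

    Spurious homozygous derivatives of large heterozygous clones (e.g. a
    hom-alt vector one site away from a dominant het clone) are produced
    almost exclusively by dropout, so their mass pins the rate far more
    tightly than the handful of spike-in control cells does.  Profiles a
    multinomial likelihood over the dropout channel with the clone
    distribution solved by nonnegative least squares at each candidate
    rate.  Assumes true clones are heterozygous at their mutated sites.
    """
    observed, index_of = _observed_vector(table)
    total = observed.sum()
    if total == 0:
        raise ValueError("empty clone table")
    k = len(table.site_ids)
    # identifiability: restrict the underlying clones to het-carrier vectors
    # ({0,1}^k); otherwise every homozygous observation is "explained" by a
    # matching true clone and the likelihood degenerates to rate 0
    het_cols = [i for g, i in index_of.items() if all(d in (0, 1) for d in g)]

    def nll(rate: float) -> float:
        M = _channel_matrix(rate, k)[:, het_cols]
        f, _ = optimize.nnls(M, observed / total)
        p = M @ f
        p = np.clip(p, 1e-12, None)
        p /= p.sum()
        return -float(observed @ np.log(p))

    res = optimize.minimize_scalar(
        nll, bounds=bounds, method="bounded", options={"xatol": 1e-5}
    )
    return float(res.x)


def deconvolve_ado(table: CloneTable, ado_rate: float | None = None) -> CloneTable:
    """Dropout-corrected clone table.

    Builds the full observation channel over genotype space (Kronecker
    product of per-site channels), solves a nonnegative least-squares
    system for the underlying clone distribution, and renormalises.
    Corrects the attenuation of heterozygous clones (a k-het clone is
    observed intact with probability (1-r)^k) and reassigns the leaked
    mass from spurious homozygous derivatives.  With ``ado_rate=None``
    the rate is fitted from the table by ``fit_ado_rate``.
    """
    k = len(table.site_ids)
    if k == 0 or table.n_cells == 0:
        return table
    if ado_rate is None:
        ado_rate = fit_ado_rate(table)
    M = _channel_matrix(ado_rate, k)
    observed, index_of = _observed_vector(table)
    solution, _ = optimize.nnls(M, observed)
    total = solution.sum()
    corrected = solution / total if total > 0 else solution
    rows = [
        (g, clone_label(g, table.site_ids), corrected[i])
        for g, i in index_of.items()
        if corrected[i] > 1e-9
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    out = pd.DataFrame(
        {
            "label": [r[1] for r in rows],
            "count": [int(round(r[2] * table.n_cells)) for r in rows],
            "frequency": [r[2] for r in rows],
        },
        index=pd.MultiIndex.from_tuples([r[0] for r in rows], names=table.site_ids),
    )
    return CloneTable(
        out, table.site_ids, table.n_excluded_missing, table.n_excluded_spikein
    )


def merge_clone_tables(tables: Sequence[CloneTable]) -> CloneTable:
    """Pool replicate runs: counts summed by genotype, frequencies recomputed."""
    if not tables:
        raise ValueError("no tables to merge")
    site_ids = tables[0].site_ids
    if any(t.site_ids != site_ids for t in tables):
        raise ValueError("clone tables cover different analysis sites")
    counts: dict[tuple, int] = {}
    for t in tables:
        for key in t.table.index:
            g = tuple(key) if isinstance(key, tuple) else (key,)
            counts[g] = counts.get(g, 0) + t.count_of(g)
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    out = pd.DataFrame(
        {
            "label": [clone_label(g, site_ids) for g, _ in rows],
            "count": [n for _, n in rows],
            "frequency": [n / total for _, n in rows] if total else 0.0,
        },
        index=pd.MultiIndex.from_tuples([g for g, _ in rows], names=site_ids),
    )
    return CloneTable(
        out,
        site_ids,
        sum(t.n_excluded_missing for t in tables),
        sum(t.n_excluded_spikein for t in tables),
    )


def compare_timepoints(table1: CloneTable, table2: CloneTable) -> pd.DataFrame:
    """Outer-join clone frequencies of two timepoints; absent clones get 0.

    Returns a frame indexed by genotype tuple with columns label, freq1,
    freq2, delta (freq2 - freq1), present1, present2.
    """
    if table1.site_ids != table2.site_ids:
        raise ValueError("clone tables cover different analysis sites")
    f1 = table1.table["frequency"]
    f2 = table2.table["frequency"]
    joined = pd.concat({"freq1": f1, "freq2": f2}, axis=1).fillna(0.0)
    labels = {}
    for t in (table1, table2):
        for key in t.table.index:
            g = tuple(key) if isinstance(key, tuple) else (key,)
            labels[g] = t.table.loc[[key], "label"].iloc[0]
    joined["label"] = [
        labels[tuple(k) if isinstance(k, tuple) else (k,)] for k in joined.index
    ]
    joined["delta"] = joined["freq2"] - joined["freq1"]
    joined["present1"] = joined["freq1"] > 0
    joined["present2"] = joined["freq2"] > 0
    return joined.sort_values("delta", ascending=False, kind="stable")[
        ["label", "freq1", "freq2", "delta", "present1", "present2"]
    ]


def order_for_heatmap(
    genotypes: GenotypeMatrix, site_ids: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Deterministic heat-map ordering.

    Cells are sorted by genotype vector, lexicographic with hom-alt > het
    > hom-ref (missing sorts lowest); ties broken by cell id.  Sites keep
    panel order.  Cells of one clone land in a contiguous block.
    """
    sites = list(site_ids)
    calls = genotypes.calls[sites]

    def key(cell: str) -> tuple:
        row = calls.loc[cell]
        return tuple(-1.0 if pd.isna(v) else -float(v) for v in row) + (cell,)

    ordered = sorted(calls.index, key=key)
    return ordered, sites
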