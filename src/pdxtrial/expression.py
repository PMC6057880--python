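"""Expression normalization, ABCB1-style expression binning and a
permutation-based two-group differential-expression test.

Counts are normalized with median-of-ratios size factors (the DESeq-style
estimator): for each sample, the factor is the median over
all-nonzero genes of that sample's count divided by the gene's geometric
mean across samples. Normalized expression of a marker gene is binned
into the trial's three categories:

* low  : 0-99 normalized reads
* mid  : 100-1000 normalized reads (1000 inclusive)
* high : >1000 normalized reads

The two-group test works in log2(normalized + 1) space with per-batch
mean-centering as the batch adjustment; the p-value comes from a
two-sided permutation test of the group labels stratified by batch
(exact enumeration whenever the number of distinct label assignments is
within the permutation budget) and q-values from Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

BIN_LOW = "low"
BIN_MID = "mid"
BIN_HIGH = "high"

#: Bin edges on normalized reads: < LOW_EDGE -> low, <= HIGH_EDGE -> mid.
LOW_EDGE = 100.0
HIGH_EDGE = 1000.0


def filter_unexpressed(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero counts across all samples."""
    return counts.loc[counts.sum(axis=1) > 0]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one positive factor per sample.

    Only genes with nonzero counts in every sample contribute ratios;
    absence of any such gene is an error.
    """
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    nonzero = counts.loc[(counts > 0).all(axis=1)]
    if nonzero.empty:
        raise ValueError("no gene has nonzero counts in all samples; "
                         "size factors are undefined")
    log_geomean = np.log(nonzero).mean(axis=1)
    ratios = np.log(nonzero).sub(log_geomean, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts divided by their sample's size factor."""
    return counts.div(size_factors(counts), axis=1)


def bin_expression(normalized_reads: float) -> str:
    """Bin one normalized expression value into low / mid / high."""
    if normalized_reads < 0:
        raise ValueError("normalized reads must be non-negative")
    if normalized_reads < LOW_EDGE:
        return BIN_LOW
    if normalized_reads <= HIGH_EDGE:
        return BIN_MID
    return BIN_HIGH


def bin_gene(counts: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Normalize a count matrix and bin one gene across samples.

    Returns a table (sample_id, normalized_reads, bin).
    """
    norm = normalize(filter_unexpressed(counts))
    if gene not in norm.index:
        raise KeyError(f"gene {gene!r} not in matrix (or unexpressed)")
    vals = norm.loc[gene]
    return pd.DataFrame({
        "sample_id": vals.index,
        "normalized_reads": vals.values,
        "bin": [bin_expression(v) for v in vals.values],
    })


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def _batch_center(logmat: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Per-batch mean-centering in log space (removeBatchEffect-style)."""
    out = logmat.copy()
    grand = logmat.mean(axis=1)
    for b in batch.unique():
        cols = batch.index[batch == b]
        out[cols] = logmat[cols].sub(logmat[cols].mean(axis=1), axis=0) \
                                .add(grand, axis=0)
    return out


def de_test(counts: pd.DataFrame,
            groups: pd.Series,
            group_a: str,
            group_b: str,
            batch: pd.Series | None = None,
            n_permutations: int = 10_000,
            seed: int = 0) -> pd.DataFrame:
    """Two-group differential expression by stratified permutation.

    Parameters
    ----------
    counts
        Raw gene x sample count matrix.
    groups
        Sample -> group label; only samples labeled ``group_a`` or
        ``group_b`` enter the test (>= 2 each).
    batch
        Optional sample -> batch label. Permutations shuffle group labels
        within each batch; a batch containing only one of the two groups
        makes the stratified permutation degenerate and is rejected.
    n_permutations
        Monte-Carlo budget. When the exact number of distinct stratified
        assignments is at most this budget, all are enumerated and the
        p-value is exact.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2fc`` (group_a minus
    group_b, batch-adjusted), ``p`` and ``q`` (Benjamini-Hochberg).
    """
    samples = [s for s in counts.columns if groups.get(s) in (group_a, group_b)]
    lab = groups.loc[samples]
    if (lab == group_a).sum() < 2 or (lab == group_b).sum() < 2:
        raise ValueError("each group needs at least two samples")
    sub = counts[samples]
    if batch is None:
        batch = pd.Series("batch0", index=samples)
    else:
        batch = batch.loc[samples]
        for b in batch.unique():
            in_b = lab[batch == b]
            if in_b.nunique() < 2:
                raise ValueError(
                    f"batch {b!r} contains samples from only one group; "
                    "stratified permutation is impossible")

    sub = filter_unexpressed(sub)
    logmat = np.log2(normalize(sub) + 1.0)
    adj = _batch_center(logmat, batch)

    a_mask = (lab == group_a).values
    X = adj.values  # genes x samples

    def stat(mask: np.ndarray) -> np.ndarray:
        return X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1)

    obs = stat(a_mask)

    # enumerate within-batch label assignments exactly when affordable
    strata = [np.flatnonzero((batch == b).values) for b in batch.unique()]
    n_exact = 1
    for idx in strata:
        n_exact *= math.comb(len(idx), int(a_mask[idx].sum()))
        if n_exact > n_permutations:
            break

    exceed = np.zeros(X.shape[0], dtype=int)
    if n_exact <= n_permutations:
        per_stratum = []
        for idx in strata:
            k = int(a_mask[idx].sum())
            per_stratum.append([frozenset(c) for c in
                                itertools.combinations(idx, k)])
        total = 0
        for combo in itertools.product(*per_stratum):
            mask = np.zeros(len(samples), dtype=bool)
            for chosen in combo:
                mask[list(chosen)] = True
            exceed += np.abs(stat(mask)) >= np.abs(obs) - 1e-12
            total += 1
        p = exceed / total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_permutations):
            mask = np.zeros(len(samples), dtype=bool)
            for idx in strata:
                k = int(a_mask[idx].sum())
                mask[rng.choice(idx, size=k, replace=False)] = True
            exceed += np.abs(stat(mask)) >= np.abs(obs) - 1e-12
        p = (1 + exceed) / (1 + n_permutations)

    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": obs, "p": p, "q": q}, index=adj.index)


def volcano(de_results: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Volcano table: (log2fc, -log10 p) with a significance flag at the
    given q cutoff."""
    out = de_results.copy()
    out["neg_log10_p"] = -np.log10(out["p"].clip(lower=np.finfo(float).tiny))
    out["significant"] = out["q"] <= q_threshold
    return out


def plot_volcano(volcano_table: pd.DataFrame, path: str | None = None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sig = volcano_table["significant"]
    ax.scatter(volcano_table.loc[~sig, "log2fc"],
               volcano_table.loc[~sig, "neg_log10_p"], s=8, c="grey")
    ax.scatter(volcano_table.loc[sig, "log2fc"],
               volcano_table.loc[sig, "neg_log10_p"], s=10, c="#c0392b")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
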