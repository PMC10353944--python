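"""Single-cell gene-set signature scoring and accessibility/expression deciles.

The adhesion/migration signature of a cell is the cumulative expression of a
gene set (e.g. the GO "cell adhesion" list, GO:0007155): expression values
are log-normalized counts per 10,000 transcripts (CP10K, natural log), and
the per-cell score sums those values over the genes of the set.  Group
comparisons use the two-tailed Mann-Whitney test; young populations can be
downsampled to old population sizes before comparison so that group sizes
match.  A separate helper bins gene promoters into accessibility deciles and
reports the expression distribution per decile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import GroupComparison, mann_whitney_two_tailed

__all__ = [
    "lognormalize_cp10k",
    "signature_score",
    "SignatureScores",
    "downsample_group",
    "compare_signature",
    "decile_association",
    "bimodality_report",
    "read_gmt",
]


def lognormalize_cp10k(counts, on_zero_total="error") -> pd.DataFrame:
    """Log-normalize raw counts to counts per 10,000 transcripts.

    value = ln(1 + 1e4 * c / cell_total), cells as rows and genes as columns.
    Cells with zero total counts either raise (default) or are dropped
    (``on_zero_total="drop"``).
    """
    counts = pd.DataFrame(counts)
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    totals = arr.sum(axis=1)
    zero = totals == 0
    if zero.any():
        if on_zero_total == "drop":
            counts = counts.loc[~zero]
            arr = arr[~zero]
            totals = totals[~zero]
        else:
            raise ValueError(
                f"{int(zero.sum())} cell(s) have zero total counts"
            )
    values = np.log1p(1e4 * arr / totals[:, None])
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


@dataclass
class SignatureScores:
    """Per-cell cumulative gene-set score with bookkeeping.

    ``scores`` indexes cells; ``genes_used`` are the set members found in the
    matrix; ``n_missing`` counts set members absent from the matrix (dropped,
    but reported rather than silently ignored).
    """

    scores: pd.Series
    genes_used: tuple
    n_missing: int


def signature_score(matrix, gene_set) -> SignatureScores:
    """Sum of log-normalized expression over a gene set, per cell.

    ``matrix`` is cells x genes (already normalized); genes in the set but
    absent from the matrix are dropped with a reported count.  An empty
    intersection is an error — a score of 0 for every cell would be
    indistinguishable from genuine silence.
    """
    matrix = pd.DataFrame(matrix)
    genes = list(dict.fromkeys(gene_set))  # preserve order, drop duplicates
    present = [g for g in genes if g in matrix.columns]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    scores = matrix[present].sum(axis=1).rename("signature_score")
    return SignatureScores(scores, tuple(present), len(genes) - len(present))


def downsample_group(index, target_n, seed) -> pd.Index:
    """Uniform sample of ``target_n`` cells without replacement, seeded.

    Used to downsample a young population to the size of the matched old
    population before score comparisons.
    """
    index = pd.Index(index)
    if target_n > len(index):
        raise ValueError(
            f"target_n={target_n} exceeds group size {len(index)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(index), size=target_n, replace=False)
    return index[np.sort(chosen)]


def compare_signature(scores, groups, animals=None) -> dict:
    """Compare per-cell signature scores between two groups.

    Two-tailed Mann-Whitney on per-cell scores; when ``animals`` is given a
    second comparison on per-animal mean scores is reported as well.
    """
    scores = pd.Series(np.asarray(scores, dtype=float))
    groups = pd.Series(np.asarray(groups), index=scores.index)
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    g1, g2 = labels
    out = {
        "groups": (g1, g2),
        "per_cell": mann_whitney_two_tailed(
            scores[groups == g1], scores[groups == g2]
        ),
        "means": {
            g1: float(scores[groups == g1].mean()),
            g2: float(scores[groups == g2].mean()),
        },
    }
    if animals is not None:
        animals = pd.Series(np.asarray(animals), index=scores.index)
        df = pd.DataFrame({"score": scores, "group": groups, "animal": animals})
        am = df.groupby(["group", "animal"])["score"].mean().reset_index()
        out["per_animal"] = mann_whitney_two_tailed(
            am.loc[am["group"] == g1, "score"],
            am.loc[am["group"] == g2, "score"],
        )
    return out


def decile_association(accessibility, expression, n_bins=10) -> pd.DataFrame:
    """Bin genes into promoter-accessibility deciles; report expression.

    Both inputs are Series indexed by gene; only shared genes are used.
    Genes are ranked by accessibility (stable order on ties) and split into
    ``n_bins`` equal-count bins (sizes differ by at most 1); the returned
    frame has one row per gene with its decile (1 = least accessible),
    accessibility, and expression.  Use ``.groupby("decile")`` for the
    per-decile distributions.
    """
    accessibility = pd.Series(accessibility).astype(float)
    expression = pd.Series(expression).astype(float)
    shared = accessibility.index.intersection(expression.index)
    if len(shared) < n_bins:
        raise ValueError(
            f"need >= {n_bins} shared genes, got {len(shared)}"
        )
    acc = accessibility.loc[shared]
    order = np.argsort(acc.to_numpy(), kind="stable")
    deciles = np.empty(len(shared), dtype=int)
    for i, chunk in enumerate(np.array_split(order, n_bins), start=1):
        deciles[chunk] = i
    return pd.DataFrame(
        {
            "gene": shared,
            "decile": deciles,
            "accessibility": acc.to_numpy(),
            "expression": expression.loc[shared].to_numpy(),
        }
    ).reset_index(drop=True)


def bimodality_report(values, n_hist_bins=30) -> dict:
    """Descriptive bimodality summary of a score distribution.

    Reports Sarle's bimodality coefficient ((skew^2 + 1) / kurtosis, > 5/9
    suggesting bimodality) alongside a histogram summary.  Purely
    descriptive — no calibrated test is claimed.
    """
    from scipy.stats import kurtosis, skew

    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValueError("need >= 4 values")
    g = skew(values)
    k = kurtosis(values, fisher=False)
    hist, edges = np.histogram(values, bins=n_hist_bins)
    return {
        "bimodality_coefficient": float((g**2 + 1) / k) if k > 0 else float("nan"),
        "skewness": float(g),
        "kurtosis": float(k),
        "histogram": hist.tolist(),
        "bin_edges": edges.tolist(),
        "n": int(values.size),
    }


def read_gmt(path) -> dict:
    """Read gene sets from a GMT file: name, description, then genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
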