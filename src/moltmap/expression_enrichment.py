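"""Tissue enrichment, secretome partition and binned abundance statistics.

A gene is tissue-enriched when its TPM in the target tissue exceeds a fold
threshold against every other tissue (strict reading; a mean-of-others mode is
available) and clears a minimum abundance.  The secretome is the set of genes
whose signal-peptide score reaches the 0.45 cutoff.  Binned profiles report,
per hourly bin, the mean transcript abundance of the genes peaking in that
bin with a one-sample Student's t-test against the global average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from moltmap.errors import InputError

logger = logging.getLogger(__name__)

SIGNALP_CUTOFF = 0.45
ENRICH_FOLD = 1.5
MIN_TPM = 25.0
N_BINS = 8


def classify_tissue_enriched(
    matrix: pd.DataFrame,
    target: str,
    fold: float = ENRICH_FOLD,
    min_tpm: float = MIN_TPM,
    mode: str = "max",
) -> set[str]:
    """Genes enriched in ``target``: fold over other tissues and >= min_tpm.

    ``matrix`` has genes as rows and tissues as columns (TPM).  ``mode='max'``
    requires the fold against every other tissue (i.e. against their maximum);
    ``mode='mean'`` compares against the mean of the other tissues.
    """
    if target not in matrix.columns:
        raise InputError(f"classify_tissue_enriched: tissue {target!r} not in matrix")
    if matrix.shape[1] < 2:
        raise InputError("classify_tissue_enriched: need at least two tissues")
    if (matrix.to_numpy() < 0).any():
        raise InputError("classify_tissue_enriched: negative TPM values")
    tgt = matrix[target]
    others = matrix.drop(columns=[target])
    ref = others.max(axis=1) if mode == "max" else others.mean(axis=1)
    if mode not in ("max", "mean"):
        raise InputError(f"classify_tissue_enriched: unknown mode {mode!r}")
    hit = (tgt > fold * ref) & (tgt >= min_tpm)
    return set(matrix.index[hit].astype(str))


def partition_secretome(
    genes: list[str] | pd.Index,
    signalp_scores: pd.Series | dict[str, float],
    cutoff: float = SIGNALP_CUTOFF,
) -> tuple[set[str], set[str]]:
    """Split genes into (secreted, non-secreted) by signal-peptide score.

    The cutoff is inclusive (score >= 0.45 is secreted).  Genes without a
    score are placed in the non-secreted set with a warning.
    """
    scores = pd.Series(signalp_scores)
    secreted: set[str] = set()
    non_secreted: set[str] = set()
    missing = 0
    for g in map(str, genes):
        s = scores.get(g)
        if s is None or not np.isfinite(s):
            missing += 1
            non_secreted.add(g)
        elif s >= cutoff:
            secreted.add(g)
        else:
            non_secreted.add(g)
    if missing:
        logger.warning(
            "partition_secretome: %d genes without a score -> non-secreted", missing
        )
    return secreted, non_secreted


@dataclass
class BinProfile:
    """Per-bin abundance summary with one-sample tests vs the global mean."""

    table: pd.DataFrame  # columns: bin, n, mean, sem, p
    global_mean: float


def bin_abundance_profile(
    gene_set: set[str] | list[str],
    expression: pd.Series | dict[str, float],
    peak_hours: pd.Series | dict[str, int],
    n_bins: int = N_BINS,
    global_mean: float | None = None,
) -> BinProfile:
    """Mean transcript abundance per hourly bin over a gene set.

    ``expression`` gives each gene's TPM in the tissue of interest and
    ``peak_hours`` its hourly bin.  Each bin's values are tested against the
    global mean with a two-tailed one-sample Student's t-test.  By default the
    global mean is that of the supplied gene set; pass ``global_mean`` to test
    against a wider reference (e.g. the full oscillating set's average).
    """
    expr = pd.Series(expression)
    hours = pd.Series(peak_hours)
    genes = [str(g) for g in gene_set]
    missing = [g for g in genes if g not in expr.index or g not in hours.index]
    if missing:
        raise InputError(
            f"bin_abundance_profile: {len(missing)} genes lack expression or peak_hour"
            f" (e.g. {missing[:3]})"
        )
    values = expr.loc[genes].to_numpy(dtype=float)
    bins = hours.loc[genes].to_numpy(dtype=int)
    gmean = float(values.mean()) if global_mean is None else float(global_mean)

    rows = []
    for b in range(1, n_bins + 1):
        v = values[bins == b]
        n = len(v)
        if n == 0:
            logger.warning("bin_abundance_profile: bin %d is empty", b)
            rows.append((b, 0, np.nan, np.nan, 1.0))
            continue
        mean = v.mean()
        sem = v.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        if n > 1 and v.std(ddof=1) > 0:
            p = float(stats.ttest_1samp(v, popmean=gmean).pvalue)
        else:
            p = 1.0
        rows.append((b, n, mean, sem, p))
    table = pd.DataFrame(rows, columns=["bin", "n", "mean", "sem", "p"])
    return BinProfile(table, gmean)


def cluster_summary(
    cluster_matrix: pd.DataFrame,
    grouping: dict[str, list[str]],
    mode: str = "average",
    gene_set: list[str] | None = None,
) -> pd.DataFrame:
    """Summarize cell clusters into cell types (genes x cell types).

    ``mode='average'`` takes the per-gene mean over the listed clusters.
    ``mode='max-average'`` copies the values of the single cluster whose
    average over ``gene_set`` (default: all genes) is highest — the cluster is
    chosen once per cell type, not per gene.
    """
    if mode not in ("average", "max-average"):
        raise InputError(f"cluster_summary: unknown mode {mode!r}")
    out = {}
    genes = cluster_matrix.index if gene_set is None else [g for g in gene_set]
    for cell_type, clusters in grouping.items():
        unknown = [c for c in clusters if c not in cluster_matrix.columns]
        if unknown:
            raise InputError(
                f"cluster_summary: unknown clusters {unknown} for {cell_type!r}"
            )
        sub = cluster_matrix[clusters]
        if mode == "average":
            out[cell_type] = sub.mean(axis=1)
        else:
            best = sub.loc[genes].mean(axis=0).idxmax()
            out[cell_type] = sub[best]
    return pd.DataFrame(out)


def lagged_bin_test(
    bin_values: dict[int, np.ndarray] | pd.Series,
    lag: int = 2,
    alpha: float = 0.01,
    n_bins: int = N_BINS,
) -> dict[int, bool]:
    """Flag bins significantly above the bin ``lag`` hours earlier.

    ``bin_values`` maps each bin (1..8) to the per-gene expression values of
    the genes peaking in it.  Bin ``b`` is flagged when a one-sided two-sample
    Student's t-test of bin ``b`` against bin ``b-lag`` gives p < ``alpha``.
    Bins without a comparator, or with fewer than two genes on either side,
    are never flagged.
    """
    if isinstance(bin_values, pd.Series):
        bin_values = {int(b): np.asarray(v) for b, v in bin_values.items()}
    flags: dict[int, bool] = {}
    for b in range(1, n_bins + 1):
        flags[b] = False
        if b - lag < 1 or b not in bin_values or (b - lag) not in bin_values:
            continue
        cur = np.asarray(bin_values[b], dtype=float)
        prev = np.asarray(bin_values[b - lag], dtype=float)
        if len(cur) < 2 or len(prev) < 2:
            logger.warning("lagged_bin_test: bin %d or %d has <2 genes", b, b - lag)
            continue
        if cur.std(ddof=1) == 0 and prev.std(ddof=1) == 0:
            continue
        res = stats.ttest_ind(cur, prev, equal_var=True, alternative="greater")
        flags[b] = bool(res.pvalue < alpha)
    return flags


def network_density(
    node_set: set[str] | list[str], edge_list: list[tuple[str, str]]
) -> tuple[float, int, int]:
    """Edges-per-node of an ingested interaction network.

    Returns ``(density, n_edges, n_nodes)`` where density = edges within the
    node set / number of nodes.  Edges touching unknown nodes are dropped with
    a warning; duplicate and self edges are ignored.
    """
    nodes = {str(n) for n in node_set}
    if not nodes:
        raise InputError("network_density: empty node set")
    kept = set()
    dropped = 0
    for a, b in edge_list:
        a, b = str(a), str(b)
        if a in nodes and b in nodes and a != b:
            kept.add(frozenset((a, b)))
        else:
            dropped += 1
    if dropped:
        logger.warning("network_density: dropped %d edges outside the node set", dropped)
    return len(kept) / len(nodes), len(kept), len(nodes)


def summarize_secretome_strata(
    oscillating_enriched: set[str],
    oscillating_other: set[str],
    non_oscillating: set[str],
    signalp_scores: pd.Series | dict[str, float],
    cutoff: float = SIGNALP_CUTOFF,
) -> pd.DataFrame:
    """Signal-peptide fractions for the three map strata.

    Strata must be disjoint; together they cover the genome list.  Returns a
    table with columns stratum, n, n_secreted, fraction.
    """
    strata = {
        "oscillating_enriched": set(map(str, oscillating_enriched)),
        "oscillating_other": set(map(str, oscillating_other)),
        "non_oscillating": set(map(str, non_oscillating)),
    }
    names = list(strata)
    for i, a in enumerate(names):
        if not strata[a]:
            raise InputError(f"summarize_secretome_strata: stratum {a!r} is empty")
        for b in names[i + 1 :]:
            overlap = strata[a] & strata[b]
            if overlap:
                raise InputError(
                    f"summarize_secretome_strata: strata {a!r} and {b!r} overlap"
                    f" ({len(overlap)} genes)"
                )
    rows = []
    for name, genes in strata.items():
        secreted, _ = partition_secretome(sorted(genes), signalp_scores, cutoff)
        rows.append((name, len(genes), len(secreted), len(secreted) / len(genes)))
    return pd.DataFrame(rows, columns=["stratum", "n", "n_secreted", "fraction"])
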