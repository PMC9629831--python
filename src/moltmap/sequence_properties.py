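"""Low-complexity and disorder quantification of protein sequences.

The centrepiece is a SEG-style low-complexity detector: length-12 windows of
Shannon entropy trigger at K2 <= 2.2 bits, extend while K2 <= 2.5 bits, and
each merged candidate region is refined to the subsequence of minimal
compositional probability P0.  Disorder tracks (per-residue probabilities
from an external predictor) are reduced to intrinsically disordered regions:
maximal runs of 30 or more residues at probability >= 0.5.  The module also
aggregates ingested predictor scores, residue compositions, and
transcript-weighted temporal property waves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd
from scipy import stats

from moltmap.errors import InputError
from moltmap.synthetic_data import AMINO_ACIDS, ProteinRecord

logger = logging.getLogger(__name__)

SEG_WINDOW = 12
SEG_LOWCUT = 2.2
SEG_HIGHCUT = 2.5
IDR_MIN_RUN = 30
IDR_PROB_THRESHOLD = 0.5
SIGNAL_PEPTIDE_LEN = 20
PLAAC_OFFSET = 60.0

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_LOG20 = log(20.0)
_TIE_TOL = 1e-9


def window_entropy(window: str) -> float:
    """Shannon entropy K2 (bits) of a residue window.

    ``K2 = -sum_i (n_i/L) * log2(n_i/L)`` over the residues present.
    """
    if not window:
        raise InputError("window_entropy: empty window")
    counts = np.zeros(20, dtype=float)
    for c in window:
        i = _AA_INDEX.get(c)
        if i is None:
            raise InputError(f"window_entropy: non-canonical residue {c!r}")
        counts[i] += 1
    p = counts[counts > 0] / len(window)
    return float(-(p * np.log2(p)).sum()) + 0.0


@dataclass(frozen=True)
class LcrSegment:
    """One low-complexity segment, 0-based half-open residue coordinates."""

    start: int
    end: int
    trigger_entropy: float

    def __len__(self) -> int:
        return self.end - self.start


def _encode(seq: str, on_noncanonical: str) -> np.ndarray:
    """Residue indices; non-canonical letters become -1 (skip) or raise."""
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        j = _AA_INDEX.get(c)
        if j is None:
            if on_noncanonical == "error":
                raise InputError(
                    f"seg_low_complexity: non-canonical residue {c!r} at position {i}"
                )
            out[i] = -1
        else:
            out[i] = j
    return out


def _window_entropies(idx: np.ndarray, W: int) -> np.ndarray:
    """K2 of every length-W window; windows with skipped residues get +inf."""
    L = len(idx)
    n_win = L - W + 1
    ent = np.empty(n_win)
    counts = np.zeros(21, dtype=np.int64)  # slot 20 counts skipped residues
    nlogn = np.zeros(W + 1)
    for k in range(2, W + 1):
        nlogn[k] = k * np.log2(k)
    clipped = np.where(idx < 0, 20, idx)
    for j in clipped[:W]:
        counts[j] += 1
    for i in range(n_win):
        if counts[20] > 0:
            ent[i] = np.inf
        else:
            ent[i] = np.log2(W) - nlogn[counts[:20]].sum() / W
        if i + 1 < n_win:
            counts[clipped[i]] -= 1
            counts[clipped[i + W]] += 1
    return ent


def _log_p0(counts: np.ndarray, L: int) -> float:
    """log of the compositional probability P0 = Omega * F / 20^L.

    ``Omega = L!/prod n_i!`` counts the orderings of the composition and
    ``F = 20!/prod_k r_k!`` the compositions equivalent under residue
    relabelling, with ``r_k`` the number of the 20 residue types occurring
    exactly k times (k = 0 included).
    """
    log_omega = lgamma(L + 1) - sum(lgamma(c + 1) for c in counts if c)
    r = np.bincount(counts, minlength=L + 1)
    log_f = lgamma(21.0) - sum(lgamma(rk + 1) for rk in r if rk > 1)
    return log_omega + log_f - L * _LOG20


def _min_p0_subsequence(idx: np.ndarray, s: int, e: int) -> tuple[int, int]:
    """Subsequence of ``idx[s:e]`` minimizing P0; ties longest then leftmost."""
    best = (np.inf, 0, 0)  # (log_p0, -length, start)
    for i in range(s, e):
        counts = np.zeros(20, dtype=np.int64)
        log_omega = 0.0
        for j in range(i, e):
            c = idx[j]
            if c < 0:  # skipped residue breaks the subsequence
                break
            L = j - i + 1
            counts[c] += 1
            log_omega += log(L) - log(counts[c])
            r = np.bincount(counts, minlength=2)
            log_f = lgamma(21.0) - sum(lgamma(rk + 1) for rk in r if rk > 1)
            lp = log_omega + log_f - L * _LOG20
            cand = (lp, -L, i)
            if lp < best[0] - _TIE_TOL or (
                abs(lp - best[0]) <= _TIE_TOL and cand[1:] < best[1:]
            ):
                best = cand
    length = -best[1]
    return best[2], best[2] + length


def seg_low_complexity(
    seq: str,
    W: int = SEG_WINDOW,
    K_low: float = SEG_LOWCUT,
    K_high: float = SEG_HIGHCUT,
    on_noncanonical: str = "error",
) -> list[LcrSegment]:
    """Detect low-complexity segments with the two-stage windowed-entropy scan.

    Stage 1: every length-``W`` window with entropy K2 <= ``K_low`` triggers;
    each trigger extends to the maximal contiguous run of windows with
    K2 <= ``K_high``, and overlapping residue spans merge into candidate
    regions.  Stage 2: each candidate region is reduced to its subsequence of
    minimal compositional probability P0 (ties: longest, then leftmost).

    Sequences shorter than ``W`` return no segments (with a warning).
    ``on_noncanonical`` is ``"error"`` (default) or ``"skip"`` — skipped
    residues never participate in windows or reported segments.
    """
    if len(seq) < W:
        logger.warning(
            "seg_low_complexity: sequence of length %d < window %d; no segments",
            len(seq), W,
        )
        return []
    idx = _encode(seq, on_noncanonical)
    ent = _window_entropies(idx, W)
    low = ent <= K_low
    if not low.any():
        return []
    high = ent <= K_high

    # maximal runs of extension windows that contain at least one trigger
    spans: list[tuple[int, int, float]] = []  # residue spans + min trigger K2
    n_win = len(ent)
    i = 0
    while i < n_win:
        if not high[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_win and high[j + 1]:
            j += 1
        if low[i : j + 1].any():
            spans.append((i, j + W, float(ent[i : j + 1][low[i : j + 1]].min())))
        i = j + 1

    merged: list[list[float]] = []
    for s, e, k2 in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] = min(merged[-1][2], k2)
        else:
            merged.append([s, e, k2])

    segments = []
    for s, e, k2 in merged:
        a, b = _min_p0_subsequence(idx, int(s), int(e))
        segments.append(LcrSegment(a, b, k2))
    return segments


def pct_lcr(protein: ProteinRecord | str, segments: list[LcrSegment]) -> float:
    """Percent of residues inside low-complexity segments."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    covered = sum(len(s) for s in segments)
    return 100.0 * covered / len(seq)


def call_idrs(
    disorder_track: np.ndarray,
    prob_threshold: float = IDR_PROB_THRESHOLD,
    min_run: int = IDR_MIN_RUN,
) -> tuple[list[tuple[int, int]], float]:
    """Intrinsically disordered regions from a per-residue probability track.

    A residue is disordered when its probability >= ``prob_threshold``;
    maximal disordered runs of at least ``min_run`` residues are IDRs.
    Returns the 0-based half-open intervals and the percentage of residues
    inside them.
    """
    track = np.asarray(disorder_track, dtype=float)
    if track.ndim != 1 or len(track) == 0:
        raise InputError("call_idrs: empty or non-1D disorder track")
    disordered = track >= prob_threshold
    intervals: list[tuple[int, int]] = []
    padded = np.concatenate([[False], disordered, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_run:
            intervals.append((int(s), int(e)))
    covered = sum(e - s for s, e in intervals)
    return intervals, 100.0 * covered / len(track)


def mean_composition(
    proteins: list[ProteinRecord] | list[str], weighted: bool = False
) -> pd.Series:
    """Average residue composition (percent) of a protein set.

    By default each protein contributes its own percentage vector with equal
    weight; ``weighted=True`` pools residues across the set instead
    (length-weighted).  Entries sum to 100.
    """
    if not proteins:
        raise InputError("mean_composition: empty protein set")
    seqs = [p.sequence if isinstance(p, ProteinRecord) else p for p in proteins]
    mats = []
    for s in seqs:
        counts = np.zeros(20)
        for c in s:
            i = _AA_INDEX.get(c)
            if i is None:
                raise InputError(f"mean_composition: non-canonical residue {c!r}")
            counts[i] += 1
        mats.append(counts if weighted else 100.0 * counts / counts.sum())
    if weighted:
        total = np.sum(mats, axis=0)
        vec = 100.0 * total / total.sum()
    else:
        vec = np.mean(mats, axis=0)
    return pd.Series(vec, index=list(AMINO_ACIDS))


def adjust_plaac(raw_score: float) -> float:
    """Shift a PLAAC score into non-negative display range (raw + 60).

    PLAAC reports scores down to -60; the offset makes the floor 0.
    """
    if raw_score < -PLAAC_OFFSET:
        raise InputError(f"adjust_plaac: raw score {raw_score} below -{PLAAC_OFFSET:g}")
    return raw_score + PLAAC_OFFSET


def trim_signal_peptide(seq: str, n: int = SIGNAL_PEPTIDE_LEN) -> str:
    """Remove the N-terminal signal peptide (first ``n`` residues).

    Intended for proteins with a predicted signal peptide only; callers gate
    on the secreted flag.
    """
    if len(seq) <= n:
        raise InputError(
            f"trim_signal_peptide: sequence of length {len(seq)} <= trim length {n}"
        )
    return seq[n:]


def property_enrichment(
    groups: dict[str, list[str]],
    values: pd.Series | dict[str, float],
    global_mean: float | None = None,
) -> pd.DataFrame:
    """Per-group property means with one-sample t-tests vs the global mean.

    ``values`` maps protein ids to a property (e.g. %LCR); the global mean is
    the mean over every protein with a value unless overridden.  Groups of
    size < 2 (after dropping proteins without a value, with a warning) get
    p = 1.  Returns columns group, n, mean, sem, p.
    """
    vals = pd.Series(values).astype(float).dropna()
    gmean = float(vals.mean()) if global_mean is None else float(global_mean)
    rows = []
    for name, members in groups.items():
        ids = [str(m) for m in members]
        have = [m for m in ids if m in vals.index]
        if len(have) < len(ids):
            logger.warning(
                "property_enrichment: %d/%d members of %r lack a value",
                len(ids) - len(have), len(ids), name,
            )
        v = vals.loc[have].to_numpy()
        n = len(v)
        if n < 2:
            logger.warning("property_enrichment: group %r has <2 values; p=1", name)
            rows.append((name, n, v.mean() if n else np.nan, np.nan, 1.0))
            continue
        sem = v.std(ddof=1) / np.sqrt(n)
        p = float(stats.ttest_1samp(v, popmean=gmean).pvalue) if v.std(ddof=1) > 0 else 1.0
        rows.append((name, n, v.mean(), sem, p))
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sem", "p"])


def weighted_property_profile(
    expression: pd.Series | dict[str, float],
    property_values: pd.Series | dict[str, float],
    peak_hours: pd.Series | dict[str, int],
    n_bins: int = 8,
) -> pd.Series:
    """Transcript-weighted temporal property wave.

    For each gene the transcript count is multiplied by its product's
    property value, and the products are averaged within each hourly bin.
    Genes missing a property or a peak hour are excluded with a warning.
    """
    expr = pd.Series(expression).astype(float)
    prop = pd.Series(property_values).astype(float)
    hours = pd.Series(peak_hours)
    common = expr.index.intersection(prop.dropna().index).intersection(hours.dropna().index)
    dropped = len(expr) - len(common)
    if dropped:
        logger.warning(
            "weighted_property_profile: %d genes lack a property or peak hour", dropped
        )
    product = expr.loc[common] * prop.loc[common]
    bins = hours.loc[common].astype(int)
    out = product.groupby(bins).mean().reindex(range(1, n_bins + 1))
    out.index.name = "bin"
    return out


def build_property_table(
    proteins: list[ProteinRecord],
    external_scores: pd.DataFrame | None = None,
    seg_window: int = SEG_WINDOW,
    seg_lowcut: float = SEG_LOWCUT,
    seg_highcut: float = SEG_HIGHCUT,
    idr_threshold: float = IDR_PROB_THRESHOLD,
    idr_min_run: int = IDR_MIN_RUN,
    on_noncanonical: str = "error",
) -> pd.DataFrame:
    """Per-protein property table: %LCR, %IDR and ingested predictor scores.

    ``external_scores`` (optional) is indexed by protein id and may carry
    ``psp_score``, ``plaac_score`` (raw; emitted as ``plaac_score_adjusted``),
    ``llphy_score``, ``larks_fraction`` and ``amyloid_flag`` columns.
    Proteins without a disorder track get %IDR = NaN (excluded from
    aggregates) with a warning.
    """
    rows = []
    n_trackless = 0
    for p in proteins:
        segs = seg_low_complexity(
            p.sequence, seg_window, seg_lowcut, seg_highcut, on_noncanonical
        )
        if p.disorder_track is not None:
            _, pidr = call_idrs(p.disorder_track, idr_threshold, idr_min_run)
        else:
            n_trackless += 1
            pidr = np.nan
        rows.append((p.protein_id, len(p.sequence), pct_lcr(p, segs), pidr, len(segs)))
    if n_trackless:
        logger.warning(
            "build_property_table: %d proteins lack disorder tracks", n_trackless
        )
    table = pd.DataFrame(
        rows, columns=["protein_id", "length", "pct_lcr", "pct_idr", "n_lcr"]
    ).set_index("protein_id")
    if external_scores is not None:
        ext = external_scores.copy()
        if "plaac_score" in ext.columns:
            ext["plaac_score_adjusted"] = [
                adjust_plaac(x) if np.isfinite(x) else np.nan
                for x in ext.pop("plaac_score").astype(float)
            ]
        table = table.join(ext, how="left")
    return table


def segments_to_table(per_protein: dict[str, list[LcrSegment]]) -> pd.DataFrame:
    """Flatten SEG results to a BED-like table (0-based half-open)."""
    rows = [
        (pid, s.start, s.end, s.trigger_entropy)
        for pid, segs in per_protein.items()
        for s in segs
    ]
    return pd.DataFrame(rows, columns=["protein_id", "start", "end", "trigger_entropy"])
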