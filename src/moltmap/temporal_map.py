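"""Phase-resolved temporal mapping of oscillating genes.

Each gene in the 16-hour time course is assigned a peak phase in degrees of
the 8-hour oscillation cycle by harmonic (cosinor) regression, then binned
into eight hourly bins.  Overlaying a molt-upregulated gene set on the binned
map locates the reference molting hour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from moltmap.errors import InputError

logger = logging.getLogger(__name__)

OSC_P_THRESHOLD = 1e-3  # oscillation call: harmonic F-test p < 0.001
DEFAULT_MIN_AMPLITUDE = 0.1  # log2 units; a p-value alone flags tiny wobbles
N_BINS = 8


def fit_phase(
    values: np.ndarray, times: np.ndarray | None = None, period: float = 8.0
) -> tuple[float, float, float]:
    """Cosinor fit of one expression row: ``y ~ b0 + a*cos(wt) + b*sin(wt)``.

    Returns ``(phase_deg, amplitude, p_value)`` where ``phase_deg/360 * period``
    is the fitted peak time modulo the period, ``amplitude = hypot(a, b)`` and
    the p-value is the F-test of the two harmonic terms against the
    intercept-only model.  A constant series returns amplitude 0 and p = 1.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise InputError(f"fit_phase: need at least 4 timepoints, got {y.size}")
    if times is None:
        times = np.arange(len(y), dtype=float)
    t = np.asarray(times, dtype=float)
    if len(t) != len(y):
        raise InputError("fit_phase: times and values differ in length")

    phase, amp, p = _fit_harmonic(y[None, :], t, period)
    return float(phase[0]), float(amp[0]), float(p[0])


def _fit_harmonic(
    Y: np.ndarray, t: np.ndarray, period: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized harmonic regression over rows of ``Y`` (shared time grid)."""
    w = 2 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    a, b = coef[1], coef[2]
    amplitude = np.hypot(a, b)
    phase_deg = np.mod(np.degrees(np.arctan2(b, a)), 360.0)

    fitted = (X @ coef).T
    rss1 = np.sum((Y - fitted) ** 2, axis=1)
    rss0 = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    df1, df2 = 2, len(t) - 3
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = stats.f.sf(F, df1, df2)
    # constant (or perfectly fitted flat) series: no oscillation evidence
    flat = rss0 <= 1e-12
    p = np.where(flat, 1.0, p)
    amplitude = np.where(flat, 0.0, amplitude)
    # perfect non-flat cosine: F is infinite, sf returns 0 which is correct
    p = np.where(np.isnan(p), 1.0, p)
    return phase_deg, amplitude, p


def phase_to_hour(phase_deg: float, n_bins: int = N_BINS) -> int:
    """Map a phase in [0, 360) to its hourly bin in 1..n_bins.

    Bins are half-open: ``[45*(k-1), 45*k) -> k`` for the default 8 bins.
    """
    if not (0.0 <= phase_deg < 360.0):
        raise InputError(f"phase_to_hour: phase {phase_deg!r} outside [0, 360)")
    return int(phase_deg // (360.0 / n_bins)) + 1


@dataclass
class MapTable:
    """Per-gene map records sorted by ascending phase.

    ``data`` columns: gene_id, phase_deg, peak_hour, amplitude, osc_pvalue,
    oscillating, molt_upregulated (after :func:`overlay_molt`), and any
    annotation columns merged downstream (tissue_class, signalp_score,
    secreted).
    """

    data: pd.DataFrame
    period: float = 8.0

    def __post_init__(self) -> None:
        self.data = self.data.sort_values(
            "phase_deg", kind="stable", na_position="last"
        ).reset_index(drop=True)

    @property
    def oscillating(self) -> pd.DataFrame:
        return self.data[self.data["oscillating"]]

    def bin_counts(self, n_bins: int = N_BINS) -> pd.Series:
        """Oscillating gene count per hourly bin (index 1..n_bins)."""
        hours = self.oscillating["peak_hour"]
        return hours.value_counts().reindex(range(1, n_bins + 1), fill_value=0).sort_index()


def build_map_table(
    timecourse: pd.DataFrame,
    period: float = 8.0,
    times: np.ndarray | None = None,
    p_threshold: float = OSC_P_THRESHOLD,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> MapTable:
    """Fit every gene of a time course and assemble the sorted map.

    ``timecourse`` is indexed by gene id with one column per timepoint; column
    headers give the hours unless ``times`` is supplied.
    """
    if timecourse.shape[1] < 4:
        raise InputError("build_map_table: need at least 4 timepoints")
    if times is None:
        try:
            times = np.array([float(c) for c in timecourse.columns])
        except ValueError:
            times = np.arange(timecourse.shape[1], dtype=float)
    Y = timecourse.to_numpy(dtype=float)
    phase, amp, p = _fit_harmonic(Y, times, period)
    oscillating = (p < p_threshold) & (amp >= min_amplitude)
    bin_width = 360.0 / N_BINS
    peak_hour = (phase // bin_width).astype(int) + 1
    df = pd.DataFrame(
        {
            "gene_id": timecourse.index.astype(str),
            "phase_deg": np.where(oscillating, phase, np.nan),
            "peak_hour": pd.array(np.where(oscillating, peak_hour, pd.NA), dtype="Int64"),
            "amplitude": amp,
            "osc_pvalue": p,
            "oscillating": oscillating,
        }
    )
    logger.info(
        "build_map_table: %d/%d genes oscillating (p<%g, amplitude>=%g)",
        int(oscillating.sum()), len(df), p_threshold, min_amplitude,
    )
    return MapTable(df, period=period)


def passthrough_map_table(table: pd.DataFrame, period: float = 8.0) -> MapTable:
    """Build a map directly from an ingested phase table (no fitting).

    ``table`` needs ``gene_id`` and ``phase_deg``; an ``oscillating`` column is
    honoured if present, otherwise any gene with a finite phase is taken as
    oscillating.  Peak hours are (re)derived from the phases.
    """
    df = table.copy()
    if "gene_id" not in df.columns or "phase_deg" not in df.columns:
        raise InputError("passthrough_map_table: need gene_id and phase_deg columns")
    phase = pd.to_numeric(df["phase_deg"], errors="coerce")
    if "oscillating" in df.columns:
        osc = df["oscillating"].astype(bool).to_numpy()
    else:
        osc = np.isfinite(phase.to_numpy())
    bad = osc & ~np.isfinite(phase.to_numpy())
    if bad.any():
        raise InputError(
            f"passthrough_map_table: {int(bad.sum())} oscillating genes lack a phase"
        )
    phase = np.mod(phase.to_numpy(dtype=float), 360.0)
    bin_width = 360.0 / N_BINS
    hours = np.zeros(len(phase), dtype=int)
    hours[osc] = (phase[osc] // bin_width).astype(int) + 1
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "phase_deg": np.where(osc, phase, np.nan),
            "peak_hour": pd.array(np.where(osc, hours, pd.NA), dtype="Int64"),
            "amplitude": pd.to_numeric(df.get("amplitude", np.nan), errors="coerce"),
            "osc_pvalue": pd.to_numeric(df.get("osc_pvalue", np.nan), errors="coerce"),
            "oscillating": osc,
        }
    )
    return MapTable(out, period=period)


def overlay_molt(map_table: MapTable, molt_genes: set[str] | list[str]) -> pd.Series:
    """Count, per hourly bin, the oscillating map genes in the molt set.

    Molt genes absent from the map are logged and excluded.  The map gains a
    ``molt_upregulated`` column as a side effect.
    """
    molt = {str(g) for g in molt_genes}
    if not molt:
        raise InputError("overlay_molt: empty molt gene set")
    known = set(map_table.data["gene_id"])
    missing = molt - known
    if missing:
        logger.warning(
            "overlay_molt: %d molt genes absent from the map (e.g. %s)",
            len(missing), sorted(missing)[:3],
        )
    map_table.data["molt_upregulated"] = map_table.data["gene_id"].isin(molt)
    osc = map_table.oscillating
    hits = osc.loc[osc["molt_upregulated"], "peak_hour"]
    counts = (
        hits.value_counts().reindex(range(1, N_BINS + 1), fill_value=0).sort_index()
    )
    counts.index.name = "peak_hour"
    if counts.sum() == 0:
        logger.warning("overlay_molt: molt set is disjoint from the oscillating map")
    return counts.astype(int)


def peak_molt_hour(overlap_counts: pd.Series | np.ndarray) -> int:
    """Reference molting hour: the bin with the highest molt overlap.

    Ties return the earliest tied bin with a warning; all-zero counts are an
    input error.
    """
    counts = np.asarray(overlap_counts, dtype=float)
    if counts.sum() == 0:
        raise InputError("peak_molt_hour: all overlap counts are zero")
    best = int(np.argmax(counts))
    if (counts == counts[best]).sum() > 1:
        logger.warning("peak_molt_hour: tie at count %g; returning earliest bin", counts[best])
    if isinstance(overlap_counts, pd.Series):
        return int(overlap_counts.index[best])
    return best + 1
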