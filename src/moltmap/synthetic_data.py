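"""Synthetic pipeline inputs with planted ground truth.

Every downstream stage of the package (phase fitting, tissue enrichment,
secretome partition, SEG, family discovery) can be exercised against data whose
true labels are known.  The generator emulates the study conditions of the
molting cycle at 25 degC: a 16-hour, hourly time course in which a subset of
genes oscillates with an 8-hour period; a molt-upregulated subset whose peak
phases concentrate in one hourly bin; tissue expression summaries in TPM with
planted pharynx enrichment (fold change plus a transcript-abundance burst at
the molting hour); signal peptides with scores respecting the 0.45 secretome
cutoff; and low-complexity protein families derived from biased-composition
consensus sequences with per-residue mutational divergence.

Defaults follow the genome-scale composition of the mapped dataset: 20,330
protein-coding genes of which 2716 oscillate, 602 of those are upregulated
during the L4 molt (peaking in hour 6), 470 are pharynx-enriched (367 of them
oscillating), and signal-peptide incidence is stratified at 62% / 39% / 17%
for oscillating pharynx-enriched / remaining oscillating / non-oscillating
genes respectively.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from moltmap.errors import ConfigError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Approximate residue frequencies of a eukaryotic proteome, used for
#: non-family protein bodies and for substitution targets.
BACKGROUND_FREQS = np.array(
    [
        0.083,  # A
        0.014,  # C
        0.054,  # D
        0.067,  # E
        0.038,  # F
        0.071,  # G
        0.022,  # H
        0.059,  # I
        0.058,  # K
        0.096,  # L
        0.024,  # M
        0.040,  # N
        0.047,  # P
        0.039,  # Q
        0.055,  # R
        0.066,  # S
        0.053,  # T
        0.068,  # V
        0.011,  # W
        0.029,  # Y
    ]
)
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

#: (dominant, secondary) residues of the six planted low-complexity families.
#: Disjoint residue pairs keep between-family identity low while the
#: 0.50/0.25 concentration keeps 12-residue window entropy below the SEG
#: trigger.
FAMILY_BIASES: tuple[tuple[str, str], ...] = (
    ("Q", "P"),
    ("C", "S"),
    ("G", "A"),
    ("N", "D"),
    ("T", "V"),
    ("H", "R"),
)

#: Tissue-enriched gene counts of the L2 single-cell summaries.
DEFAULT_ENRICHED_COUNTS: Mapping[str, int] = {
    "pharynx": 470,
    "BWM": 326,
    "glia": 426,
    "gonad": 832,
    "hypodermis": 411,
    "intestine": 781,
    "neurons": 965,
}

_GENOME_SIZE = 20330  # 2716 oscillating + 17,614 non-oscillating


#: Family member counts used when ``family_sizes`` is left at its default;
#: shrunk automatically for genomes too small to host the full plan.
DEFAULT_FAMILY_SIZES = (12, 10, 8, 6, 5, 5)


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"SimConfig.{fieldname}: {msg}")


def _resolve_family_sizes(cfg: "SimConfig", pool_size: int) -> list[int]:
    """Family sizes that fit the secreted enriched pool.

    Explicit sizes are taken literally (too-small pools are a configuration
    error).  The default plan shrinks gracefully: sizes decrement toward the
    minimum of 3, then whole families are dropped, with a warning.
    """
    if cfg.family_sizes is not None:
        if sum(cfg.family_sizes) > pool_size:
            raise ConfigError(
                "SimConfig.family_sizes: "
                f"sum {sum(cfg.family_sizes)} exceeds the {pool_size} secreted "
                f"{cfg.enriched_target}-enriched genes"
            )
        return list(cfg.family_sizes)
    base = list(DEFAULT_FAMILY_SIZES)
    while len(base) < cfg.n_families:
        base.append(DEFAULT_FAMILY_SIZES[-1])
    sizes = base[: cfg.n_families]
    while sizes and sum(sizes) > pool_size:
        m = max(sizes)
        if m > 3:
            sizes[sizes.index(m)] -= 1
        else:
            sizes.pop()
    if len(sizes) < cfg.n_families:
        logger.warning(
            "family plan shrunk to %d families (pool of %d secreted enriched genes)",
            len(sizes), pool_size,
        )
    return sizes


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Fractions are planted per-gene by Bernoulli draws, so realized counts vary
    binomially around their expectations.  ``seed`` fixes every output
    bit-for-bit; each generator stage derives an independent stream from it,
    so the stages may be called in any order or combination.
    """

    n_genes: int = _GENOME_SIZE
    frac_oscillating: float = 2716 / _GENOME_SIZE
    period_hours: float = 8.0
    n_timepoints: int = 16
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.25
    baseline_range: tuple[float, float] = (3.0, 9.0)
    molt_hour: int = 6
    molt_fraction: float = 602 / 2716
    molt_phase_sd_deg: float = 25.0
    tissues: tuple[str, ...] = (
        "pharynx",
        "hypodermis",
        "BWM",
        "glia",
        "gonad",
        "intestine",
        "neurons",
    )
    enriched_target: str = "pharynx"
    enriched_counts: Mapping[str, int] | None = None
    frac_enriched_oscillating: float = 367 / 470
    enrich_fold: float = 4.0
    abundance_boost: float = 30.0
    frac_secreted: float = 0.62
    frac_secreted_osc: float = 0.39
    frac_secreted_bg: float = 0.17
    n_families: int = 6
    family_sizes: tuple[int, ...] | None = None
    family_mutation_rate: float = 0.15
    family_length_range: tuple[int, int] = (90, 220)
    protein_length_range: tuple[int, int] = (120, 360)
    frac_idr_background: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        for name in (
            "frac_oscillating",
            "molt_fraction",
            "frac_enriched_oscillating",
            "frac_secreted",
            "frac_secreted_osc",
            "frac_secreted_bg",
            "family_mutation_rate",
            "frac_idr_background",
        ):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, f"fraction {v!r} not in [0, 1]")
        _check(self.period_hours > 0, "period_hours", "must be positive")
        _check(
            self.n_timepoints >= self.period_hours,
            "n_timepoints",
            "needs at least one full period of hourly samples",
        )
        lo, hi = self.amplitude_range
        _check(0 <= lo <= hi, "amplitude_range", "must be ordered and non-negative")
        _check(self.noise_sd >= 0, "noise_sd", "must be non-negative")
        n_bins = self.n_bins
        _check(
            1 <= self.molt_hour <= n_bins,
            "molt_hour",
            f"must be a bin in 1..{n_bins}",
        )
        _check(len(self.tissues) == len(set(self.tissues)), "tissues", "labels must be unique")
        _check(len(self.tissues) >= 2, "tissues", "need at least two tissues")
        _check(
            self.enriched_target in self.tissues,
            "enriched_target",
            f"{self.enriched_target!r} not in tissues",
        )
        _check(self.enrich_fold > 1, "enrich_fold", "must exceed 1")
        _check(self.abundance_boost >= 1, "abundance_boost", "must be >= 1")
        if self.family_sizes is not None:
            _check(
                self.n_families == len(self.family_sizes),
                "family_sizes",
                f"{len(self.family_sizes)} sizes given for n_families={self.n_families}",
            )
            for s in self.family_sizes:
                _check(s >= 3, "family_sizes", f"family size {s} < 3")
        _check(int(self.seed) == self.seed, "seed", "must be an integer")

    @property
    def n_bins(self) -> int:
        """Number of hourly bins per oscillation period (8 by default)."""
        return int(round(self.period_hours))

    def resolved_enriched_counts(self) -> dict[str, int]:
        """Per-tissue enriched gene counts, scaled to ``n_genes`` if defaulted."""
        if self.enriched_counts is not None:
            counts = dict(self.enriched_counts)
            unknown = set(counts) - set(self.tissues)
            _check(not unknown, "enriched_counts", f"unknown tissues {sorted(unknown)}")
            return counts
        scale = self.n_genes / _GENOME_SIZE
        return {
            t: max(1, int(round(DEFAULT_ENRICHED_COUNTS.get(t, 0) * scale)))
            for t in self.tissues
            if DEFAULT_ENRICHED_COUNTS.get(t, 0) > 0
        }

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["enriched_counts"] = (
            dict(self.enriched_counts) if self.enriched_counts is not None else None
        )
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        d = json.loads(Path(path).read_text())
        for key in ("amplitude_range", "baseline_range", "family_sizes",
                    "family_length_range", "protein_length_range", "tissues"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ProteinRecord:
    """One protein: identifier, sequence, optional per-residue disorder track."""

    protein_id: str
    sequence: str
    disorder_track: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        if self.disorder_track is not None:
            self.disorder_track = np.asarray(self.disorder_track, dtype=float)
            if len(self.disorder_track) != len(self.sequence):
                raise ValueError(
                    f"{self.protein_id}: track length {len(self.disorder_track)}"
                    f" != sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    # independent, order-insensitive stream per generator stage
    return np.random.default_rng([int(cfg.seed), stage])


def plant_truth(cfg: SimConfig) -> pd.DataFrame:
    """Draw the complete ground-truth table for one simulated genome.

    Columns: ``gene_id``, ``oscillating``, ``phase_deg`` (NaN when silent),
    ``peak_hour`` (nullable int), ``molt_upregulated``, ``enriched_tissue``
    ("" when non-specific), ``secreted``, ``family`` ("" when none).
    """
    rng = _rng(cfg, 0)
    n = cfg.n_genes
    gene_ids = np.array([f"g{i + 1:06d}" for i in range(n)])

    osc = np.zeros(n, dtype=bool)
    n_osc = int(round(cfg.frac_oscillating * n))
    osc[rng.choice(n, size=n_osc, replace=False)] = True

    # molt subset: phases concentrate in the molt bin, others are uniform
    bin_width = 360.0 / cfg.n_bins
    phase = np.full(n, np.nan)
    osc_idx = np.flatnonzero(osc)
    phase[osc_idx] = rng.uniform(0.0, 360.0, size=n_osc)
    molt = np.zeros(n, dtype=bool)
    n_molt = int(round(cfg.molt_fraction * n_osc))
    molt_idx = rng.choice(osc_idx, size=n_molt, replace=False)
    molt[molt_idx] = True
    center = (cfg.molt_hour - 0.5) * bin_width
    phase[molt_idx] = np.mod(
        rng.normal(center, cfg.molt_phase_sd_deg, size=n_molt), 360.0
    )

    peak_hour = np.where(osc, np.floor(phase / bin_width) + 1, 0).astype(int)

    # tissue-enriched labels: target tissue drawn with a fixed oscillating
    # share; other tissues drawn from whatever remains unlabelled
    enriched = np.array([""] * n, dtype=object)
    counts = cfg.resolved_enriched_counts()
    free_osc = list(rng.permutation(np.flatnonzero(osc)))
    free_non = list(rng.permutation(np.flatnonzero(~osc)))
    target_count = counts.pop(cfg.enriched_target, 0)
    n_t_osc = min(int(round(cfg.frac_enriched_oscillating * target_count)), len(free_osc))
    n_t_non = min(target_count - n_t_osc, len(free_non))
    for _ in range(n_t_osc):
        enriched[free_osc.pop()] = cfg.enriched_target
    for _ in range(n_t_non):
        enriched[free_non.pop()] = cfg.enriched_target
    free = free_osc + free_non
    rng.shuffle(free)
    for tissue, count in counts.items():
        for _ in range(min(count, len(free))):
            enriched[free.pop()] = tissue

    # stratified signal-peptide incidence
    in_target = enriched == cfg.enriched_target
    strat_a = osc & in_target
    strat_b = osc & ~in_target
    strat_c = ~osc
    u = rng.random(n)
    secreted = np.zeros(n, dtype=bool)
    secreted[strat_a] = u[strat_a] < cfg.frac_secreted
    secreted[strat_b] = u[strat_b] < cfg.frac_secreted_osc
    secreted[strat_c] = u[strat_c] < cfg.frac_secreted_bg

    # low-complexity families live in the oscillating secreted enriched set
    family = np.array([""] * n, dtype=object)
    pool = np.flatnonzero(secreted & in_target & osc)
    sizes = _resolve_family_sizes(cfg, len(pool))
    need = sum(sizes)
    members = rng.choice(pool, size=need, replace=False)
    start = 0
    for k, size in enumerate(sizes):
        family[members[start : start + size]] = f"F{k + 1}"
        start += size

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "oscillating": osc,
            "phase_deg": phase,
            "peak_hour": pd.array(
                np.where(osc, peak_hour, pd.NA), dtype="Int64"
            ),
            "molt_upregulated": molt,
            "enriched_tissue": enriched,
            "secreted": secreted,
            "family": family,
        }
    )
    return truth


def gen_timecourse(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the hourly log2-expression table and its ground truth.

    Oscillating genes follow ``baseline + A * cos(2*pi*(t - t_peak)/period)``
    with ``t_peak = phase/360 * period`` plus Gaussian noise on the log2
    scale; silent genes are baseline plus noise.

    Returns ``(timecourse, truth)`` where ``timecourse`` is indexed by
    ``gene_id`` with one column per hour (labelled "0", "1", ...).
    """
    truth = plant_truth(cfg)
    rng = _rng(cfg, 1)
    n = cfg.n_genes
    t = np.arange(cfg.n_timepoints, dtype=float)

    baseline = rng.uniform(*cfg.baseline_range, size=n)
    amplitude = rng.uniform(*cfg.amplitude_range, size=n)
    amplitude[~truth["oscillating"].to_numpy()] = 0.0
    t_peak = np.where(
        truth["oscillating"], truth["phase_deg"] / 360.0 * cfg.period_hours, 0.0
    )

    signal = baseline[:, None] + amplitude[:, None] * np.cos(
        2 * np.pi * (t[None, :] - t_peak[:, None]) / cfg.period_hours
    )
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)

    timecourse = pd.DataFrame(
        signal,
        index=pd.Index(truth["gene_id"], name="gene_id"),
        columns=[str(int(h)) for h in t],
    )
    logger.info(
        "gen_timecourse: %d genes (%d oscillating), %d timepoints, seed=%d",
        n, int(truth["oscillating"].sum()), cfg.n_timepoints, cfg.seed,
    )
    return timecourse, truth


def gen_tissue_matrix(cfg: SimConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Simulate the tissue x gene TPM matrix (genes as rows).

    Genes with an enriched-tissue label get ``enrich_fold`` times their level
    in every other tissue; secreted target-tissue genes peaking in the molt
    hour additionally carry an ``abundance_boost``-fold transcript burst
    relative to the target column mean (the fold relation is preserved).
    Columns are normalized to one million.
    """
    rng = _rng(cfg, 2)
    n = len(truth)
    tissues = list(cfg.tissues)
    k = len(tissues)

    base = rng.lognormal(mean=np.log(30.0), sigma=1.0, size=n)
    jitter = rng.uniform(0.95, 1.05, size=(n, k))
    mat = base[:, None] * jitter

    enriched = truth["enriched_tissue"].to_numpy()
    ti = {t: j for j, t in enumerate(tissues)}
    is_enriched = enriched != ""
    v = rng.uniform(15.0, 25.0, size=n)
    for i in np.flatnonzero(is_enriched):
        mat[i, :] = v[i]
        mat[i, ti[enriched[i]]] = cfg.enrich_fold * v[i]

    # transcript burst at the molt for the secreted target-tissue wave
    target_col = ti[cfg.enriched_target]
    boosted = (
        truth["secreted"].to_numpy()
        & (enriched == cfg.enriched_target)
        & (truth["peak_hour"].to_numpy(dtype=float, na_value=np.nan) == cfg.molt_hour)
    )
    if boosted.any():
        # plant the burst at abundance_boost times the post-boost column
        # mean: x = B * (S_rest + n_b * x) / n  =>  x = B*S_rest / (n - B*n_b)
        n_b = int(boosted.sum())
        s_rest = mat[~boosted, target_col].sum()
        denom = n - cfg.abundance_boost * n_b
        if denom <= 0:
            raise ConfigError(
                "SimConfig.abundance_boost: "
                f"boost {cfg.abundance_boost} x {n_b} genes exceeds a genome of {n}"
            )
        x = cfg.abundance_boost * s_rest / denom
        mat[boosted, target_col] = x
        mat[boosted, :target_col] = x / cfg.enrich_fold
        mat[boosted, target_col + 1 :] = x / cfg.enrich_fold

    mat = mat / mat.sum(axis=0, keepdims=True) * 1e6
    out = pd.DataFrame(
        mat, index=pd.Index(truth["gene_id"], name="gene_id"), columns=tissues
    )
    logger.info(
        "gen_tissue_matrix: %d genes x %d tissues, %d enriched, %d boosted",
        n, k, int(is_enriched.sum()), int(boosted.sum()),
    )
    return out


def _draw_background(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(20, size=length, p=BACKGROUND_FREQS)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _family_freqs(dominant: str, secondary: str) -> np.ndarray:
    freqs = BACKGROUND_FREQS * 0.25
    freqs[AMINO_ACIDS.index(dominant)] += 0.50
    freqs[AMINO_ACIDS.index(secondary)] += 0.25
    return freqs / freqs.sum()


def gen_proteome(
    cfg: SimConfig, truth: pd.DataFrame
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Simulate one protein per gene plus signal-peptide scores.

    Family members are copies of a family-specific biased-composition
    consensus with substitutions at ``family_mutation_rate``; secreted
    proteins carry a 20-residue hydrophobic leader and a signal-peptide score
    of at least 0.45 (non-secreted genes score below 0.45).  Disorder tracks
    assign high probability over the planted low-complexity bodies and over
    random long runs in a background fraction of proteins.

    Returns ``(proteins, scores)`` where ``scores`` has columns ``gene_id``
    and ``signalp_score``.
    """
    rng = _rng(cfg, 3)
    n = len(truth)
    secreted = truth["secreted"].to_numpy()
    family = truth["family"].to_numpy()
    gene_ids = truth["gene_id"].to_numpy()

    fam_labels = sorted({f for f in family if f})
    if len(fam_labels) > len(FAMILY_BIASES):
        raise ConfigError(
            "SimConfig.n_families: "
            f"at most {len(FAMILY_BIASES)} family composition biases are defined"
        )
    consensus: dict[str, str] = {}
    for j, lab in enumerate(fam_labels):
        freqs = _family_freqs(*FAMILY_BIASES[j])
        length = int(rng.integers(*cfg.family_length_range))
        idx = rng.choice(20, size=length, p=freqs)
        consensus[lab] = "".join(AMINO_ACIDS[i] for i in idx)

    hydrophobic = "LAVIF"
    records: list[ProteinRecord] = []
    scores = np.empty(n)
    scores[secreted] = 0.45 + 0.55 * rng.random(int(secreted.sum()))
    scores[~secreted] = 0.449 * rng.random(int((~secreted).sum()))

    for i in range(n):
        if family[i]:
            body = list(consensus[family[i]])
            if cfg.family_mutation_rate > 0:
                hit = rng.random(len(body)) < cfg.family_mutation_rate
                for p in np.flatnonzero(hit):
                    body[p] = AMINO_ACIDS[rng.choice(20, p=BACKGROUND_FREQS)]
            body = "".join(body)
            track = np.full(len(body), 0.9)
        else:
            length = int(rng.integers(*cfg.protein_length_range))
            body = _draw_background(rng, length)
            track = np.full(length, 0.1)
            if rng.random() < cfg.frac_idr_background and length > 40:
                run = int(rng.integers(30, min(81, length)))
                start = int(rng.integers(0, length - run + 1))
                track[start : start + run] = 0.9
        if secreted[i]:
            leader = "M" + "".join(
                hydrophobic[j] for j in rng.integers(0, len(hydrophobic), size=19)
            )
            body = leader + body
            track = np.concatenate([np.full(20, 0.05), track])
        records.append(ProteinRecord(gene_ids[i], body, track))

    score_table = pd.DataFrame({"gene_id": gene_ids, "signalp_score": scores})
    logger.info(
        "gen_proteome: %d proteins, %d secreted, %d family members, seed=%d",
        n, int(secreted.sum()), int((family != "").sum()), cfg.seed,
    )
    return records, score_table


@dataclass
class SyntheticData:
    """Bundle of all generated inputs plus their shared ground truth."""

    config: SimConfig
    truth: pd.DataFrame
    timecourse: pd.DataFrame
    tissue_matrix: pd.DataFrame
    proteins: list[ProteinRecord]
    signalp_scores: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write every table as TSV, proteins as FASTA, config as JSON."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_json(out / "sim_config.json")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.timecourse.to_csv(out / "timecourse.tsv", sep="\t")
        self.tissue_matrix.to_csv(out / "tissue_tpm.tsv", sep="\t")
        self.signalp_scores.to_csv(out / "signalp_scores.tsv", sep="\t", index=False)
        write_fasta(self.proteins, out / "proteome.fasta")
        write_disorder_tracks(self.proteins, out / "disorder_tracks.tsv")
        molt = self.truth.loc[self.truth["molt_upregulated"], "gene_id"]
        molt.to_csv(out / "molt_genes.txt", index=False, header=False)
        print(
            f"simulate: wrote {len(self.truth)} genes to {out} (seed={self.config.seed})",
            file=sys.stderr,
        )


def simulate(cfg: SimConfig) -> SyntheticData:
    """Generate the full input bundle for one seed."""
    timecourse, truth = gen_timecourse(cfg)
    tissue = gen_tissue_matrix(cfg, truth)
    proteins, scores = gen_proteome(cfg, truth)
    return SyntheticData(cfg, truth, timecourse, tissue, proteins, scores)


# ---------------------------------------------------------------------------
# FASTA / track serialization


def write_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in proteins
    ]
    seqio_write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    from Bio.SeqIO import parse

    return [ProteinRecord(r.id, str(r.seq)) for r in parse(str(path), "fasta")]


def write_disorder_tracks(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    """Per-protein probability strings: protein_id TAB comma-joined floats."""
    with open(path, "w") as fh:
        fh.write("protein_id\tprobabilities\n")
        for p in proteins:
            if p.disorder_track is None:
                continue
            fh.write(p.protein_id + "\t" + ",".join(f"{x:.3f}" for x in p.disorder_track) + "\n")


def read_disorder_tracks(path: str | Path) -> dict[str, np.ndarray]:
    tracks: dict[str, np.ndarray] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if {"protein_id", "probabilities"} <= set(df.columns):
        for pid, s in zip(df["protein_id"], df["probabilities"]):
            tracks[pid] = np.array([float(x) for x in s.split(",")])
    elif {"protein_id", "position", "probability"} <= set(df.columns):
        for pid, grp in df.groupby("protein_id", sort=False):
            pos = grp["position"].astype(int).to_numpy()
            prob = grp["probability"].astype(float).to_numpy()
            tracks[pid] = prob[np.argsort(pos)]
    else:
        raise ValueError(f"{path}: unrecognized disorder-track columns {list(df.columns)}")
    return tracks
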