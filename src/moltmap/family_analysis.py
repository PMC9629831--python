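"""Low-complexity protein family discovery and consensus description.

Families are the connected components, under single linkage, of the graph
whose edges join protein pairs with global-alignment percent identity at or
above a threshold (default 30%).  Each family is summarized by a center-star
multiple alignment, a position frequency matrix (the numeric substrate of a
sequence logo), and a row of temporal / sequence-property statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from moltmap.errors import InputError

logger = logging.getLogger(__name__)

IDENTITY_THRESHOLD = 30.0
MIN_FAMILY_SIZE = 3
SINGLETON = "singleton"

#: Residue classes used to annotate position frequency matrices.
RESIDUE_CLASSES: dict[str, str] = {
    **{a: "polar" for a in "GSTYC"},
    **{a: "neutral" for a in "QN"},
    **{a: "basic" for a in "KRH"},
    **{a: "acidic" for a in "DE"},
    **{a: "hydrophobic" for a in "AVLIPWFM"},
}


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _align_pair(seq_a: str, seq_b: str) -> tuple[str, str]:
    """One optimal global alignment of two sequences, as gapped strings."""
    alignment = _aligner().align(seq_a, seq_b)[0]
    return str(alignment[0]), str(alignment[1])


def pairwise_identity(seq_a: str, seq_b: str, denominator: str = "full") -> float:
    """Percent identity of an optimal global alignment of two sequences.

    ``denominator`` selects the normalization:

    * ``"full"`` (default) — the full alignment length including gap
      columns.  For compositionally biased (low-complexity) proteins this is
      the robust choice: unrelated pairs are not inflated either by a short
      shared chance core (which dominates the gap-excluded count) or by
      scattered longest-common-subsequence matches of a short sequence
      inside a much longer one (which dominate a shorter-length count).
    * ``"aligned"`` — columns where both sequences carry a residue
      (gap-excluded).
    * ``"shorter"`` — the length of the shorter sequence.
    """
    if not seq_a or not seq_b:
        raise InputError("pairwise_identity: empty sequence")
    if denominator not in ("shorter", "aligned", "full"):
        raise InputError(f"pairwise_identity: unknown denominator {denominator!r}")
    row_a, row_b = _align_pair(seq_a, seq_b)
    matches = aligned = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            aligned += 1
            if x == y:
                matches += 1
    if denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    elif denominator == "aligned":
        denom = aligned
    else:
        denom = len(row_a)
    if denom == 0:
        return 0.0
    return 100.0 * matches / denom


def build_identity_matrix(
    proteins: dict[str, str] | pd.Series, denominator: str = "full"
) -> pd.DataFrame:
    """All-vs-all percent identity matrix (symmetric, diagonal 100)."""
    items = list(pd.Series(proteins).items())
    ids = [str(k) for k, _ in items]
    if len(ids) != len(set(ids)):
        raise InputError("build_identity_matrix: duplicate protein ids")
    if len(ids) < 2:
        raise InputError("build_identity_matrix: need at least 2 proteins")
    n = len(items)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(items[i][1], items[j][1], denominator)
            mat[i, j] = mat[j, i] = pid
    return pd.DataFrame(mat, index=ids, columns=ids)


def cluster_families(
    identity_matrix: pd.DataFrame,
    identity_threshold: float = IDENTITY_THRESHOLD,
    min_family_size: int = MIN_FAMILY_SIZE,
) -> pd.Series:
    """Single-linkage families at an identity threshold.

    Proteins are nodes; pairs with identity >= ``identity_threshold`` are
    edges.  Connected components with at least ``min_family_size`` members
    become families, labelled ``F1``, ``F2``, ... by descending size then by
    lexicographically smallest member id (so labels are stable under input
    permutation); everything else is ``"singleton"``.
    """
    ids = [str(i) for i in identity_matrix.index]
    mat = identity_matrix.to_numpy()
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] >= identity_threshold:
                g.add_edge(ids[i], ids[j])
    components = [sorted(c) for c in nx.connected_components(g) if len(c) >= min_family_size]
    components.sort(key=lambda c: (-len(c), c[0]))
    assignment = pd.Series(SINGLETON, index=sorted(ids), dtype=object)
    for k, comp in enumerate(components):
        assignment.loc[comp] = f"F{k + 1}"
    assignment = assignment.loc[ids]  # restore input order
    assignment.index.name = "protein_id"
    assignment.name = "family"
    logger.info(
        "cluster_families: %d families, %d singletons (threshold %.1f%%)",
        len(components), int((assignment == SINGLETON).sum()), identity_threshold,
    )
    return assignment


def center_star_msa(sequences: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Center-star multiple alignment of a family.

    The member with the highest summed pairwise identity to the others is the
    center; every other sequence is aligned to it pairwise and the pairwise
    alignments are merged on the center's coordinates ("once a gap, always a
    gap").  Degapping any row recovers the input sequence.  Returns a
    one-column-per-position DataFrame of single characters indexed by id.
    """
    seqs = {str(k): v for k, v in pd.Series(sequences).items()}
    if len(seqs) < 2:
        raise InputError("center_star_msa: need at least 2 sequences")
    ids = list(seqs)
    total = {
        i: sum(pairwise_identity(seqs[i], seqs[j]) for j in ids if j != i) for i in ids
    }
    center = max(ids, key=lambda i: (total[i], i))
    center_seq = seqs[center]

    # per pairwise alignment: gaps inserted into the center, keyed by the
    # center position they precede (position len(center) = trailing gaps)
    pair_rows: dict[str, tuple[str, str]] = {}
    max_gaps = np.zeros(len(center_seq) + 1, dtype=int)
    for other in ids:
        if other == center:
            continue
        row_c, row_o = _align_pair(center_seq, seqs[other])
        pair_rows[other] = (row_c, row_o)
        pos = 0
        run = 0
        gaps = np.zeros(len(center_seq) + 1, dtype=int)
        for ch in row_c:
            if ch == "-":
                run += 1
            else:
                gaps[pos] = max(gaps[pos], run)
                run = 0
                pos += 1
        gaps[len(center_seq)] = run
        max_gaps = np.maximum(max_gaps, gaps)

    def project(row_c: str, row_o: str) -> str:
        out: list[str] = []
        pos = 0
        pending: list[str] = []
        for cc, oc in zip(row_c, row_o):
            if cc == "-":
                pending.append(oc)
            else:
                out.append("-" * (max_gaps[pos] - len(pending)) + "".join(pending))
                out.append(oc)
                pending = []
                pos += 1
        out.append("-" * (max_gaps[len(center_seq)] - len(pending)) + "".join(pending))
        return "".join(out)

    rows = {center: project(center_seq, center_seq)}
    for other, (row_c, row_o) in pair_rows.items():
        rows[other] = project(row_c, row_o)
    width = len(rows[center])
    aligned = pd.DataFrame(
        [list(rows[i]) for i in ids], index=pd.Index(ids, name="protein_id")
    )
    assert all(len(rows[i]) == width for i in ids)
    return aligned


def position_frequency_matrix(alignment: pd.DataFrame) -> pd.DataFrame:
    """Column-wise residue frequencies of an alignment (logo substrate).

    Each residue's frequency is its count over the number of rows, so residue
    frequencies plus the ``gap`` fraction sum to 1 per column; the occupancy
    (1 - gap fraction) is the stack width of the corresponding logo column.
    """
    if alignment.isna().any().any():
        raise InputError("position_frequency_matrix: ragged alignment")
    n_rows = len(alignment)
    letters = sorted({c for col in alignment.columns for c in alignment[col] if c != "-"})
    records = []
    for col in alignment.columns:
        counts = alignment[col].value_counts()
        row = {a: counts.get(a, 0) / n_rows for a in letters}
        row["gap"] = counts.get("-", 0) / n_rows
        records.append(row)
    pfm = pd.DataFrame(records).fillna(0.0)
    pfm.index.name = "position"
    return pfm


def consensus_sequence(pfm: pd.DataFrame, min_occupancy: float = 0.5) -> str:
    """Majority-residue consensus of a PFM, skipping gap-dominated columns."""
    residues = [c for c in pfm.columns if c != "gap"]
    out = []
    for _, row in pfm.iterrows():
        if 1.0 - row.get("gap", 0.0) < min_occupancy:
            continue
        out.append(max(residues, key=lambda a: (row[a], a)))
    return "".join(out)


@dataclass
class FamilyAssignment:
    """Families plus per-family alignments and frequency matrices."""

    assignment: pd.Series
    alignments: dict[str, pd.DataFrame]
    pfms: dict[str, pd.DataFrame]

    @property
    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for pid, fam in self.assignment.items():
            if fam != SINGLETON:
                fams.setdefault(fam, []).append(pid)
        return fams


def discover_families(
    sequences: dict[str, str] | pd.Series,
    identity_threshold: float = IDENTITY_THRESHOLD,
    min_family_size: int = MIN_FAMILY_SIZE,
) -> tuple[FamilyAssignment, pd.DataFrame]:
    """Identity matrix -> single-linkage families -> alignments and PFMs."""
    seqs = pd.Series(sequences)
    matrix = build_identity_matrix(seqs)
    assignment = cluster_families(matrix, identity_threshold, min_family_size)
    alignments: dict[str, pd.DataFrame] = {}
    pfms: dict[str, pd.DataFrame] = {}
    for fam, members in sorted(
        assignment[assignment != SINGLETON].groupby(assignment).groups.items()
    ):
        fam_seqs = seqs.loc[list(members)]
        aln = center_star_msa(fam_seqs)
        alignments[fam] = aln
        pfms[fam] = position_frequency_matrix(aln)
    return FamilyAssignment(assignment, alignments, pfms), matrix


def family_profile(
    assignment: pd.Series,
    map_table: pd.DataFrame,
    property_table: pd.DataFrame,
    score_columns: tuple[str, ...] = ("pct_idr", "pct_lcr", "plaac_score_adjusted"),
) -> pd.DataFrame:
    """Per-family temporal and property chart.

    One row per family: member count, median and modal peak hour, and
    mean +/- SEM of each property column present.  Families are ordered by
    median peak hour.  Members missing from either table are excluded with a
    warning.
    """
    map_idx = map_table.set_index("gene_id") if "gene_id" in map_table.columns else map_table
    rows = []
    for fam, members in assignment[assignment != SINGLETON].groupby(assignment).groups.items():
        members = [str(m) for m in members]
        in_map = [m for m in members if m in map_idx.index]
        in_prop = [m for m in members if m in property_table.index]
        if len(in_map) < len(members) or len(in_prop) < len(members):
            logger.warning(
                "family_profile: %s has %d/%d members in map, %d/%d in properties",
                fam, len(in_map), len(members), len(in_prop), len(members),
            )
        hours = map_idx.loc[in_map, "peak_hour"].dropna().astype(int)
        row: dict[str, object] = {
            "family": fam,
            "n": len(members),
            "median_peak_hour": float(hours.median()) if len(hours) else np.nan,
            "modal_peak_hour": int(hours.mode().iloc[0]) if len(hours) else pd.NA,
        }
        for col in score_columns:
            if col not in property_table.columns:
                continue
            v = property_table.loc[in_prop, col].dropna().to_numpy(dtype=float)
            row[f"mean_{col}"] = v.mean() if len(v) else np.nan
            row[f"sem_{col}"] = (
                v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
            )
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["median_peak_hour", "family"], kind="stable"
    ).reset_index(drop=True)
    return out
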