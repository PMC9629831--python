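"""End-to-end orchestration: simulate -> map -> enrich -> properties -> families.

:func:`run_pipeline` executes the full analysis on a synthetic bundle (or any
bundle of the same shape) and returns a :class:`ReportBundle` whose tables
mirror the published map: the phase-sorted gene map with molt overlay, the
tissue enrichment and secretome partition with stratified signal-peptide
fractions, binned abundance and transcript-weighted property waves, and the
low-complexity family chart.  :func:`report_from_master` consumes an already
phase-annotated master table (pass-through mode) instead of fitting phases.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from moltmap import __version__
from moltmap.errors import InputError
from moltmap.expression_enrichment import (
    SIGNALP_CUTOFF,
    bin_abundance_profile,
    classify_tissue_enriched,
    partition_secretome,
    summarize_secretome_strata,
)
from moltmap.family_analysis import discover_families, family_profile
from moltmap.sequence_properties import (
    build_property_table,
    property_enrichment,
    trim_signal_peptide,
    weighted_property_profile,
)
from moltmap.synthetic_data import SimConfig, SyntheticData, simulate
from moltmap.temporal_map import (
    MapTable,
    build_map_table,
    overlay_molt,
    passthrough_map_table,
    peak_molt_hour,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and mode selection for one pipeline run."""

    sim: SimConfig | None = None
    enrich_fold: float = 1.5
    min_tpm: float = 25.0
    signalp_cutoff: float = SIGNALP_CUTOFF
    identity_threshold: float = 30.0
    min_family_size: int = 3
    min_candidate_pct_lcr: float = 20.0
    target_tissue: str = "pharynx"
    outdir: str | None = None

    def provenance(self) -> dict:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return {
            "config": d,
            "config_sha1": hashlib.sha1(blob).hexdigest(),
            "moltmap_version": __version__,
        }


@dataclass
class ReportBundle:
    """All tables of one pipeline run plus summary statistics."""

    map_table: MapTable
    molt_overlap: pd.Series
    molt_hour: int
    enriched: dict[str, set[str]]
    strata: pd.DataFrame
    bin_profiles: dict[str, pd.DataFrame]
    property_table: pd.DataFrame
    property_stats: pd.DataFrame
    weighted_waves: pd.DataFrame
    family_assignment: pd.Series
    family_chart: pd.DataFrame
    identity_matrix: pd.DataFrame
    summary: dict
    provenance: dict

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.map_table.data.to_csv(out / "map.tsv", sep="\t", index=False)
        self.molt_overlap.rename("molt_count").to_csv(out / "molt_overlap.tsv", sep="\t")
        self.strata.to_csv(out / "secretome_strata.tsv", sep="\t", index=False)
        for name, prof in self.bin_profiles.items():
            prof.to_csv(out / f"bin_profile_{name}.tsv", sep="\t", index=False)
        self.property_table.to_csv(out / "property_table.tsv", sep="\t")
        self.property_stats.to_csv(out / "property_stats.tsv", sep="\t", index=False)
        self.weighted_waves.to_csv(out / "weighted_waves.tsv", sep="\t")
        self.family_assignment.rename("family").to_csv(out / "families.tsv", sep="\t")
        self.family_chart.to_csv(out / "family_chart.tsv", sep="\t", index=False)
        self.identity_matrix.to_csv(out / "identity_matrix.tsv", sep="\t")
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2) + "\n")
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str) + "\n"
        )


def run_pipeline(config: PipelineConfig, data: SyntheticData | None = None) -> ReportBundle:
    """Run every stage on a synthetic (or synthetic-shaped) bundle."""
    if data is None:
        if config.sim is None:
            raise InputError("run_pipeline: need either a SimConfig or a data bundle")
        data = simulate(config.sim)
    cfg = data.config
    target = config.target_tissue

    # --- temporal map -----------------------------------------------------
    map_table = build_map_table(data.timecourse, period=cfg.period_hours)
    molt_genes = set(data.truth.loc[data.truth["molt_upregulated"], "gene_id"])
    overlap = overlay_molt(map_table, molt_genes)
    molt_hour = peak_molt_hour(overlap)

    # --- enrichment and secretome ----------------------------------------
    enriched = {
        t: classify_tissue_enriched(
            data.tissue_matrix, t, config.enrich_fold, config.min_tpm
        )
        for t in data.tissue_matrix.columns
    }
    scores = data.signalp_scores.set_index("gene_id")["signalp_score"]
    md = map_table.data
    md["signalp_score"] = md["gene_id"].map(scores)
    md["secreted"] = md["signalp_score"] >= config.signalp_cutoff
    md["tissue_class"] = "non-specific"
    for t, genes in enriched.items():
        md.loc[md["gene_id"].isin(genes), "tissue_class"] = t

    osc = set(md.loc[md["oscillating"], "gene_id"])
    all_genes = set(md["gene_id"])
    osc_enriched = osc & enriched[target]
    strata = summarize_secretome_strata(
        osc_enriched, osc - osc_enriched, all_genes - osc, scores, config.signalp_cutoff
    )
    secreted_all, _ = partition_secretome(sorted(all_genes), scores, config.signalp_cutoff)
    secreted_enriched = osc_enriched & secreted_all

    # --- binned abundance profiles ---------------------------------------
    peak_hours = md.set_index("gene_id")["peak_hour"].dropna().astype(int)
    target_expr = data.tissue_matrix[target]
    # reference line of the binned profiles: the genome-wide average
    # transcript number in the target tissue
    global_mean = float(target_expr.mean())
    bin_profiles = {}
    for name, genes in (
        ("enriched", osc_enriched),
        ("enriched_secreted", secreted_enriched),
        ("enriched_non_secreted", osc_enriched - secreted_all),
    ):
        if genes:
            prof = bin_abundance_profile(
                sorted(genes), target_expr, peak_hours, global_mean=global_mean
            )
            bin_profiles[name] = prof.table

    # --- sequence properties ----------------------------------------------
    property_table = build_property_table(data.proteins)
    groups = {
        f"{target}_secreted": sorted(secreted_enriched),
        f"{target}_non_secreted": sorted(osc_enriched - secreted_all),
        "non_specific": sorted(all_genes - enriched[target]),
    }
    property_stats = property_enrichment(groups, property_table["pct_lcr"])
    waves = {}
    for col in ("pct_lcr", "pct_idr"):
        waves[col] = weighted_property_profile(
            target_expr.loc[sorted(secreted_enriched)],
            property_table[col],
            peak_hours,
        )
    weighted_waves = pd.DataFrame(waves)

    # --- family discovery -------------------------------------------------
    seqs = {p.protein_id: p.sequence for p in data.proteins}
    candidates = {
        g: trim_signal_peptide(seqs[g])
        for g in sorted(secreted_enriched)
        if g in seqs
        and len(seqs[g]) > 20
        and property_table.loc[g, "pct_lcr"] >= config.min_candidate_pct_lcr
    }
    if len(candidates) >= 2:
        families, identity_matrix = discover_families(
            candidates, config.identity_threshold, config.min_family_size
        )
        family_assignment = families.assignment
        family_chart = family_profile(family_assignment, md, property_table)
    else:
        logger.warning("run_pipeline: <2 family candidates; skipping family stage")
        family_assignment = pd.Series(dtype=object, name="family")
        family_chart = pd.DataFrame()
        identity_matrix = pd.DataFrame()

    n_families = int((family_assignment[family_assignment != "singleton"]).nunique())
    summary = {
        "n_genes": len(md),
        "n_oscillating": len(osc),
        "n_enriched_target": len(enriched[target]),
        "n_oscillating_enriched": len(osc_enriched),
        "n_secreted_enriched": len(secreted_enriched),
        "molt_hour": int(molt_hour),
        "global_mean_tpm": global_mean,
        "secretome_fractions": {
            r.stratum: r.fraction for r in strata.itertuples()
        },
        "n_family_candidates": len(candidates),
        "n_families": n_families,
    }
    logger.info("run_pipeline summary: %s", summary)
    return ReportBundle(
        map_table=map_table,
        molt_overlap=overlap,
        molt_hour=molt_hour,
        enriched=enriched,
        strata=strata,
        bin_profiles=bin_profiles,
        property_table=property_table,
        property_stats=property_stats,
        weighted_waves=weighted_waves,
        family_assignment=family_assignment,
        family_chart=family_chart,
        identity_matrix=identity_matrix,
        summary=summary,
        provenance=config.provenance(),
    )


def report_from_master(
    master: pd.DataFrame,
    target: str = "pharynx",
    signalp_cutoff: float = SIGNALP_CUTOFF,
) -> dict:
    """Pass-through reproduction of the map statistics from a master table.

    ``master`` carries one row per gene with columns ``gene_id``,
    ``oscillating`` (bool), ``phase_deg`` (degrees, for oscillating genes),
    ``enriched`` (bool: enriched in the target tissue), ``signalp_score``,
    and optionally ``domainless`` (bool) and ``tpm`` (transcript abundance in
    the target tissue).  Phases are taken as given — no fitting — and the
    printed map statistics are recomputed from scratch.
    """
    required = {"gene_id", "oscillating", "phase_deg", "enriched", "signalp_score"}
    missing = required - set(master.columns)
    if missing:
        raise InputError(f"report_from_master: missing columns {sorted(missing)}")
    mt = passthrough_map_table(master)
    md = mt.data.merge(
        master[[c for c in master.columns if c not in ("phase_deg", "oscillating")]],
        on="gene_id",
        how="left",
    )
    scores = master.set_index("gene_id")["signalp_score"]

    osc = set(md.loc[md["oscillating"], "gene_id"])
    enriched = set(master.loc[master["enriched"].astype(bool), "gene_id"])
    all_genes = set(md["gene_id"])
    osc_enriched = osc & enriched
    strata = summarize_secretome_strata(
        osc_enriched, osc - osc_enriched, all_genes - osc, scores, signalp_cutoff
    )
    secreted, _ = partition_secretome(sorted(all_genes), scores, signalp_cutoff)
    secreted_enriched = osc_enriched & secreted

    out = {
        "n_oscillating": len(osc),
        "n_oscillating_enriched": len(osc_enriched),
        "n_secreted_enriched": len(secreted_enriched),
        "pct_secreted_enriched": 100.0 * len(secreted_enriched) / len(osc_enriched)
        if osc_enriched
        else float("nan"),
        "strata": {r.stratum: 100.0 * r.fraction for r in strata.itertuples()},
        "n_enriched_total": len(enriched),
    }
    if "domainless" in master.columns:
        domainless = set(master.loc[master["domainless"].astype(bool), "gene_id"])
        out["n_domainless_secreted"] = len(secreted_enriched & domainless)
    if "tpm" in master.columns:
        tpm = master.set_index("gene_id")["tpm"]
        out["global_mean_tpm"] = float(tpm.loc[sorted(osc)].mean())
    return out
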