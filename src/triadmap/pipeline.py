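"""End-to-end orchestration: simulate -> extract -> contacts -> iCLIP ->
annotate -> differential -> integrate, with recovery metrics against the
planted ground truth.

The stages are exactly the public functions of the per-stage modules;
this module only wires them together and measures recovery, so it
doubles as the reference for how the pieces are meant to be combined on
real inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate as ann
from . import contacts as cm
from . import diffbind as db
from . import iclip as ic
from . import network as net
from .chimera import (
    BridgeSpec,
    GenomeIndex,
    SplitConfig,
    find_bridge_batch,
    revcomp,
    split_at_bridge,
    BridgeHit,
    trim_rna3_anchor,
    validate_rna3,
)
from .synthetic import SyntheticConfig, SyntheticDataset, simulate

#: normalized-frequency floor (contacts per million) separating planted
#: guide contacts from uniform background at the default library depth
DEFAULT_CONTACT_FREQ_THRESHOLD = 50.0


def extract_parts(
    reads1: list[tuple[str, str]],
    reads2: list[tuple[str, str]],
    genome: dict[str, str],
    bridge: BridgeSpec = BridgeSpec(),
    split_cfg: SplitConfig = SplitConfig(),
    index: GenomeIndex | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Deduplicate pairs, find and split bridges, validate 3'-RNA mates,
    align all three parts uniquely.

    Returns (parts table, stats).  The parts table carries one row per
    pair that had a bridge hit, a long-enough split and a valid 3'-RNA
    mate, with per-part unique-alignment flags and loci.
    """
    if index is None:
        index = GenomeIndex(genome)

    # exact duplicate-pair removal, first occurrence wins
    seen: set[tuple[str, str]] = set()
    keep: list[int] = []
    for i, ((_, s1), (_, s2)) in enumerate(zip(reads1, reads2)):
        key = (s1, s2)
        if key not in seen:
            seen.add(key)
            keep.append(i)
    stats = {"n_pairs": len(reads1), "n_after_dedup": len(keep)}

    ids = [reads1[i][0] for i in keep]
    seqs1 = [reads1[i][1] for i in keep]
    seqs2 = [reads2[i][1] for i in keep]

    ori, off, mm = find_bridge_batch(seqs1, bridge)
    stats["n_bridge_found"] = int((ori >= 0).sum())

    rows = []
    n_valid3 = 0
    for j in range(len(ids)):
        if ori[j] < 0:
            continue
        hit = BridgeHit("forward" if ori[j] == 0 else "reverse", int(off[j]), int(mm[j]))
        split = split_at_bridge(seqs1[j], hit, split_cfg, bridge, read_id=ids[j])
        if split is None:
            continue
        if not validate_rna3(seqs2[j]):
            continue
        n_valid3 += 1
        rna3 = trim_rna3_anchor(seqs2[j])
        dna_hit = index.align_unique(split.dna_part)
        rna_hit = index.align_unique(split.rna5_part)
        rna3_hit = index.align_unique(rna3)
        rows.append(
            (
                ids[j],
                split.orientation,
                split.bridge_mismatches,
                *(dna_hit if dna_hit else ("", -1, "")),
                dna_hit is not None,
                *(rna_hit if rna_hit else ("", -1, "")),
                rna_hit is not None,
                *(rna3_hit if rna3_hit else ("", -1, "")),
                rna3_hit is not None,
            )
        )
    stats["n_valid_rna3"] = n_valid3
    parts = pd.DataFrame(
        rows,
        columns=[
            "read_id", "orientation", "mismatches",
            "dna_chrom", "dna_pos", "dna_strand", "dna_unique",
            "rna_chrom", "rna_pos", "rna_strand", "rna_unique",
            "rna3_chrom", "rna3_pos", "rna3_strand", "rna3_unique",
        ],
    )
    stats["n_split"] = len(parts)
    return parts, stats


@dataclass
class PipelineResult:
    """Everything the end-to-end run computes, plus recovery metrics."""

    dataset: SyntheticDataset
    parts: pd.DataFrame
    extract_stats: dict
    contact_table: pd.DataFrame
    recovered_contacts: pd.DataFrame
    contact_recall: float
    contact_precision: float
    sites: pd.DataFrame
    site_recall: float
    site_precision: float
    coverages: pd.DataFrame
    biotype_enrichment: pd.DataFrame
    candidates: pd.DataFrame
    guide_ranks: dict[str, int]
    lost_sets: dict[str, set]
    differential: dict[str, pd.DataFrame]
    target_recall: dict[str, float]
    protac_lost: set
    protac_recall: float
    links: pd.DataFrame
    upset: pd.DataFrame
    attribution: dict
    hub_histograms: dict[str, pd.Series]
    deg_recovery: dict[str, float]
    peak_rna_class: pd.Series
    trans_peak_enhancer_fraction: float
    summary: dict = field(default_factory=dict)


def run_all(
    config: SyntheticConfig,
    contact_freq_threshold: float = DEFAULT_CONTACT_FREQ_THRESHOLD,
) -> PipelineResult:
    """Run every stage on a freshly simulated dataset and score recovery."""
    ds = simulate(config)
    truth = ds.truth
    chrom_sizes = {c: len(s) for c, s in ds.genome.items()}

    # --- chimera extraction ------------------------------------------------
    bridge = BridgeSpec(bridge_sequence=config.bridge_sequence)
    parts, stats = extract_parts(ds.reads1, ds.reads2, ds.genome, bridge)

    # --- contact map -------------------------------------------------------
    ccfg = cm.ContactConfig(bin_width=config.bin_width, trans_distance=config.trans_distance)
    table, drops = cm.assign_contacts(parts, ds.genes, chrom_sizes, ccfg)
    table = cm.normalize(table, ccfg)
    table = cm.classify_cis_trans(table, ds.genes, ccfg)
    recovered = table[table.normalized_frequency >= contact_freq_threshold]

    truth_pairs = {
        (g, t) for g, targets in truth.guide_targets.items() for t in targets
    }
    found_pairs = {
        (r.rna_gene_id, f"{r.chrom}:{r.start}-{r.end}")
        for r in recovered.itertuples(index=False)
        if r.rna_class == "trans"
    }
    contact_recall = len(found_pairs & truth_pairs) / len(truth_pairs)
    contact_precision = (
        len(found_pairs & truth_pairs) / len(found_pairs) if found_pairs else 0.0
    )

    # --- iCLIP -------------------------------------------------------------
    icfg = ic.IclipConfig(n_replicates=config.n_iclip_replicates)
    pooled = (
        pd.concat(ds.iclip_replicates)
        .groupby(["chrom", "pos"], as_index=False)["count"].sum()
    )
    iclip_lib = float(pooled["count"].sum())
    iclip_cov = ic.coverage_per_gene(pooled, ds.genes, iclip_lib)
    rna_lib = float(ds.expression["count"].sum())
    lengths = (ds.genes.end - ds.genes.start).to_numpy()
    rnaseq_cov = pd.DataFrame(
        {
            "gene_id": ds.genes.gene_id,
            "biotype": ds.genes.biotype,
            "events": ds.expression["count"].to_numpy(),
            "rpkm": ds.expression["count"].to_numpy() * 1e9 / (lengths * rna_lib),
        }
    )
    coverages = ic.gene_coverage_table(iclip_cov, rnaseq_cov)
    sites = ic.call_binding_sites(ds.iclip_replicates, ds.iclip_scores, icfg, ds.genes)
    site_recall, site_precision = _site_overlap_metrics(sites, ds)
    cpm = pd.Series(
        (ds.expression["count"] / rna_lib * 1e6).to_numpy(), index=ds.expression.gene_id
    )
    biotype_enr = ic.biotype_site_enrichment(sites, coverages, cpm, icfg)

    contact_genes = set(table.rna_gene_id)
    site_genes = set(sites.gene_id.dropna())
    presence = pd.DataFrame(
        {
            "gene_id": ds.genes.gene_id,
            "in_redc": ds.genes.gene_id.isin(contact_genes),
            "in_redchip": ds.genes.gene_id.isin(contact_genes),
            "has_site": ds.genes.gene_id.isin(site_genes),
            "expressed": ds.genes.gene_id.map(cpm) > icfg.expression_cpm_threshold,
        }
    )
    candidates = ic.stratify_candidates(coverages, sites, presence, icfg)
    ranks = candidates.set_index("gene_id")["rank"]
    guide_ranks = {
        g: int(ranks[g]) if g in ranks.index else -1 for g in ds.guides
    }

    # --- differential binding ---------------------------------------------
    dcfg = db.DiffConfig()
    wide = ds.brg1_counts.pivot_table(
        index="peak_id", columns=["condition", "replicate"], values="count"
    )
    wide.columns = [f"{c}_rep{r}" for c, r in wide.columns]
    cond_of = {col: col.rsplit("_rep", 1)[0] for col in wide.columns}
    lost_sets: dict[str, set] = {}
    differential: dict[str, pd.DataFrame] = {}
    target_recall: dict[str, float] = {}
    for guide in ds.guides:
        cond = f"si{guide}"
        cols = [c for c in wide.columns if cond_of[c] in ("control", cond)]
        res = db.test_differential(wide[cols], cond_of, "control", cond, dcfg)
        differential[guide] = res
        lost = set(res[res.direction == "lost"].index)
        lost_sets[guide] = lost
        planted = truth.knockdown_lost_peaks[guide]
        target_recall[guide] = len(lost & planted) / len(planted)

    pileups = ds.atac.rename(columns={"control": "c1", "protac": "c2"})[
        ["peak_id", "c1", "c2"]
    ]
    lr = db.poisson_loglr_table(pileups, cfg=dcfg)
    protac_lost = set(lr[lr.direction == "lost"].index)
    protac_recall = len(protac_lost & truth.protac_lost_peaks) / len(
        truth.protac_lost_peaks
    )

    # --- annotation --------------------------------------------------------
    rna_class = pd.Series(
        [
            ann.classify_peak_rna_association(
                (p.chrom, int(p.start), int(p.end)), recovered
            )
            for p in ds.peaks.itertuples(index=False)
        ],
        index=ds.peaks.peak_id,
        name="rna_class",
    )
    seg = ds.segmentations["huvec"]
    trans_peaks = ds.peaks[rna_class.to_numpy() == "trans"]
    if len(trans_peaks):
        states = [
            ann.assign_state((p.chrom, int(p.start), int(p.end)), seg)
            for p in trans_peaks.itertuples(index=False)
        ]
        trans_enh_frac = float(np.mean([s == "Strong_Enhancer" for s in states]))
    else:
        trans_enh_frac = float("nan")

    # --- integration -------------------------------------------------------
    ncfg = net.IntegrationConfig()
    elements = ds.peaks[["peak_id", "chrom", "start", "end"]].rename(
        columns={"peak_id": "element_id"}
    )
    elements = elements.merge(ds.activities, on="element_id")
    links = net.compute_abc(elements, ds.loops, ds.genes, ncfg)
    upset = net.lost_enhancer_overlap(lost_sets)
    attribution = net.protac_attribution(protac_lost, lost_sets)

    hub_histograms: dict[str, pd.Series] = {}
    deg_recovery: dict[str, float] = {}
    for guide in ds.guides:
        cond = f"si{guide}"
        degs = set(
            net.filter_degs(ds.deg_tables[cond], ncfg).query("is_deg").gene_id
        )
        hist, linked = net.hub_degree(lost_sets[guide], links, degs)
        hub_histograms[guide] = hist
        planted = truth.planted_degs[cond]
        deg_recovery[guide] = (
            len(linked & planted) / len(planted) if planted else float("nan")
        )

    summary = {
        "bridge_detection_rate": stats["n_bridge_found"] / stats["n_after_dedup"],
        "contact_recall": contact_recall,
        "contact_precision": contact_precision,
        "site_recall": site_recall,
        "site_precision": site_precision,
        "guides_in_top_n": sum(
            1 for g, r in guide_ranks.items() if 0 < r <= config.n_guides
        ),
        "mean_target_recall": float(np.mean(list(target_recall.values()))),
        "protac_recall": protac_recall,
        "attributed_fraction": attribution["attributed_fraction"],
        "mean_deg_recovery": float(np.mean(list(deg_recovery.values()))),
        "trans_peak_enhancer_fraction": trans_enh_frac,
    }
    return PipelineResult(
        dataset=ds,
        parts=parts,
        extract_stats=stats,
        contact_table=table,
        recovered_contacts=recovered,
        contact_recall=contact_recall,
        contact_precision=contact_precision,
        sites=sites,
        site_recall=site_recall,
        site_precision=site_precision,
        coverages=coverages,
        biotype_enrichment=biotype_enr,
        candidates=candidates,
        guide_ranks=guide_ranks,
        lost_sets=lost_sets,
        differential=differential,
        target_recall=target_recall,
        protac_lost=protac_lost,
        protac_recall=protac_recall,
        links=links,
        upset=upset,
        attribution=attribution,
        hub_histograms=hub_histograms,
        deg_recovery=deg_recovery,
        peak_rna_class=rna_class,
        trans_peak_enhancer_fraction=trans_enh_frac,
        summary=summary,
    )


def _site_overlap_metrics(sites: pd.DataFrame, ds: SyntheticDataset):
    """Overlap-based recall/precision of called sites vs planted windows."""
    gidx = ds.genes.set_index("gene_id")
    planted: list[tuple[str, int, int]] = []
    for gene_id, wins in ds.truth.planted_binding_sites.items():
        chrom = gidx.loc[gene_id, "chrom"]
        planted.extend((chrom, s, s + w) for s, w in wins)
    if not planted or len(sites) == 0:
        return 0.0, 0.0
    called = [(r.chrom, int(r.start), int(r.end)) for r in sites.itertuples(index=False)]

    def overlaps(a, pool):
        return any(a[0] == b[0] and a[1] < b[2] and a[2] > b[1] for b in pool)

    by_chrom: dict[str, list] = {}
    for c in called:
        by_chrom.setdefault(c[0], []).append(c)
    pl_by_chrom: dict[str, list] = {}
    for p in planted:
        pl_by_chrom.setdefault(p[0], []).append(p)
    recall = float(
        np.mean([overlaps(p, by_chrom.get(p[0], [])) for p in planted])
    )
    precision = float(
        np.mean([overlaps(c, pl_by_chrom.get(c[0], [])) for c in called])
    )
    return recall, precision
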