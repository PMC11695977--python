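"""Synthetic multi-omic dataset with planted lncRNA-to-enhancer guidance.

Generates a miniature genome plus every input the downstream stages
consume: bridge-containing chimeric read pairs (RNA-DNA proximity
ligation), per-nucleotide crosslink tracks for five iCLIP replicates,
consensus peak sets with replicate count matrices for control /
knockdown / PROTAC conditions, an enhancer-promoter loop table with
activities, and per-condition differential-expression tables.  A
:class:`GroundTruthManifest` records what was planted so recovery can be
measured exactly.

Each artifact type draws from its own RNG stream (``seed + offset``) so
regenerating one file never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chimera import DEFAULT_BRIDGE, revcomp

_STREAM = {
    "reference": 0,
    "expression": 1,
    "fastq": 2,
    "iclip": 3,
    "peaks": 4,
    "hic_deg": 5,
    "segmentation": 6,
}

_BASES = np.array(list("ACGT"))


def _rng(config: "SyntheticConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(config.seed + _STREAM[stream])


@dataclass
class SyntheticConfig:
    """Study conditions for the planted dataset.

    Defaults are the conditions every recovery test runs under: a
    3 x 12 Mb genome, 300 genes, five guide lncRNAs with 40 distal
    (>5 Mb or interchromosomal) target enhancer bins each, 100k chimeric
    reads with 30% uniform background, a 2% per-base bridge substitution
    rate, negative-binomial peak counts at dispersion 0.1 with an
    8-fold knockdown drop over 3 replicates.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 12_000_000
    n_genes: int = 300
    biotype_fractions: dict = field(
        default_factory=lambda: {
            "lncRNA": 0.25,
            "protein_coding": 0.60,
            "snoRNA": 0.05,
            "snRNA": 0.05,
            "miRNA": 0.05,
        }
    )
    n_guides: int = 5
    targets_per_guide: int = 40
    n_contacts: int = 100_000
    background_contact_fraction: float = 0.3
    bridge_mutation_rate: float = 0.02
    n_iclip_replicates: int = 5
    loops_per_enhancer: tuple = (1, 5)

    # library geometry
    read_length: int = 100
    bridge_sequence: str = DEFAULT_BRIDGE
    duplication_rate: float = 0.0
    min_part_length_generated: int = 20

    # genome / annotation
    bin_width: int = 5000
    trans_distance: int = 5_000_000
    gene_length_range: tuple = (1000, 5000)

    # expression
    guide_expression_count: int = 8000
    expressed_fraction: float = 0.8

    # iCLIP planting
    sites_per_guide: int = 20
    decoy_lnc_genes: int = 10
    decoy_lnc_sites: int = 3
    decoy_pc_genes: int = 5
    decoy_pc_sites: int = 1
    iclip_noise_events_per_replicate: int = 2000

    # peak matrices
    n_background_peaks: int = 800
    peak_width: int = 600
    peak_base_mean: float = 200.0
    knockdown_fold: float = 8.0
    dispersion: float = 0.1
    n_peak_replicates: int = 3
    protac_fold: float = 10.0
    atac_base_mean: float = 300.0
    n_protac_extra_lost: int = 50

    # loops
    max_promoters_per_gene: int = 6
    contact_range: tuple = (8.0, 12.0)

    def validate(self) -> None:
        total = sum(self.biotype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"biotype_fractions must sum to 1, got {total}")
        if self.chromosome_length < 20 * self.bin_width:
            raise ValueError("chromosome_length must be >= 20 x bin width")
        if self.n_chromosomes < 2 and self.chromosome_length <= self.trans_distance:
            raise ValueError(
                "cannot place distal targets: need >1 chromosome or a "
                "chromosome longer than the trans distance"
            )
        parts = self.read_length - len(self.bridge_sequence)
        if parts < 2 * self.min_part_length_generated:
            raise ValueError("read too short for two parts plus the bridge")


@dataclass
class GroundTruthManifest:
    """What was planted, keyed so recovery is a set comparison."""

    guide_targets: dict[str, set[str]] = field(default_factory=dict)
    planted_binding_sites: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    knockdown_lost_peaks: dict[str, set[str]] = field(default_factory=dict)
    protac_lost_peaks: set[str] = field(default_factory=set)
    planted_degs: dict[str, set[str]] = field(default_factory=dict)
    loop_table: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "guide_targets": {k: sorted(v) for k, v in self.guide_targets.items()},
                "planted_binding_sites": self.planted_binding_sites,
                "knockdown_lost_peaks": {
                    k: sorted(v) for k, v in self.knockdown_lost_peaks.items()
                },
                "protac_lost_peaks": sorted(self.protac_lost_peaks),
                "planted_degs": {k: sorted(v) for k, v in self.planted_degs.items()},
                "loop_table": self.loop_table,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        d = json.loads(text)
        return cls(
            guide_targets={k: set(v) for k, v in d["guide_targets"].items()},
            planted_binding_sites={
                k: [tuple(x) for x in v] for k, v in d["planted_binding_sites"].items()
            },
            knockdown_lost_peaks={
                k: set(v) for k, v in d["knockdown_lost_peaks"].items()
            },
            protac_lost_peaks=set(d["protac_lost_peaks"]),
            planted_degs={k: set(v) for k, v in d["planted_degs"].items()},
            loop_table=d["loop_table"],
        )


@dataclass
class SyntheticDataset:
    """In-memory bundle of every generated artifact."""

    config: SyntheticConfig
    genome: dict[str, str]
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, biotype, is_guide
    expression: pd.DataFrame  # gene_id, count
    reads1: list[tuple[str, str]]  # (read_id, sequence) chimeric mate
    reads2: list[tuple[str, str]]  # 3'-RNA mate
    read_meta: pd.DataFrame
    iclip_replicates: list[pd.DataFrame]  # chrom, pos, count
    iclip_scores: pd.DataFrame  # chrom, pos, score
    peaks: pd.DataFrame  # peak_id, chrom, start, end, is_target, guide
    brg1_counts: pd.DataFrame  # peak_id, condition, replicate, count
    atac: pd.DataFrame  # peak_id, control, protac
    loops: pd.DataFrame  # element_id, gene_id, contact
    activities: pd.DataFrame  # element_id, activity
    deg_tables: dict[str, pd.DataFrame]
    segmentations: dict[str, pd.DataFrame]
    truth: GroundTruthManifest

    @property
    def guides(self) -> list[str]:
        return list(self.truth.guide_targets)


def bin_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


# ---------------------------------------------------------------------------
# reference


def _biotype_counts(config: SyntheticConfig) -> dict[str, int]:
    """Largest-remainder apportionment of n_genes across biotypes."""
    items = list(config.biotype_fractions.items())
    raw = [config.n_genes * f for _, f in items]
    counts = [int(np.floor(r)) for r in raw]
    remainder = config.n_genes - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest frac first
    for i in range(remainder):
        counts[order[i]] += 1
    return {items[i][0]: counts[i] for i in range(len(items))}


def _random_chromosome(rng: np.random.Generator, length: int, forbidden: Sequence[str]) -> str:
    seq = "".join(_BASES[rng.integers(0, 4, size=length)])
    # scrub any (astronomically unlikely) copy of the bridge so detection
    # in reads is unambiguous
    for pattern in forbidden:
        while pattern in seq:
            i = seq.find(pattern)
            patch = "".join(_BASES[rng.integers(0, 4, size=len(pattern))])
            seq = seq[:i] + patch + seq[i + len(pattern):]
    return seq


def generate_reference(config: SyntheticConfig):
    """Random genome plus non-overlapping gene annotation.

    Returns ``(genome, genes)`` where genes is a DataFrame with gene_id,
    chrom, start, end (half-open), strand, biotype and is_guide columns.
    Deterministic under the config seed.
    """
    config.validate()
    rng = _rng(config, "reference")
    forbidden = [config.bridge_sequence, revcomp(config.bridge_sequence)]
    genome = {
        f"chr{i + 1}": _random_chromosome(rng, config.chromosome_length, forbidden)
        for i in range(config.n_chromosomes)
    }

    counts = _biotype_counts(config)
    biotypes = [b for b, c in counts.items() for _ in range(c)]
    rng.shuffle(biotypes)

    lo, hi = config.gene_length_range
    chroms = list(genome)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    gap = 500  # keep genes separated so overlap logic stays trivial
    for gi in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        for attempt in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chromosome_length - length))
            end = start + length
            if all(end + gap <= s or start >= e + gap for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                break
        else:
            raise ValueError("genome too small to place all genes without overlap")
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"G{gi:04d}", chrom, start, end, strand, biotypes[gi]))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
    )

    lnc = genes.index[genes.biotype == "lncRNA"].to_numpy()
    guide_idx = rng.choice(lnc, size=config.n_guides, replace=False)
    genes["is_guide"] = False
    genes.loc[guide_idx, "is_guide"] = True
    return genome, genes


def _full_bins(config: SyntheticConfig) -> pd.DataFrame:
    w = config.bin_width
    rows = []
    for i in range(config.n_chromosomes):
        chrom = f"chr{i + 1}"
        for s in range(0, config.chromosome_length - w + 1, w):
            rows.append((chrom, s, s + w))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def plant_targets(config: SyntheticConfig, genes: pd.DataFrame) -> dict[str, set[str]]:
    """Pick distal, intergenic target bins for each guide (no bin reused)."""
    rng = np.random.default_rng(config.seed + 100)  # own stream, independent of the genome
    bins = _full_bins(config)
    # intergenic: bin overlaps no gene
    occupied = np.zeros(len(bins), dtype=bool)
    for _, g in genes.iterrows():
        sel = (bins.chrom == g.chrom) & (bins.start < g.end) & (bins.end > g.start)
        occupied |= sel.to_numpy()
    eligible = bins[~occupied]

    used: set[int] = set()
    guide_targets: dict[str, set[str]] = {}
    for _, g in genes[genes.is_guide].iterrows():
        distal = eligible[
            (eligible.chrom != g.chrom)
            | (eligible.start > g.end + config.trans_distance)
            | (eligible.end + config.trans_distance < g.start)
        ]
        pool = [i for i in distal.index if i not in used]
        if len(pool) < config.targets_per_guide:
            raise ValueError("not enough distal intergenic bins for targets")
        chosen = rng.choice(pool, size=config.targets_per_guide, replace=False)
        used.update(int(i) for i in chosen)
        guide_targets[g.gene_id] = {
            bin_id(bins.chrom[i], int(bins.start[i]), int(bins.end[i])) for i in chosen
        }
    return guide_targets


# ---------------------------------------------------------------------------
# expression


def generate_expression(config: SyntheticConfig, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene RNA-seq counts; guides sit in the top expression percentiles."""
    rng = _rng(config, "expression")
    n = len(genes)
    expressed = rng.random(n) < config.expressed_fraction
    counts = np.where(
        expressed,
        np.round(rng.lognormal(np.log(800.0), 0.8, size=n)),
        rng.poisson(0.3, size=n),
    ).astype(int)
    counts[genes.is_guide.to_numpy()] = config.guide_expression_count
    return pd.DataFrame({"gene_id": genes.gene_id, "count": counts})


# ---------------------------------------------------------------------------
# chimeric FASTQ


def generate_chimeric_fastq(
    config: SyntheticConfig,
    genome: dict[str, str],
    genes: pd.DataFrame,
    truth: GroundTruthManifest,
):
    """Paired bridge-containing reads: mate 1 = DNA + bridge + 5'-RNA,
    mate 2 = GGG-anchored 3'-RNA fragment from the same gene.

    Signal reads pair a guide RNA with one of its planted target bins;
    background reads pair a random gene with a random genomic bin.
    Returns (reads1, reads2, meta) with per-read bookkeeping.
    """
    rng = _rng(config, "fastq")
    bridge = config.bridge_sequence
    blen = len(bridge)
    parts_total = config.read_length - blen
    min_part = config.min_part_length_generated
    guides = sorted(truth.guide_targets)
    guide_rows = genes.set_index("gene_id").loc[guides]
    gene_rows = genes.reset_index(drop=True)
    bins = _full_bins(config)

    n = config.n_contacts
    is_bg = rng.random(n) < config.background_contact_fraction
    guide_pick = rng.integers(0, len(guides), size=n)
    gene_pick = rng.integers(0, len(gene_rows), size=n)
    bin_pick = rng.integers(0, len(bins), size=n)
    dna_lens = rng.integers(min_part, parts_total - min_part + 1, size=n)
    reverse = rng.random(n) < 0.5
    target_lists = {g: sorted(truth.guide_targets[g]) for g in guides}
    target_pick = rng.integers(0, config.targets_per_guide, size=n)

    mate2_len = config.read_length - 3

    reads1, reads2, meta = [], [], []
    for i in range(n):
        if is_bg[i]:
            g = gene_rows.iloc[gene_pick[i]]
            b = bins.iloc[bin_pick[i]]
            bchrom, bstart, bend = b.chrom, int(b.start), int(b.end)
        else:
            gid = guides[guide_pick[i]]
            g = guide_rows.loc[gid]
            tid = target_lists[gid][target_pick[i]]
            bchrom, rest = tid.split(":")
            bstart, bend = map(int, rest.split("-"))
        dna_len = int(dna_lens[i])
        rna_len = parts_total - dna_len
        ds = int(rng.integers(bstart, bend - dna_len + 1))
        dna = genome[bchrom][ds : ds + dna_len]
        gstart, gend, gchrom = int(g.start), int(g.end), g.chrom
        rs = int(rng.integers(gstart, gend - rna_len + 1))
        rna = genome[gchrom][rs : rs + rna_len]

        bcopy = list(bridge)
        n_mut = 0
        if config.bridge_mutation_rate > 0:
            hits = np.nonzero(rng.random(blen) < config.bridge_mutation_rate)[0]
            for j in hits:
                old = bcopy[j]
                choices = [c for c in "ACGT" if c != old]
                bcopy[j] = choices[int(rng.integers(3))]
            n_mut = len(hits)
        read = dna + "".join(bcopy) + rna
        if reverse[i]:
            read = revcomp(read)

        r2s = int(rng.integers(gstart, gend - mate2_len + 1))
        mate2 = "GGG" + genome[gchrom][r2s : r2s + mate2_len]

        rid = f"read{i}"
        gene_id = g.name if isinstance(g.name, str) else g.gene_id
        reads1.append((rid, read))
        reads2.append((rid, mate2))
        meta.append(
            (
                rid,
                not is_bg[i],
                gene_id,
                bin_id(bchrom, bstart, bend),
                "reverse" if reverse[i] else "forward",
                n_mut,
            )
        )

    if config.duplication_rate > 0:
        k = int(round(config.duplication_rate * n))
        dup_idx = rng.integers(0, n, size=k)
        for j, src in enumerate(dup_idx):
            rid = f"dup{j}"
            reads1.append((rid, reads1[src][1]))
            reads2.append((rid, reads2[src][1]))
            meta.append((rid, False, "", "", "duplicate", 0))

    meta_df = pd.DataFrame(
        meta,
        columns=["read_id", "is_signal", "gene_id", "bin_id", "orientation", "bridge_mismatches"],
    )
    return reads1, reads2, meta_df


# ---------------------------------------------------------------------------
# iCLIP


def generate_iclip_replicates(
    config: SyntheticConfig,
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    truth: GroundTruthManifest,
):
    """Five per-nt crosslink-event tracks plus a pooled score track.

    Planted 7-nt sites put events on their three central positions in
    every replicate; noise events are sparse, single-replicate and
    low-score, spread uniformly over gene bodies.  Site windows are
    recorded in ``truth.planted_binding_sites`` as (start, 7) with the
    start being the left edge of the 7-nt window.
    """
    rng = _rng(config, "iclip")
    cpm = expression["count"] / max(expression["count"].sum(), 1) * 1e6
    expr = expression.assign(cpm=cpm).set_index("gene_id")
    gidx = genes.set_index("gene_id")

    guides = sorted(genes[genes.is_guide].gene_id)
    lnc_pool = [
        g
        for g in genes[(genes.biotype == "lncRNA") & (~genes.is_guide)].gene_id
        if expr.loc[g, "cpm"] > 5
    ]
    pc_pool = [
        g
        for g in genes[genes.biotype == "protein_coding"].gene_id
        if expr.loc[g, "cpm"] > 5
    ]
    decoy_lnc = list(rng.choice(lnc_pool, size=min(config.decoy_lnc_genes, len(lnc_pool)), replace=False))
    decoy_pc = list(rng.choice(pc_pool, size=min(config.decoy_pc_genes, len(pc_pool)), replace=False))

    plan = [(g, config.sites_per_guide) for g in guides]
    plan += [(g, config.decoy_lnc_sites) for g in decoy_lnc]
    plan += [(g, config.decoy_pc_sites) for g in decoy_pc]

    n_rep = config.n_iclip_replicates
    rep_events = [dict() for _ in range(n_rep)]  # (chrom, pos) -> count

    def add(rep, chrom, pos, count):
        key = (chrom, int(pos))
        rep_events[rep][key] = rep_events[rep].get(key, 0) + int(count)

    planted: dict[str, list[tuple[int, int]]] = {}
    for gene_id, n_sites in plan:
        g = gidx.loc[gene_id]
        candidates = np.arange(g.start + 10, g.end - 10, 25)
        centers = rng.choice(candidates, size=min(n_sites, len(candidates)), replace=False)
        sites = []
        for c in np.sort(centers):
            c = int(c)
            sites.append((c - 3, 7))
            for rep in range(n_rep):
                for dp in (-1, 0, 1):
                    add(rep, g.chrom, c + dp, 1 + rng.poisson(1.0))
                for dp in (-2, 2):
                    if rng.random() < 0.3:
                        add(rep, g.chrom, c + dp, 1)
        planted[gene_id] = sites
    truth.planted_binding_sites = planted

    # noise: uniform over concatenated gene bodies, one event per draw
    gene_arr = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    lengths = (gene_arr.end - gene_arr.start).to_numpy()
    cum = np.concatenate([[0], np.cumsum(lengths)])
    total_bp = int(cum[-1])
    for rep in range(n_rep):
        draws = rng.integers(0, total_bp, size=config.iclip_noise_events_per_replicate)
        gi = np.searchsorted(cum, draws, "right") - 1
        for d, j in zip(draws, gi):
            pos = int(gene_arr.start[j] + (d - cum[j]))
            add(rep, gene_arr.chrom[j], pos, 1)

    replicates = []
    for rep in range(n_rep):
        items = sorted(rep_events[rep].items())
        replicates.append(
            pd.DataFrame(
                [(c, p, v) for (c, p), v in items], columns=["chrom", "pos", "count"]
            )
        )

    pooled: dict[tuple[str, int], int] = {}
    for rep in range(n_rep):
        for key, v in rep_events[rep].items():
            pooled[key] = pooled.get(key, 0) + v
    items = sorted(pooled.items())
    scores = pd.DataFrame(
        [
            (c, p, v + rng.uniform(0.0, 1.0))
            for (c, p), v in items
        ],
        columns=["chrom", "pos", "score"],
    )
    return replicates, scores


# ---------------------------------------------------------------------------
# peak sets and count matrices


def generate_peaksets(
    config: SyntheticConfig,
    genes: pd.DataFrame,
    truth: GroundTruthManifest,
):
    """Consensus peaks plus BRG1 replicate counts and ATAC pileups.

    One peak is centred in every planted target bin; background peaks
    fall in intergenic space.  Knockdown ``si<guide>`` drops counts at
    that guide's target peaks by ``knockdown_fold``; the PROTAC condition
    drops all target peaks plus extra background peaks by
    ``protac_fold``.
    """
    rng = _rng(config, "peaks")
    w = config.peak_width
    rows = []
    peak_of_bin: dict[str, str] = {}
    i = 0
    for guide in sorted(truth.guide_targets):
        for tid in sorted(truth.guide_targets[guide]):
            chrom, rest = tid.split(":")
            s, e = map(int, rest.split("-"))
            mid = (s + e) // 2
            pid = f"peak{i:05d}"
            rows.append((pid, chrom, mid - w // 2, mid + w // 2, True, guide))
            peak_of_bin[tid] = pid
            i += 1
    # background peaks: intergenic, away from genes and target bins
    taken = [
        (r[1], r[2], r[3]) for r in rows
    ] + [(g.chrom, g.start, g.end) for _, g in genes.iterrows()]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in taken:
        by_chrom.setdefault(chrom, []).append((s, e))
    for _ in range(config.n_background_peaks):
        for attempt in range(1000):
            chrom = f"chr{int(rng.integers(config.n_chromosomes)) + 1}"
            s = int(rng.integers(0, config.chromosome_length - w))
            e = s + w
            if all(e <= a or s >= b for a, b in by_chrom.get(chrom, [])):
                by_chrom.setdefault(chrom, []).append((s, e))
                rows.append((f"peak{i:05d}", chrom, s, e, False, ""))
                i += 1
                break
        else:
            raise ValueError("could not place background peaks")
    peaks = pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end", "is_target", "guide"]
    )

    truth.knockdown_lost_peaks = {
        guide: {peak_of_bin[t] for t in targets}
        for guide, targets in truth.guide_targets.items()
    }
    bg_ids = peaks[~peaks.is_target].peak_id.to_numpy()
    extra = rng.choice(bg_ids, size=min(config.n_protac_extra_lost, len(bg_ids)), replace=False)
    truth.protac_lost_peaks = set(peaks[peaks.is_target].peak_id) | set(extra)

    n_peaks = len(peaks)
    base = rng.lognormal(np.log(config.peak_base_mean), 0.3, size=n_peaks)
    conditions = ["control"] + [f"si{g}" for g in sorted(truth.guide_targets)]
    disp = config.dispersion

    def nb(mu):
        if disp <= 0:
            return np.round(mu).astype(int)
        r = 1.0 / disp
        return rng.negative_binomial(r, r / (r + mu))

    recs = []
    for cond in conditions:
        mu = base.copy()
        if cond.startswith("si"):
            lost = truth.knockdown_lost_peaks[cond[2:]]
            mask = peaks.peak_id.isin(lost).to_numpy()
            mu[mask] = mu[mask] / config.knockdown_fold
        for rep in range(1, config.n_peak_replicates + 1):
            counts = nb(mu)
            recs.extend(zip(peaks.peak_id, [cond] * n_peaks, [rep] * n_peaks, counts))
    brg1 = pd.DataFrame(recs, columns=["peak_id", "condition", "replicate", "count"])

    atac_mu = rng.lognormal(np.log(config.atac_base_mean), 0.3, size=n_peaks)
    protac_mu = atac_mu.copy()
    lost_mask = peaks.peak_id.isin(truth.protac_lost_peaks).to_numpy()
    protac_mu[lost_mask] = protac_mu[lost_mask] / config.protac_fold
    atac = pd.DataFrame(
        {
            "peak_id": peaks.peak_id,
            "control": rng.poisson(atac_mu),
            "protac": rng.poisson(protac_mu),
            "activity": atac_mu,
        }
    )
    return peaks, brg1, atac


# ---------------------------------------------------------------------------
# Hi-C loops, activities, DEG tables


def generate_hic_and_deg_inputs(
    config: SyntheticConfig,
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    atac: pd.DataFrame,
    truth: GroundTruthManifest,
    abc_threshold: float = 0.02,
):
    """Loop/contact table, element activities, per-condition DEG tables.

    Every planted loop is guaranteed to clear the ABC threshold after
    per-gene normalization (contacts are bumped where a crowded promoter
    would dilute a loop below it).  Planted DEGs per condition are the
    genes looped from that condition's lost enhancers.
    """
    rng = _rng(config, "hic_deg")
    pc = genes[genes.biotype == "protein_coding"].copy()
    pc["tss"] = np.where(pc.strand == "+", pc.start, pc.end)
    targets = peaks[peaks.is_target].reset_index(drop=True)
    lo, hi = config.loops_per_enhancer
    in_degree: dict[str, int] = {}
    loop_rows = []
    loop_table: dict[str, list[str]] = {}
    for _, p in targets.iterrows():
        mid = (p.start + p.end) // 2
        # stay inside the canonical +/-5 Mb ABC candidate window
        cand = pc[(pc.chrom == p.chrom) & ((pc.tss - mid).abs() <= 5_000_000)]
        cand = [
            g for g in cand.gene_id
            if in_degree.get(g, 0) < config.max_promoters_per_gene
        ]
        if not cand:
            continue
        k = int(rng.integers(lo, hi + 1))
        chosen = list(rng.choice(cand, size=min(k, len(cand)), replace=False))
        loop_table[p.peak_id] = chosen
        for g in chosen:
            in_degree[g] = in_degree.get(g, 0) + 1
            loop_rows.append((p.peak_id, g, float(rng.uniform(*config.contact_range))))
    loops = pd.DataFrame(loop_rows, columns=["element_id", "gene_id", "contact"])
    activities = atac[["peak_id", "activity"]].rename(columns={"peak_id": "element_id"})

    # guarantee every planted loop clears the ABC threshold
    act = activities.set_index("element_id").activity
    for gene_id, grp in loops.groupby("gene_id"):
        ac = (act.loc[grp.element_id].to_numpy() * grp.contact.to_numpy())
        for _ in range(50):
            share = ac / ac.sum()
            low = share <= abc_threshold
            if not low.any():
                break
            ac[low] *= 2.0
        loops.loc[grp.index, "contact"] = ac / act.loc[grp.element_id].to_numpy()

    truth.loop_table = loop_table

    conditions = [f"si{g}" for g in sorted(truth.guide_targets)] + ["protac"]
    lost_by_cond = {f"si{g}": truth.knockdown_lost_peaks[g] for g in truth.guide_targets}
    lost_by_cond["protac"] = truth.protac_lost_peaks
    deg_tables: dict[str, pd.DataFrame] = {}
    planted_degs: dict[str, set[str]] = {}
    all_genes = genes.gene_id.to_numpy()
    for cond in conditions:
        planted = set()
        for pid in lost_by_cond[cond]:
            planted.update(loop_table.get(pid, []))
        planted_degs[cond] = planted
        n = len(all_genes)
        is_deg = np.isin(all_genes, list(planted))
        sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        log2fc = np.where(
            is_deg,
            sign * rng.uniform(0.8, 3.0, size=n),
            np.clip(rng.normal(0.0, 0.15, size=n), -0.5, 0.5),
        )
        padj = np.where(
            is_deg, rng.uniform(1e-6, 0.01, size=n), rng.uniform(0.2, 1.0, size=n)
        )
        base_mean = np.where(
            is_deg, rng.uniform(50, 500, size=n), rng.uniform(0, 300, size=n)
        )
        deg_tables[cond] = pd.DataFrame(
            {
                "gene_id": all_genes,
                "log2fc": log2fc,
                "pvalue": padj * 0.5,
                "padj": padj,
                "base_mean": base_mean,
            }
        )
    truth.planted_degs = planted_degs
    return loops, activities, deg_tables


# ---------------------------------------------------------------------------
# chromatin-state segmentations (plumbing for annotation stages)


def generate_segmentations(
    config: SyntheticConfig,
    truth: GroundTruthManifest,
    target_cell: str = "huvec",
    other_cells: tuple = ("fibroblast", "keratinocyte"),
):
    """Tiling state BEDs: target bins are Strong_Enhancer in the target
    cell and Repressed/Quiescent elsewhere."""
    rng = _rng(config, "segmentation")
    target_bins = sorted(
        t for targets in truth.guide_targets.values() for t in targets
    )
    parsed = []
    for t in target_bins:
        chrom, rest = t.split(":")
        s, e = map(int, rest.split("-"))
        parsed.append((chrom, s, e))
    parsed.sort()
    segs: dict[str, pd.DataFrame] = {}
    for cell in (target_cell,) + tuple(other_cells):
        rows = []
        for ci in range(config.n_chromosomes):
            chrom = f"chr{ci + 1}"
            cursor = 0
            for bchrom, s, e in parsed:
                if bchrom != chrom:
                    continue
                if s > cursor:
                    rows.append((chrom, cursor, s, "Quiescent"))
                if cell == target_cell:
                    state = "Strong_Enhancer"
                else:
                    state = "Repressed" if rng.random() < 0.5 else "Quiescent"
                rows.append((chrom, s, e, state))
                cursor = e
            if cursor < config.chromosome_length:
                rows.append((chrom, cursor, config.chromosome_length, "Quiescent"))
        segs[cell] = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    return segs


# ---------------------------------------------------------------------------
# orchestration


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the complete planted dataset (deterministic under seed)."""
    genome, genes = generate_reference(config)
    truth = GroundTruthManifest(guide_targets=plant_targets(config, genes))
    expression = generate_expression(config, genes)
    reads1, reads2, meta = generate_chimeric_fastq(config, genome, genes, truth)
    replicates, scores = generate_iclip_replicates(config, genes, expression, truth)
    peaks, brg1, atac = generate_peaksets(config, genes, truth)
    loops, activities, deg_tables = generate_hic_and_deg_inputs(
        config, genes, peaks, atac, truth
    )
    segmentations = generate_segmentations(config, truth)
    return SyntheticDataset(
        config=config,
        genome=genome,
        genes=genes,
        expression=expression,
        reads1=reads1,
        reads2=reads2,
        read_meta=meta,
        iclip_replicates=replicates,
        iclip_scores=scores,
        peaks=peaks,
        brg1_counts=brg1,
        atac=atac,
        loops=loops,
        activities=activities,
        deg_tables=deg_tables,
        segmentations=segmentations,
        truth=truth,
    )
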