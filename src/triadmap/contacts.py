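"""RNA-gene x genomic-bin contact tables from split chimeric reads.

Aligned DNA parts are dropped onto fixed-width genomic bins (5 kb by
default), RNA parts onto annotated genes; a read pair contributes one
contact only when the DNA part maps uniquely to one bin and both RNA
alignments (5' part and 3' mate) map uniquely within the same gene.
Counts are depth-normalized to contacts-per-million, contacts are
classified cis vs trans by the >5 Mb / interchromosomal rule, and
enrichment of contact frequencies inside protein-binding peaks is tested
with a paired Wilcoxon signed-rank test against the out-of-peak
frequencies of the same RNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ContactConfig:
    bin_width: int = 5000
    trans_distance: int = 5_000_000
    norm_scale: float = 1e6  # contacts per million

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.trans_distance <= self.bin_width:
            raise ValueError("trans_distance must exceed bin_width")


def make_bins(chrom_sizes: dict[str, int], cfg: ContactConfig = ContactConfig()) -> pd.DataFrame:
    """Tile each chromosome with half-open bins; the last bin may be short."""
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            warnings.warn(f"skipping zero-length chromosome {chrom}")
            continue
        for s in range(0, size, cfg.bin_width):
            rows.append((chrom, s, min(s + cfg.bin_width, size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class GeneLocator:
    """Maps genomic positions to genes (disjoint intervals, per-chrom sorted arrays)."""

    def __init__(self, genes: pd.DataFrame):
        self._by_chrom = {}
        for chrom, grp in genes.groupby("chrom"):
            g = grp.sort_values("start")
            self._by_chrom[chrom] = (
                g.start.to_numpy(),
                g.end.to_numpy(),
                g.gene_id.to_numpy(),
            )

    def gene_at(self, chrom: str, pos: int) -> str | None:
        if chrom not in self._by_chrom:
            return None
        starts, ends, ids = self._by_chrom[chrom]
        i = np.searchsorted(starts, pos, "right") - 1
        if i >= 0 and pos < ends[i]:
            return str(ids[i])
        return None


def assign_contacts(
    parts: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    cfg: ContactConfig = ContactConfig(),
):
    """Aggregate valid split reads into a raw (gene, bin) contact table.

    ``parts`` needs columns: read_id, dna_chrom, dna_pos, dna_unique,
    rna_chrom, rna_pos, rna_unique, rna3_chrom, rna3_pos, rna3_unique.
    Returns (table, drop_report).
    """
    locator = GeneLocator(genes)
    counts: dict[tuple[str, str, int, int], int] = {}
    drops = {"dna_not_unique": 0, "rna_not_unique": 0, "rna_no_gene": 0, "rna_gene_mismatch": 0}
    for row in parts.itertuples(index=False):
        if not row.dna_unique:
            drops["dna_not_unique"] += 1
            continue
        if not (row.rna_unique and row.rna3_unique):
            drops["rna_not_unique"] += 1
            continue
        g5 = locator.gene_at(row.rna_chrom, int(row.rna_pos))
        g3 = locator.gene_at(row.rna3_chrom, int(row.rna3_pos))
        if g5 is None or g3 is None:
            drops["rna_no_gene"] += 1
            continue
        if g5 != g3:
            drops["rna_gene_mismatch"] += 1
            continue
        size = chrom_sizes[row.dna_chrom]
        s = (int(row.dna_pos) // cfg.bin_width) * cfg.bin_width
        e = min(s + cfg.bin_width, size)
        key = (g5, row.dna_chrom, s, e)
        counts[key] = counts.get(key, 0) + 1
    table = pd.DataFrame(
        [(g, c, s, e, n) for (g, c, s, e), n in sorted(counts.items())],
        columns=["rna_gene_id", "chrom", "start", "end", "raw_count"],
    )
    return table, drops


def normalize(table: pd.DataFrame, cfg: ContactConfig = ContactConfig()) -> pd.DataFrame:
    """Add normalized_frequency = raw x norm_scale / total valid contacts."""
    out = table.copy()
    if len(out) == 0:
        out["normalized_frequency"] = pd.Series(dtype=float)
        return out
    total = out.raw_count.sum()
    out["normalized_frequency"] = out.raw_count * cfg.norm_scale / total
    return out


def classify_cis_trans(
    table: pd.DataFrame, genes: pd.DataFrame, cfg: ContactConfig = ContactConfig()
) -> pd.DataFrame:
    """Label each contact cis or trans (strictly more than 5 Mb away, or
    another chromosome)."""
    g = genes.set_index("gene_id")
    gc = g.chrom.to_dict()
    gs = g.start.to_dict()
    ge = g.end.to_dict()
    labels = []
    for row in table.itertuples(index=False):
        gid = row.rna_gene_id
        if row.chrom != gc[gid]:
            labels.append("trans")
            continue
        gap = max(gs[gid] - row.end, row.start - ge[gid], 0)
        labels.append("trans" if gap > cfg.trans_distance else "cis")
    out = table.copy()
    out["rna_class"] = labels
    return out


DEFAULT_STRATA = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, np.inf)


def frequency_distribution(
    redc: pd.DataFrame,
    redchip: pd.DataFrame,
    edges: tuple = DEFAULT_STRATA,
    norm_scale_a: float = 1e6,
    norm_scale_b: float = 1e6,
) -> pd.DataFrame:
    """Unique-pair counts per frequency stratum and RedChIP/Red-C fold change.

    Fold change for an empty Red-C stratum is NaN (undefined), not zero.
    """
    if norm_scale_a != norm_scale_b:
        raise ValueError("tables must be normalized on the same scale")
    edges = np.asarray(edges, dtype=float)
    rows = []
    a = np.histogram(redc.normalized_frequency, bins=edges)[0]
    b = np.histogram(redchip.normalized_frequency, bins=edges)[0]
    for i in range(len(edges) - 1):
        fc = b[i] / a[i] if a[i] > 0 else np.nan
        rows.append((edges[i], edges[i + 1], int(a[i]), int(b[i]), fc))
    return pd.DataFrame(
        rows, columns=["freq_lo", "freq_hi", "redc_pairs", "redchip_pairs", "fold_change"]
    )


def _bins_in_peaks(table: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """True where a contact's bin overlaps any peak (half-open intervals)."""
    flags = np.zeros(len(table), dtype=bool)
    by_chrom = {c: g.sort_values("start") for c, g in peaks.groupby("chrom")}
    for i, row in enumerate(table.itertuples(index=False)):
        grp = by_chrom.get(row.chrom)
        if grp is None:
            continue
        starts = grp.start.to_numpy()
        ends = grp.end.to_numpy()
        j = np.searchsorted(starts, row.end, "left")
        flags[i] = bool((ends[:j] > row.start).any())
    return flags


def peak_overlap_frequencies(table: pd.DataFrame, peaks: pd.DataFrame):
    """In-peak vs out-of-peak contact frequencies, paired per RNA gene.

    Each contact's bin is labeled for peak containment (any overlap);
    per gene the mean in-peak and mean out-of-peak normalized frequency
    form one pair, and a two-sided Wilcoxon signed-rank test is run over
    genes having both.  Returns (labeled table, result dict).
    """
    out = table.copy()
    out["in_peak"] = _bins_in_peaks(table, peaks)
    per_gene = out.groupby(["rna_gene_id", "in_peak"]).normalized_frequency.mean().unstack()
    result = {"statistic": np.nan, "pvalue": np.nan, "n_pairs": 0}
    if True in per_gene.columns and False in per_gene.columns:
        paired = per_gene.dropna()
        if len(paired) >= 2 and not np.allclose(paired[True], paired[False]):
            stat, p = signed_rank_test(paired[True].to_numpy(), paired[False].to_numpy())
            result = {"statistic": float(stat), "pvalue": float(p), "n_pairs": len(paired)}
        else:
            warnings.warn("too few informative pairs for the signed-rank test")
    else:
        warnings.warn("one containment group is empty; signed-rank test skipped")
    return out, result


def signed_rank_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples (exact when
    n <= 25 and there are no zero differences)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return np.nan, 1.0
    method = "exact" if len(d) <= 25 else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def shuffle_peaks(
    peaks: pd.DataFrame,
    chrom_sizes: dict[str, int],
    seed: int,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Relocate each peak uniformly on its own chromosome, preserving
    length, with no overlap among shuffled peaks (rejection sampling)."""
    rng = np.random.default_rng(seed)
    placed: dict[str, list[tuple[int, int]]] = {}
    rows = []
    for row in peaks.itertuples(index=False):
        length = row.end - row.start
        size = chrom_sizes[row.chrom]
        if length > size:
            raise ValueError(f"peak longer than chromosome {row.chrom}")
        for _ in range(max_tries):
            s = int(rng.integers(0, size - length + 1))
            e = s + length
            if all(e <= a or s >= b for a, b in placed.get(row.chrom, [])):
                placed.setdefault(row.chrom, []).append((s, e))
                rows.append(row._replace(start=s, end=e))
                break
        else:
            raise ValueError("chromosome too crowded to place shuffled peaks")
    return pd.DataFrame(rows, columns=peaks.columns)
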