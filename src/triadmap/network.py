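"""Enhancer-gene linking and perturbation integration.

Links candidate elements to gene promoters with an adapted
activity-by-contact (ABC) score: for gene g and element e within the
candidate window, abc(e,g) = A_e C_eg / sum over the gene's candidate
elements, thresholded strictly above 0.02.  Downstream set algebra
produces upset-style exclusive overlaps of lost-enhancer sets, the
fraction of PROTAC-lost enhancers attributable to lncRNA knockdowns,
per-enhancer DEG hub degrees and knockdown-to-KO concordance.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class IntegrationConfig:
    abc_threshold: float = 0.02
    hic_resolution: int = 1000
    candidate_window: int = 5_000_000
    deg_abs_log2fc: float = 0.59
    deg_padj: float = 0.05
    deg_min_mean: float = 5.0

    def __post_init__(self):
        if not (0 < self.abc_threshold < 1):
            raise ValueError("abc_threshold must be in (0, 1)")
        if min(self.deg_abs_log2fc, self.deg_padj, self.deg_min_mean) <= 0:
            raise ValueError("DEG thresholds must be positive")


def compute_abc(
    elements: pd.DataFrame,
    contacts: pd.DataFrame,
    genes: pd.DataFrame,
    cfg: IntegrationConfig = IntegrationConfig(),
    threshold: bool = True,
) -> pd.DataFrame:
    """Per-gene-normalized activity x contact scores.

    ``elements``: element_id, chrom, start, end, activity.  ``contacts``:
    element_id, gene_id, contact.  Only elements within
    ``candidate_window`` of the gene TSS (same chromosome) count.
    Returns links with columns element_id, gene_id, activity, contact,
    abc — thresholded strictly above ``abc_threshold`` unless
    ``threshold=False``.
    """
    el = elements.set_index("element_id")
    g = genes.copy()
    g["tss"] = np.where(g.strand == "+", g.start, g.end) if "strand" in g else g.start
    g = g.set_index("gene_id")
    rows = []
    for gene_id, grp in contacts.groupby("gene_id"):
        if gene_id not in g.index:
            continue
        tss = int(g.loc[gene_id, "tss"])
        gchrom = g.loc[gene_id, "chrom"]
        prods, keep = [], []
        for r in grp.itertuples(index=False):
            if r.element_id not in el.index:
                continue
            e = el.loc[r.element_id]
            mid = (int(e.start) + int(e.end)) // 2
            if e.chrom != gchrom or abs(mid - tss) > cfg.candidate_window:
                continue
            prods.append(float(e.activity) * float(r.contact))
            keep.append((r.element_id, float(e.activity), float(r.contact)))
        denom = sum(prods)
        if denom <= 0:
            warnings.warn(f"gene {gene_id}: zero activity x contact denominator")
            continue
        for (eid, act, con), prod in zip(keep, prods):
            rows.append((eid, gene_id, act, con, prod / denom))
    links = pd.DataFrame(
        rows, columns=["element_id", "gene_id", "activity", "contact", "abc"]
    )
    if threshold and len(links):
        links = links[links.abc > cfg.abc_threshold].reset_index(drop=True)
    return links


def filter_degs(stats: pd.DataFrame, cfg: IntegrationConfig = IntegrationConfig()) -> pd.DataFrame:
    """Flag DEGs: |log2FC| >= 0.59, BH padj <= 0.05, combined mean >= 5.

    Rows with missing padj are excluded with a warning.
    """
    df = stats.copy()
    missing = df.padj.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} genes lack padj; excluded")
        df = df[~missing]
    df["is_deg"] = (
        (df.log2fc.abs() >= cfg.deg_abs_log2fc)
        & (df.padj <= cfg.deg_padj)
        & (df.base_mean >= cfg.deg_min_mean)
    )
    return df


def lost_enhancer_overlap(lost_sets: dict[str, set]) -> pd.DataFrame:
    """Upset-style exclusive intersection counts over named sets.

    Pattern counts sum to the cardinality of the union.
    """
    names = sorted(lost_sets)
    patterns: Counter = Counter()
    for element in set().union(*lost_sets.values()) if lost_sets else set():
        member = frozenset(n for n in names if element in lost_sets[n])
        patterns[member] += 1
    rows = [
        ("+".join(sorted(k)), len(k), v)
        for k, v in sorted(patterns.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["pattern", "degree", "count"])


def protac_attribution(protac_lost: set, knockdown_lost: dict[str, set]) -> dict:
    """Fraction of PROTAC-lost enhancers also lost in any lncRNA knockdown."""
    if not protac_lost:
        raise ValueError("empty PROTAC lost set: attribution undefined")
    union = set().union(*knockdown_lost.values()) if knockdown_lost else set()
    both = protac_lost & union
    return {
        "protac_only": len(protac_lost - union),
        "knockdown_only": len(union - protac_lost),
        "both": len(both),
        "attributed_fraction": len(both) / len(protac_lost),
    }


def hub_degree(
    lost_enhancers: set,
    links: pd.DataFrame,
    deg_genes: set,
) -> tuple[pd.Series, set]:
    """Per lost enhancer, the number of linked DEG promoters.

    Returns (degree histogram indexed by degree, union of linked DEGs).
    """
    sub = links[links.element_id.isin(lost_enhancers)]
    deg_links = sub[sub.gene_id.isin(deg_genes)]
    degree = deg_links.groupby("element_id").gene_id.nunique()
    degree = degree.reindex(sorted(lost_enhancers), fill_value=0)
    hist = degree.value_counts().sort_index()
    hist.index.name = "degree"
    return hist, set(deg_links.gene_id)


def perturbation_concordance(
    lost_a: set, links: pd.DataFrame, degs_b: set
) -> dict:
    """Venn counts between genes linked to lost set A and DEG set B."""
    linked = set(links[links.element_id.isin(lost_a)].gene_id)
    return {
        "linked_only": len(linked - degs_b),
        "deg_only": len(degs_b - linked),
        "overlap": len(linked & degs_b),
    }
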