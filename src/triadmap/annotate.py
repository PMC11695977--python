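"""Peak annotation: genomic context, chromatin state, RNA-association
class and cross-cell-type specificity.

Context labels (promoter / intronic / intergenic) partition any peak
set: the peak midpoint decides, with a strand-aware promoter window
around the TSS taking precedence over gene-body containment.  Chromatin
states come from tiling segmentations (one per cell type); a feature is
cell-type *specific* when it is an enhancer state in the target cell and
repressed/inactive in every other cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AnnotationConfig:
    promoter_upstream: int = 1000
    promoter_downstream: int = 100

    def __post_init__(self):
        if self.promoter_upstream < 0 or self.promoter_downstream < 0:
            raise ValueError("promoter window bounds must be >= 0")


@dataclass(frozen=True)
class SpecificityConfig:
    enhancer_states: frozenset = frozenset({"Strong_Enhancer"})
    inactive_states: frozenset = frozenset({"Repressed", "Quiescent"})


def _promoter_window(tss: int, strand: str, cfg: AnnotationConfig) -> tuple[int, int]:
    if strand == "+":
        return tss - cfg.promoter_upstream, tss + cfg.promoter_downstream
    return tss - cfg.promoter_downstream, tss + cfg.promoter_upstream


def annotate_context(
    peak: tuple[str, int, int],
    genes: pd.DataFrame,
    cfg: AnnotationConfig = AnnotationConfig(),
) -> str:
    """promoter | intronic | intergenic, decided by the peak midpoint."""
    chrom, start, end = peak
    mid = (start + end) // 2
    sub = genes[genes.chrom == chrom]
    for g in sub.itertuples(index=False):
        tss = g.start if g.strand == "+" else g.end
        lo, hi = _promoter_window(tss, g.strand, cfg)
        if lo <= mid <= hi:
            return "promoter"
    for g in sub.itertuples(index=False):
        if g.start <= mid < g.end:
            return "intronic"
    return "intergenic"


def annotate_context_table(
    peaks: pd.DataFrame, genes: pd.DataFrame, cfg: AnnotationConfig = AnnotationConfig()
) -> pd.Series:
    return pd.Series(
        [
            annotate_context((r.chrom, int(r.start), int(r.end)), genes, cfg)
            for r in peaks.itertuples(index=False)
        ],
        index=peaks.index,
        name="context",
    )


def assign_state(peak: tuple[str, int, int], segmentation: pd.DataFrame) -> str:
    """Chromatin state with maximal bp overlap; ties go to the state at
    the peak midpoint; peaks outside the segmentation are 'unannotated'."""
    chrom, start, end = peak
    sub = segmentation[segmentation.chrom == chrom]
    overlaps: dict[str, int] = {}
    mid_state = None
    mid = (start + end) // 2
    for seg in sub.itertuples(index=False):
        bp = min(end, seg.end) - max(start, seg.start)
        if bp > 0:
            overlaps[seg.state] = overlaps.get(seg.state, 0) + bp
        if seg.start <= mid < seg.end:
            mid_state = seg.state
    if not overlaps:
        return "unannotated"
    best = max(overlaps.values())
    winners = sorted(s for s, v in overlaps.items() if v == best)
    if len(winners) > 1 and mid_state in winners:
        return mid_state
    return winners[0]


def classify_peak_rna_association(
    peak: tuple[str, int, int], contacts: pd.DataFrame
) -> str:
    """none | trans | cis | mixed from the cis/trans labels of contacts
    whose bin overlaps the peak (any overlap)."""
    chrom, start, end = peak
    hit = contacts[
        (contacts.chrom == chrom) & (contacts.start < end) & (contacts.end > start)
    ]
    classes = set(hit.rna_class)
    if not classes:
        return "none"
    if classes == {"trans"}:
        return "trans"
    if classes == {"cis"}:
        return "cis"
    return "mixed"


def cell_type_specificity(
    features: pd.DataFrame,
    segmentations: dict[str, pd.DataFrame],
    target_cell: str,
    cfg: SpecificityConfig = SpecificityConfig(),
):
    """Specific vs shared classification of features across cell types.

    A feature is *specific* when its state in the target cell is an
    enhancer state and its state in every other cell type is
    repressed/inactive.  Features unannotated in the target cell are
    excluded.  Returns (calls Series, feature x cell state matrix).
    """
    if len(segmentations) < 2:
        raise ValueError("need segmentations for at least two cell types")
    cells = list(segmentations)
    matrix = pd.DataFrame(index=features.index, columns=cells, dtype=object)
    for cell in cells:
        seg = segmentations[cell]
        matrix[cell] = [
            assign_state((r.chrom, int(r.start), int(r.end)), seg)
            for r in features.itertuples(index=False)
        ]
    annotated = matrix[matrix[target_cell] != "unannotated"]
    others = [c for c in cells if c != target_cell]
    calls = pd.Series("shared", index=annotated.index, name="specificity")
    specific = annotated[target_cell].isin(cfg.enhancer_states) & annotated[others].isin(
        cfg.inactive_states
    ).all(axis=1)
    calls[specific] = "specific"
    return calls, matrix
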