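"""iCLIP coverage enrichment, reproducible binding-site calling and
lncRNA candidate ranking.

Crosslink events are per-nucleotide truncation counts, one track per
replicate, plus a pooled per-position score track.  Binding sites are
called by (1) dropping the lowest 2% of scored positions, (2) greedily
seeding non-overlapping 7-nt windows at the remaining positions in
descending score order, (3) requiring >= 3 event-covered positions in
the pooled track and (4) >= 4 of 5 replicates with at least one event in
the window.  Candidate lncRNAs are ranked by the mean of four z-scored
metrics (iCLIP coverage, expression, coverage enrichment, site count)
standardized over all lncRNAs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class IclipConfig:
    score_percentile_drop: float = 0.02
    site_width: int = 7
    min_covered_positions: int = 3
    min_replicate_support: int = 4
    n_replicates: int = 5
    expression_cpm_threshold: float = 5.0
    top_k: int = 16

    def __post_init__(self):
        if not (0 <= self.score_percentile_drop < 1):
            raise ValueError("score_percentile_drop must be in [0, 1)")
        if self.min_replicate_support > self.n_replicates:
            raise ValueError("replicate support cannot exceed replicate count")
        if self.site_width % 2 == 0:
            raise ValueError("site_width must be odd")


def coverage_per_gene(
    track: pd.DataFrame, genes: pd.DataFrame, library_size: float
) -> pd.DataFrame:
    """Events per gene as RPKM = events x 1e9 / (gene bp x library size).

    ``track`` has columns (chrom, pos, count); genes with no events get
    RPKM 0.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    events = dict.fromkeys(genes.gene_id, 0)
    for chrom, grp in track.groupby("chrom"):
        sub = genes[genes.chrom == chrom].sort_values("start")
        if len(sub) == 0:
            continue
        starts = sub.start.to_numpy()
        ends = sub.end.to_numpy()
        ids = sub.gene_id.to_numpy()
        pos = grp.pos.to_numpy()
        cnt = grp["count"].to_numpy()
        idx = np.searchsorted(starts, pos, "right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        for gid, c in zip(ids[idx[ok]], cnt[ok]):
            events[gid] += int(c)
    lengths = (genes.end - genes.start).to_numpy()
    ev = np.array([events[g] for g in genes.gene_id], dtype=float)
    rpkm = ev * 1e9 / (lengths * library_size)
    return pd.DataFrame(
        {"gene_id": genes.gene_id, "biotype": genes.biotype, "events": ev, "rpkm": rpkm}
    )


def gene_coverage_table(
    iclip_cov: pd.DataFrame, rnaseq_cov: pd.DataFrame
) -> pd.DataFrame:
    """Join iCLIP and RNA-seq RPKMs; enrichment = log2 ratio, defined only
    when both RPKMs are positive."""
    df = iclip_cov[["gene_id", "biotype", "rpkm"]].rename(columns={"rpkm": "iclip_rpkm"})
    df = df.merge(
        rnaseq_cov[["gene_id", "rpkm"]].rename(columns={"rpkm": "rnaseq_rpkm"}),
        on="gene_id",
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.log2(df.iclip_rpkm / df.rnaseq_rpkm)
    enr[(df.iclip_rpkm <= 0) | (df.rnaseq_rpkm <= 0)] = np.nan
    df["enrichment"] = enr
    return df


def class_enrichment(coverages: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of log2(iCLIP/RNA-seq) per biotype.

    Genes with undefined enrichment (zero coverage on either side) are
    excluded; empty classes are omitted with a warning.
    """
    rows = []
    for biotype, grp in coverages.groupby("biotype"):
        vals = grp.enrichment.dropna().to_numpy()
        if len(vals) == 0:
            warnings.warn(f"no genes with defined enrichment in class {biotype}")
            continue
        q = np.percentile(vals, [0, 25, 50, 75, 100])
        rows.append((biotype, len(vals), *q))
    return pd.DataFrame(
        rows, columns=["biotype", "n", "min", "q1", "median", "q3", "max"]
    )


def call_binding_sites(
    replicates: list[pd.DataFrame],
    scores: pd.DataFrame,
    cfg: IclipConfig = IclipConfig(),
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Reproducible fixed-width binding sites from replicate crosslink tracks.

    Returns a DataFrame (chrom, start, end, score, covered_positions,
    replicate_support[, gene_id]) of non-overlapping ``site_width``-nt
    sites.
    """
    if len(scores) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "score", "covered_positions", "replicate_support"]
        )
    half = cfg.site_width // 2

    # (1) drop the lowest fraction of scored crosslink positions (global)
    sc = scores.sort_values(["score", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    n_drop = int(math.floor(cfg.score_percentile_drop * len(sc)))
    kept = sc.iloc[n_drop:]

    pooled: dict[tuple[str, int], int] = {}
    for rep in replicates:
        for row in rep.itertuples(index=False):
            key = (row.chrom, int(row.pos))
            pooled[key] = pooled.get(key, 0) + int(row.count)
    rep_sets = [
        {(row.chrom, int(row.pos)) for row in rep.itertuples(index=False)}
        for rep in replicates
    ]

    # (2) greedy seeding in descending score order, ties by coordinate
    order = kept.sort_values(
        ["score", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    accepted: list[tuple[str, int, int, float]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for row in order.itertuples(index=False):
        s, e = int(row.pos) - half, int(row.pos) + half + 1
        spans = occupied.setdefault(row.chrom, [])
        if any(s < b and e > a for a, b in spans):
            continue
        spans.append((s, e))
        accepted.append((row.chrom, s, e, float(row.score)))

    # (3) + (4) pooled coverage and replicate-support filters
    out = []
    for chrom, s, e, score in accepted:
        covered = sum(1 for p in range(s, e) if pooled.get((chrom, p), 0) > 0)
        if covered < cfg.min_covered_positions:
            continue
        support = sum(
            1
            for rs in rep_sets
            if any((chrom, p) in rs for p in range(s, e))
        )
        if support < cfg.min_replicate_support:
            continue
        out.append((chrom, s, e, score, covered, support))
    sites = pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "score", "covered_positions", "replicate_support"],
    ).sort_values(["chrom", "start"]).reset_index(drop=True)

    if genes is not None and len(sites):
        from .contacts import GeneLocator

        loc = GeneLocator(genes)
        sites["gene_id"] = [
            loc.gene_at(r.chrom, (r.start + r.end) // 2) for r in sites.itertuples(index=False)
        ]
    return sites


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test by full hypergeometric enumeration.

    Returns (odds_ratio, p).  The p-value sums, over the support of the
    hypergeometric distribution with the table's margins, every
    probability not exceeding that of the observed table (with a small
    relative tolerance against float noise).
    """
    n1, n2 = a + b, c + d
    k = a + c
    n = n1 + n2
    lo, hi = max(0, k - n2), min(k, n1)

    def log_pmf(x: int) -> float:
        return (
            math.lgamma(n1 + 1) - math.lgamma(x + 1) - math.lgamma(n1 - x + 1)
            + math.lgamma(n2 + 1) - math.lgamma(k - x + 1) - math.lgamma(n2 - k + x + 1)
            - (math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1))
        )

    obs = log_pmf(a)
    p = sum(
        math.exp(lp) for x in range(lo, hi + 1) if (lp := log_pmf(x)) <= obs + 1e-7
    )
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return odds, min(p, 1.0)


def biotype_site_enrichment(
    sites: pd.DataFrame,
    coverages: pd.DataFrame,
    expression_cpm: pd.Series,
    cfg: IclipConfig = IclipConfig(),
) -> pd.DataFrame:
    """Observed vs expected binding-site counts per biotype.

    The expected proportion of sites per biotype is that biotype's share
    of the expressed-gene universe (CPM > threshold); a 2x2 table of
    observed vs expected-scaled counts per biotype is tested with the
    two-sided Fisher's exact test.
    """
    universe = coverages[
        coverages.gene_id.map(expression_cpm) > cfg.expression_cpm_threshold
    ]
    if len(universe) == 0:
        raise ValueError("no expressed genes in the universe")
    site_genes = sites.dropna(subset=["gene_id"])
    biotype_of = coverages.set_index("gene_id").biotype
    site_biotypes = site_genes.gene_id.map(biotype_of)
    total_sites = len(site_biotypes)
    rows = []
    for biotype, share in universe.biotype.value_counts(normalize=True).items():
        observed = int((site_biotypes == biotype).sum())
        expected = int(round(total_sites * share))
        a, b = observed, total_sites - observed
        c, d = expected, total_sites - expected
        odds, p = fisher_exact_2x2(a, b, c, d)
        rows.append((biotype, observed, expected, share, odds, p))
    return pd.DataFrame(
        rows,
        columns=["biotype", "observed", "expected", "universe_share", "odds_ratio", "pvalue"],
    )


def stratify_candidates(
    coverages: pd.DataFrame,
    sites: pd.DataFrame,
    presence: pd.DataFrame,
    cfg: IclipConfig = IclipConfig(),
) -> pd.DataFrame:
    """Rank lncRNA candidates by the mean of four z-scored metrics.

    ``presence`` has columns gene_id plus boolean flags (all must be
    True for a gene to be a candidate).  Metrics are standardized over
    the full lncRNA universe with defined metrics; the composite is the
    unweighted mean.  Returns all candidates, ranked; callers take the
    top ``cfg.top_k``.
    """
    lnc = coverages[coverages.biotype == "lncRNA"].copy()
    n_sites = sites.dropna(subset=["gene_id"]).gene_id.value_counts()
    lnc["n_binding_sites"] = lnc.gene_id.map(n_sites).fillna(0).astype(int)
    metrics = ["iclip_rpkm", "rnaseq_rpkm", "enrichment", "n_binding_sites"]
    universe = lnc.dropna(subset=["enrichment"])
    zcols = {}
    for m in metrics:
        mu = universe[m].mean()
        sd = universe[m].std(ddof=0)
        zcols[f"z_{m}"] = (universe[m] - mu) / sd if sd > 0 else universe[m] * 0.0
    scored = universe.assign(**zcols)
    scored["composite"] = scored[[f"z_{m}" for m in metrics]].mean(axis=1)

    flags = presence.set_index("gene_id")
    passing = flags.all(axis=1)
    scored = scored[scored.gene_id.map(passing).fillna(False)]
    scored = scored.sort_values(
        ["composite", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    scored["rank"] = np.arange(1, len(scored) + 1)
    if len(scored) < cfg.top_k:
        warnings.warn(
            f"only {len(scored)} candidates pass the presence screen (top_k={cfg.top_k})"
        )
    return scored
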