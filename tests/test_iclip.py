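"""Coverage, binding-site calling, Fisher enrichment and candidate ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from triadmap import iclip as ic


@pytest.fixture
def genes():
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2"],
            "chrom": ["chr1", "chr1"],
            "start": [0, 10_000],
            "end": [1000, 12_000],
            "strand": ["+", "-"],
            "biotype": ["lncRNA", "protein_coding"],
        }
    )


class TestCoveragePerGene:
    def test_rpkm_closed_form(self, genes):
        track = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [100, 200], "count": [4, 6]})
        cov = ic.coverage_per_gene(track, genes, library_size=1e6)
        # 10 events on a 1-kb gene, library 1e6 -> RPKM 10
        assert cov.set_index("gene_id").rpkm["g1"] == pytest.approx(10.0)
        assert cov.set_index("gene_id").rpkm["g2"] == 0.0

    def test_doubling_library_halves_rpkm(self, genes):
        track = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "count": [10]})
        a = ic.coverage_per_gene(track, genes, 1e6).rpkm.iloc[0]
        b = ic.coverage_per_gene(track, genes, 2e6).rpkm.iloc[0]
        assert a == pytest.approx(2 * b)

    def test_matches_bruteforce_counting(self, genes):
        rng = np.random.default_rng(1)
        pos = rng.integers(0, 13_000, size=200)
        cnt = rng.integers(1, 5, size=200)
        track = pd.DataFrame({"chrom": "chr1", "pos": pos, "count": cnt})
        cov = ic.coverage_per_gene(track, genes, 1e6).set_index("gene_id")
        for _, g in genes.iterrows():
            expected = sum(
                int(c) for p, c in zip(pos, cnt) if g.start <= p < g.end
            )
            assert cov.events[g.gene_id] == expected

    def test_zero_library_rejected(self, genes):
        with pytest.raises(ValueError):
            ic.coverage_per_gene(pd.DataFrame(columns=["chrom", "pos", "count"]), genes, 0)


class TestClassEnrichment:
    def test_equal_coverages_give_zero_enrichment(self):
        cov = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "biotype": ["lncRNA", "protein_coding"],
                "iclip_rpkm": [5.0, 2.0],
                "rnaseq_rpkm": [5.0, 2.0],
            }
        )
        cov["enrichment"] = np.log2(cov.iclip_rpkm / cov.rnaseq_rpkm)
        summary = ic.class_enrichment(cov)
        assert (summary["median"] == 0).all()

    def test_five_number_summary_matches_sort_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=101)
        cov = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(101)],
                "biotype": "lncRNA",
                "enrichment": vals,
            }
        )
        row = ic.class_enrichment(cov).iloc[0]
        s = np.sort(vals)
        assert row["min"] == s[0] and row["max"] == s[-1]
        assert row["median"] == pytest.approx(np.median(s))

    def test_planted_excess_recovered(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(200):
            biotype = "lncRNA" if i < 100 else "protein_coding"
            rna = rng.lognormal(0, 0.2)
            excess = 4.0 if biotype == "lncRNA" else 1.0
            rows.append((f"g{i}", biotype, rna * excess * rng.lognormal(0, 0.1), rna))
        cov = pd.DataFrame(rows, columns=["gene_id", "biotype", "iclip_rpkm", "rnaseq_rpkm"])
        cov["enrichment"] = np.log2(cov.iclip_rpkm / cov.rnaseq_rpkm)
        out = ic.class_enrichment(cov).set_index("biotype")
        assert out.loc["lncRNA", "median"] == pytest.approx(2.0, abs=0.15)
        assert out.loc["protein_coding", "median"] == pytest.approx(0.0, abs=0.15)

    def test_empty_class_warns(self):
        cov = pd.DataFrame(
            {"gene_id": ["a"], "biotype": ["snoRNA"], "enrichment": [np.nan]}
        )
        with pytest.warns(UserWarning):
            out = ic.class_enrichment(cov)
        assert len(out) == 0


def oracle_call_sites(replicates, scores, cfg=ic.IclipConfig()):
    """Window-enumeration oracle applying drop/greedy/coverage/support rules."""
    half = cfg.site_width // 2
    sc = scores.sort_values(["score", "chrom", "pos"], kind="mergesort")
    kept = sc.iloc[int(math.floor(cfg.score_percentile_drop * len(sc))):]
    pooled = {}
    for rep in replicates:
        for r in rep.itertuples(index=False):
            pooled[(r.chrom, r.pos)] = pooled.get((r.chrom, r.pos), 0) + r.count
    order = kept.sort_values(["score", "chrom", "pos"], ascending=[False, True, True],
                             kind="mergesort")
    chosen = []
    for r in order.itertuples(index=False):
        win = (r.chrom, r.pos - half, r.pos + half + 1)
        if any(c[0] == win[0] and c[1] < win[2] and c[2] > win[1] for c in chosen):
            continue
        chosen.append(win)
    out = []
    for chrom, s, e in chosen:
        covered = sum(1 for p in range(s, e) if pooled.get((chrom, p), 0) > 0)
        if covered < cfg.min_covered_positions:
            continue
        support = 0
        for rep in replicates:
            hits = rep[(rep.chrom == chrom) & (rep.pos >= s) & (rep.pos < e)]
            if len(hits) > 0:
                support += 1
        if support < cfg.min_replicate_support:
            continue
        out.append((chrom, s, e))
    return sorted(out)


def random_tracks(rng, n_rep=5, length=200):
    replicates = []
    for _ in range(n_rep):
        n = int(rng.integers(3, 15))
        pos = rng.choice(length, size=n, replace=False)
        replicates.append(
            pd.DataFrame({"chrom": "chr1", "pos": np.sort(pos), "count": rng.integers(1, 4, n)})
        )
    pooled_pos = sorted({int(p) for rep in replicates for p in rep.pos})
    scores = pd.DataFrame(
        {"chrom": "chr1", "pos": pooled_pos, "score": rng.uniform(0.1, 10, len(pooled_pos))}
    )
    return replicates, scores


class TestCallBindingSites:
    def test_empty_track_gives_no_sites(self):
        sites = ic.call_binding_sites([], pd.DataFrame(columns=["chrom", "pos", "score"]))
        assert len(sites) == 0

    def test_single_isolated_site(self):
        replicates = [
            pd.DataFrame({"chrom": "chr1", "pos": [99, 100, 101], "count": [1, 2, 1]})
            for _ in range(5)
        ]
        scores = pd.DataFrame({"chrom": "chr1", "pos": [99, 100, 101], "score": [5.0, 9.0, 4.0]})
        sites = ic.call_binding_sites(replicates, scores)
        assert len(sites) == 1
        row = sites.iloc[0]
        assert (row.start, row.end) == (97, 104)
        assert row.covered_positions == 3 and row.replicate_support == 5

    def test_insufficient_replicate_support_filtered(self):
        active = pd.DataFrame({"chrom": "chr1", "pos": [99, 100, 101], "count": [1, 2, 1]})
        empty = pd.DataFrame(columns=["chrom", "pos", "count"])
        scores = pd.DataFrame({"chrom": "chr1", "pos": [99, 100, 101], "score": [5.0, 9.0, 4.0]})
        sites = ic.call_binding_sites([active] * 3 + [empty] * 2, scores)
        assert len(sites) == 0

    def test_sites_never_overlap_and_are_7nt(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            replicates, scores = random_tracks(rng)
            sites = ic.call_binding_sites(replicates, scores)
            assert ((sites.end - sites.start) == 7).all()
            s = sites.sort_values(["chrom", "start"])
            assert (s.start.to_numpy()[1:] >= s.end.to_numpy()[:-1]).all()

    def test_matches_window_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            replicates, scores = random_tracks(rng)
            sites = ic.call_binding_sites(replicates, scores)
            got = sorted(
                (r.chrom, int(r.start), int(r.end)) for r in sites.itertuples(index=False)
            )
            assert got == oracle_call_sites(replicates, scores)

    def test_raising_score_drop_never_adds_sites(self):
        rng = np.random.default_rng(19)
        replicates, scores = random_tracks(rng)
        counts = []
        for drop in (0.0, 0.02, 0.1, 0.3, 0.6):
            cfg = ic.IclipConfig(score_percentile_drop=drop)
            counts.append(len(ic.call_binding_sites(replicates, scores, cfg)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestFisherExact:
    def test_balanced_table_p_one(self):
        _, p = ic.fisher_exact_2x2(5, 5, 5, 5)
        assert p == pytest.approx(1.0)

    def test_documented_table(self):
        odds, p = ic.fisher_exact_2x2(5, 1, 1, 5)
        assert p == pytest.approx(0.08008, abs=1e-4)
        assert odds == 25.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, size=4)
            _, p = ic.fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(sps.fisher_exact([[a, b], [c, d]])[1], rel=1e-9)


class TestBiotypeEnrichment:
    def _inputs(self):
        cov = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "biotype": ["lncRNA"] * 5 + ["protein_coding"] * 5,
            }
        )
        cpm = pd.Series(10.0, index=cov.gene_id)
        return cov, cpm

    def test_sites_only_in_lncrnas_enriched(self):
        cov, cpm = self._inputs()
        sites = pd.DataFrame({"gene_id": ["g0", "g1", "g2", "g3", "g4"] * 6})
        out = ic.biotype_site_enrichment(sites, cov, cpm).set_index("biotype")
        assert out.loc["lncRNA", "pvalue"] < 0.05
        assert out.loc["lncRNA", "observed"] > out.loc["lncRNA", "expected"]

    def test_proportional_sites_not_significant(self):
        cov, cpm = self._inputs()
        sites = pd.DataFrame({"gene_id": ["g0", "g5"] * 10})
        out = ic.biotype_site_enrichment(sites, cov, cpm).set_index("biotype")
        assert all(p == pytest.approx(1.0) for p in out.pvalue)

    def test_empty_universe_rejected(self):
        cov, cpm = self._inputs()
        with pytest.raises(ValueError):
            ic.biotype_site_enrichment(
                pd.DataFrame({"gene_id": []}), cov, cpm * 0.0
            )


class TestStratifyCandidates:
    def _coverages(self, metrics):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(metrics))],
                "biotype": "lncRNA",
                "iclip_rpkm": [m[0] for m in metrics],
                "rnaseq_rpkm": [m[1] for m in metrics],
                "enrichment": [m[2] for m in metrics],
            }
        )

    def _presence(self, gene_ids, passing):
        return pd.DataFrame(
            {"gene_id": gene_ids, "present": [g in passing for g in gene_ids]}
        )

    def test_single_passing_candidate_ranks_first(self):
        cov = self._coverages([(1, 1, 0.0), (2, 2, 1.0)])
        sites = pd.DataFrame({"gene_id": ["g0", "g1"]})
        presence = self._presence(cov.gene_id, {"g1"})
        out = ic.stratify_candidates(cov, sites, presence)
        assert list(out.gene_id) == ["g1"] and out["rank"].iloc[0] == 1

    def test_dominant_candidate_wins(self):
        cov = self._coverages([(10, 10, 2.0), (1, 1, 0.1), (2, 2, 0.5)])
        sites = pd.DataFrame({"gene_id": ["g0"] * 5 + ["g1", "g2"]})
        presence = self._presence(cov.gene_id, {"g0", "g1", "g2"})
        out = ic.stratify_candidates(cov, sites, presence)
        assert out.gene_id.iloc[0] == "g0"

    def test_ranking_matches_independent_zscore_oracle(self):
        rng = np.random.default_rng(29)
        n = 20
        metrics = rng.lognormal(0, 1, size=(n, 3))
        cov = self._coverages([tuple(m) for m in metrics])
        n_sites = rng.integers(0, 10, size=n)
        sites = pd.DataFrame(
            {"gene_id": np.repeat(cov.gene_id.to_numpy(), n_sites)}
        )
        presence = self._presence(cov.gene_id, set(cov.gene_id))
        out = ic.stratify_candidates(cov, sites, presence)

        mat = np.column_stack([metrics, n_sites])
        z = (mat - mat.mean(axis=0)) / mat.std(axis=0)
        composite = z.mean(axis=1)
        oracle_order = [
            cov.gene_id[i] for i in np.argsort(-composite, kind="stable")
        ]
        assert list(out.gene_id) == oracle_order

    def test_fewer_than_top_k_warns(self):
        cov = self._coverages([(1, 1, 0.0)])
        presence = self._presence(cov.gene_id, {"g0"})
        with pytest.warns(UserWarning, match="candidates pass"):
            ic.stratify_candidates(cov, pd.DataFrame({"gene_id": ["g0"]}), presence)
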