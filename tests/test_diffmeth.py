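from __future__ import annotations

import pytest

from conftest import make_record, make_states
from symmeth.diffmeth import (
    DiffSite,
    MotifSummary,
    assign_to_genes,
    diff_sites,
    gain_loss_binomtest,
    methylation_loss,
    regional_tally,
    summarize_motif,
)
from symmeth.genome import GeneAnnotation, GenomicRegion
from symmeth.modcalls import SiteState
from symmeth.motifs import MotifSite, MotifSpec, default_motifs

GANTC = next(m for m in default_motifs() if m.name == "GANTC")
CCTTGAG = next(m for m in default_motifs() if m.name == "CCTTGAG")


def _states_at(motif, spec, condition):
    """spec: list of (position, methylated)."""
    out = []
    for pos, meth in spec:
        site = MotifSite(motif.name, pos, "+", pos)
        if meth:
            out.append(SiteState(site, condition, "methylated", make_record(pos)))
        else:
            out.append(SiteState(site, condition, "unmethylated"))
    return out


class TestDiffSites:
    def test_identical_states_all_unchanged(self):
        a = _states_at(GANTC, [(10, True), (20, False)], "a")
        b = _states_at(GANTC, [(10, True), (20, False)], "b")
        diff = diff_sites(a, b)
        assert all(d.change == "unchanged" for d in diff)

    def test_planted_gains_and_losses_flagged(self, rng):
        positions = list(range(10, 210, 10))  # 20 sites
        meth_a = [False] * 5 + [True] * 3 + [True] * 12
        meth_b = [True] * 5 + [False] * 3 + [True] * 12
        a = _states_at(GANTC, list(zip(positions, meth_a)), "a")
        b = _states_at(GANTC, list(zip(positions, meth_b)), "b")
        diff = diff_sites(a, b)
        changes = {d.change for d in diff[:8]}
        assert sum(d.change == "gain" for d in diff) == 5
        assert sum(d.change == "loss" for d in diff) == 3
        assert sum(d.change == "unchanged" for d in diff) == 12
        assert changes <= {"gain", "loss"}

    def test_partition_invariant(self):
        a = _states_at(GANTC, [(i, i % 2 == 0) for i in range(10, 100, 10)], "a")
        b = _states_at(GANTC, [(i, i % 3 == 0) for i in range(10, 100, 10)], "b")
        diff = diff_sites(a, b)
        n = {c: sum(d.change == c for d in diff) for c in ("gain", "loss", "unchanged")}
        assert sum(n.values()) == len(diff) == 9

    def test_site_set_mismatch_raises(self):
        a = _states_at(GANTC, [(10, True)], "a")
        b = _states_at(GANTC, [(20, True)], "b")
        with pytest.raises(ValueError, match="site sets differ"):
            diff_sites(a, b)


class TestSummarizeMotif:
    def test_percent_to_two_decimals(self):
        states = make_states(CCTTGAG, 1361, 1700 - 1361, "bacteroid")
        s = summarize_motif(states, CCTTGAG)
        assert (s.n_methylated, s.n_motifs, s.pct_methylated) == (1361, 1700, 80.06)

    def test_zero_of_ten(self):
        s = summarize_motif(make_states(GANTC, 0, 10), GANTC)
        assert s.pct_methylated == 0.0

    def test_no_sites_reports_missing(self):
        s = summarize_motif([], GANTC)
        assert s.pct_methylated is None and s.n_motifs == 0

    def test_order_invariant(self):
        states = make_states(GANTC, 3, 7)
        assert summarize_motif(states, GANTC) == summarize_motif(states[::-1], GANTC)

    def test_means_over_methylated_only(self):
        site = MotifSite(GANTC.name, 2, "+", 1)
        states = [
            SiteState(site, "a", "methylated", make_record(2, qv=100, coverage=50, ipd=4.0)),
            SiteState(MotifSite(GANTC.name, 7, "+", 6), "a", "unmethylated"),
        ]
        s = summarize_motif(states, GANTC)
        assert (s.mean_qv, s.mean_coverage, s.mean_ipd) == (100.0, 50.0, 4.0)

    def test_wrong_motif_rejected(self):
        with pytest.raises(ValueError, match="passed to summary"):
            summarize_motif(make_states(GANTC, 1, 0), CCTTGAG)


class TestMethylationLoss:
    def _summary(self, motif, n_meth, n=33196):
        return MotifSummary(motif, 2, "m6A", n, n_meth, None, None, None, None)

    def test_published_style_differences(self):
        assert methylation_loss(self._summary("GANTC", 33118),
                                self._summary("GANTC", 32353)) == 765
        assert methylation_loss(self._summary("CRAGGAT", 4003, 4005),
                                self._summary("CRAGGAT", 3504, 4005)) == 499

    def test_equal_summaries_zero(self):
        assert methylation_loss(self._summary("GANTC", 5), self._summary("GANTC", 5)) == 0

    def test_motif_mismatch_raises(self):
        with pytest.raises(ValueError, match="different motifs"):
            methylation_loss(self._summary("GANTC", 5), self._summary("CRAGGAT", 5, 33196))


def _diff(motif_name, position, changed, state_a="methylated"):
    state_b = ("unmethylated" if state_a == "methylated" else "methylated") if changed \
        else state_a
    return DiffSite(MotifSite(motif_name, position, "+", position), state_a, state_b)


class TestAssignToGenes:
    genes = [
        GeneAnnotation("g1", 1001, 2000, "+"),
        GeneAnnotation("g2", 2501, 3500, "-"),
    ]
    upstream = {
        "g1": GenomicRegion(501, 1000),
        "g2": GenomicRegion(3501, 4000),
    }

    def test_coding_site(self):
        res = assign_to_genes([_diff("GANTC", 1500, True)], self.genes, self.upstream)
        (gm,) = res.per_gene
        assert (gm.gene_id, gm.changes_coding, gm.changes_upstream) == ("g1", 1, 0)

    def test_unchanged_sites_ignored(self):
        res = assign_to_genes([_diff("GANTC", 1500, False)], self.genes, self.upstream)
        assert res.per_gene == [] and res.n_intergenic == 0

    def test_intergenic_site_counted(self):
        res = assign_to_genes([_diff("GANTC", 4500, True)], self.genes, self.upstream)
        assert res.per_gene == [] and res.n_intergenic == 1

    def test_shared_upstream_of_divergent_genes_counts_both(self):
        # <-g1 (ends 1000)   gap 1001..1400   g2-> (starts 1401)
        genes = [
            GeneAnnotation("g1", 500, 1000, "-"),
            GeneAnnotation("g2", 1401, 2000, "+"),
        ]
        upstream = {
            "g1": GenomicRegion(1001, 1400),
            "g2": GenomicRegion(1001, 1400),
        }
        res = assign_to_genes([_diff("GANTC", 1200, True)], genes, upstream)
        assert {g.gene_id for g in res.per_gene} == {"g1", "g2"}
        assert all(g.changes_upstream == 1 for g in res.per_gene)

    def test_multi_motif_gene_pattern(self):
        # 13 changes over two motifs concentrated on one gene
        diff = [_diff("GANTC", 1000 + 10 * i, True) for i in range(11)]
        diff += [_diff("CRAGGAT", 1900, True), _diff("CRAGGAT", 1950, True)]
        res = assign_to_genes(diff, self.genes, self.upstream)
        (gm,) = res.per_gene
        assert gm.total_changes == 13
        assert gm.motifs_changed == {"GANTC", "CRAGGAT"}

    def test_coding_changes_conserved_for_nonoverlapping_genes(self, rng):
        genes = [GeneAnnotation(f"g{i}", 1 + 1200 * i, 900 + 1200 * i, "+")
                 for i in range(20)]
        upstream = {g.gene_id: None for g in genes}
        positions = rng.choice(24000, size=200, replace=False) + 1
        diff = [_diff("GANTC", int(p), True) for p in positions]
        res = assign_to_genes(diff, genes, upstream)
        in_coding = sum(
            1 for p in positions
            if any(g.start <= p <= g.end for g in genes)
        )
        assert sum(g.changes_coding for g in res.per_gene) == in_coding


class TestRegionalTally:
    island = GenomicRegion(1, 5000, "island")
    genes = [GeneAnnotation("g1", 1001, 3000, "+"), GeneAnnotation("g2", 7001, 9000, "+")]
    upstream = {"g1": GenomicRegion(501, 1000), "g2": GenomicRegion(6501, 7000)}

    def test_all_sites_in_island_leaves_rest_empty(self):
        diff = [_diff("GANTC", p, True) for p in (1200, 2200, 2900)]
        tallies = regional_tally(diff, self.island, self.genes, self.upstream, 10000)
        rest = [t for t in tallies if t.region_label == "rest"]
        assert all(t.n_sites == 0 and t.n_changed == 0 for t in rest)

    def test_per_kb_definition(self):
        diff = [_diff("GANTC", 1001 + i * 200, True) for i in range(10)]
        tallies = regional_tally(diff, self.island, self.genes, self.upstream, 10000)
        t = next(t for t in tallies
                 if t.region_label == "island" and t.compartment == "coding")
        assert t.compartment_bp == 2000
        assert t.changed_per_kb == pytest.approx(5.0)

    def test_island_share_matches_planted_fraction(self, rng):
        # plant 10% of changed sites inside the island
        island = GenomicRegion(1, 10_000, "island")
        n = 2000
        inside = rng.random(n) < 0.10
        positions = [int(rng.integers(1, 10_001)) if i else int(rng.integers(10_001, 100_001))
                     for i in inside]
        diff = [_diff("GANTC", p, True) for p in positions]
        tallies = regional_tally(diff, island, [], {}, 100_000)
        t = next(t for t in tallies
                 if t.region_label == "island" and t.compartment == "all")
        frac = t.n_changed / n
        se = (0.1 * 0.9 / n) ** 0.5
        assert abs(frac - 0.10) <= 3 * se

    def test_island_outside_genome_rejected(self):
        with pytest.raises(ValueError, match="island"):
            regional_tally([], GenomicRegion(1, 20000), self.genes, self.upstream, 10000)


class TestGainLossBinomtest:
    def test_balanced_changes_not_significant(self):
        diff = [_diff("GANTC", 10 * i, True, "methylated") for i in range(1, 11)]
        diff += [_diff("GANTC", 1000 + 10 * i, True, "unmethylated") for i in range(1, 11)]
        assert gain_loss_binomtest(diff) == pytest.approx(1.0)

    def test_no_changes_is_none(self):
        assert gain_loss_binomtest([_diff("GANTC", 5, False)]) is None
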