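import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cassava_mgwas import signals as sig
from cassava_mgwas.quantgen import AssociationResult


def make_result(chroms, positions, pvals):
    n = len(positions)
    return AssociationResult(
        snp_ids=[f"{c}:{p}" for c, p in zip(chroms, positions)],
        chroms=np.asarray(chroms),
        positions=np.asarray(positions, dtype=np.int64),
        beta=np.zeros(n),
        se=np.ones(n),
        stat=np.zeros(n),
        p=np.asarray(pvals, dtype=float),
        var_explained=np.zeros(n),
    )


def brute_force_clump(snps, gap_bp, min_snps):
    """Exhaustive reference: for every chromosome, every maximal window of
    consecutive significant SNPs whose adjacent gaps are all < gap_bp."""
    by_chrom = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    loci = []
    for chrom, ss in by_chrom.items():
        n = len(ss)
        used = [False] * n
        for i in range(n):
            if used[i]:
                continue
            j = i
            while j + 1 < n and ss[j + 1].pos - ss[j].pos < gap_bp:
                j += 1
            run = ss[i : j + 1]
            for k in range(i, j + 1):
                used[k] = True
            if len(run) >= min_snps:
                lead = min(run, key=lambda s: (s.p, s.pos))
                loci.append((chrom, run[0].pos, run[-1].pos, len(run), lead.pos))
    return sorted(loci)


class TestThreshold:
    def test_p_equal_to_threshold_included(self):
        res = make_result(["Chr1"] * 3, [10, 20, 30], [4.43e-7, 4.44e-7, 1e-9])
        out = sig.threshold_significant(res, 4.43e-7)
        assert sorted(s.pos for s in out) == [10, 30]

    def test_empty_result_gives_empty_set(self):
        res = make_result([], [], [])
        assert sig.threshold_significant(res, 0.05) == []

    def test_matches_brute_force_filter(self, rng):
        p = rng.random(500)
        res = make_result(["Chr1"] * 500, np.arange(1, 501) * 10, p)
        out = sig.threshold_significant(res, 0.3)
        assert {s.pos for s in out} == {
            int(pos) for pos, pv in zip(res.positions, p) if pv <= 0.3
        }

    def test_invalid_alpha_rejected(self):
        res = make_result(["Chr1"], [1], [0.5])
        with pytest.raises(ValueError):
            sig.threshold_significant(res, 0.0)


class TestClump:
    def test_five_close_snps_form_one_locus(self):
        snps = [sig.SigSnp("Chr1", 1000 * (i + 1), f"s{i}", 10 ** -(i + 3)) for i in range(5)]
        loci, rem = sig.clump_loci(snps)
        assert len(loci) == 1 and not rem
        assert loci[0].lead.pos == 5000  # smallest P is the last one
        assert loci[0].n_snps == 5

    def test_four_snps_do_not_form_a_locus(self):
        snps = [sig.SigSnp("Chr1", 1000 * (i + 1), f"s{i}", 1e-8) for i in range(4)]
        loci, rem = sig.clump_loci(snps)
        assert loci == [] and len(rem) == 4

    def test_gap_at_exactly_one_mb_breaks_the_run(self):
        pos = [1, 500_000, 1_000_000, 1_999_999, 2_999_998, 3_999_997]
        snps = [sig.SigSnp("Chr1", p, f"s{i}", 1e-8) for i, p in enumerate(pos)]
        loci, _ = sig.clump_loci(snps, gap_bp=1_000_000, min_snps=5)
        assert len(loci) == 1 and loci[0].n_snps == 6
        # a gap of exactly 1 Mb must split the run
        far = [sig.SigSnp("Chr1", p, f"f{i}", 1e-8) for i, p in enumerate(
            [1, 2, 3, 4, 5, 1_000_005])]
        loci3, rem3 = sig.clump_loci(far, gap_bp=1_000_000, min_snps=5)
        assert len(loci3) == 1 and loci3[0].n_snps == 5 and len(rem3) == 1

    def test_unsorted_input_rejected(self):
        snps = [sig.SigSnp("Chr1", 50, "a", 0.1), sig.SigSnp("Chr1", 10, "b", 0.1)]
        with pytest.raises(ValueError, match="unsorted"):
            sig.clump_loci(snps)

    def test_matches_exhaustive_reference_on_random_instances(self, rng):
        for _ in range(1000):
            n = int(rng.integers(0, 40))
            pos = np.sort(rng.choice(np.arange(1, 5_000_001, 7), n, replace=False))
            chrom = rng.choice(["Chr1", "Chr2"])
            snps = [
                sig.SigSnp(str(chrom), int(p), f"s{p}", float(pv))
                for p, pv in zip(pos, rng.random(n))
            ]
            gap = int(rng.choice([100_000, 500_000, 1_000_000]))
            k = int(rng.choice([2, 3, 5]))
            loci, rem = sig.clump_loci(snps, gap_bp=gap, min_snps=k)
            got = sorted(
                (l.chrom, l.start, l.end, l.n_snps, l.lead.pos) for l in loci
            )
            assert got == brute_force_clump(snps, gap, k)
            assert len(rem) + sum(l.n_snps for l in loci) == n

    def test_clumping_is_idempotent(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), 60, replace=False))
        snps = [sig.SigSnp("Chr1", int(p), f"s{p}", float(v))
                for p, v in zip(pos, rng.random(60))]
        loci, _ = sig.clump_loci(snps, gap_bp=200_000, min_snps=3)
        for l in loci:
            again, rem = sig.clump_loci(l.members, gap_bp=200_000, min_snps=3)
            assert len(again) == 1 and not rem
            assert (again[0].start, again[0].end, again[0].lead.pos) == (
                l.start, l.end, l.lead.pos
            )

    def test_order_of_lead_tie_break_is_position(self):
        snps = [sig.SigSnp("Chr1", p, f"s{p}", 1e-9) for p in (10, 20, 30, 40, 50)]
        loci, _ = sig.clump_loci(snps)
        assert loci[0].lead.pos == 10


class TestIntersectReplicates:
    def make_loci(self, specs, trait="m1"):
        out = []
        for chrom, pos in specs:
            lead = sig.SigSnp(chrom, pos, f"{chrom}:{pos}", 1e-9)
            out.append(sig.Locus(trait, chrom, pos - 100, pos + 100, [lead] * 5, lead))
        return out

    def test_identical_lists_fully_match(self):
        a = self.make_loci([("Chr1", 1000), ("Chr2", 5000)])
        r = sig.intersect_replicates(a, a)
        assert len(r.matched) == 2 and not r.only_rep1 and not r.only_rep2

    def test_disjoint_chromosomes_do_not_match(self):
        a = self.make_loci([("Chr1", 1000)])
        b = self.make_loci([("Chr2", 1000)])
        r = sig.intersect_replicates(a, b)
        assert not r.matched and len(r.only_rep1) == 1 and len(r.only_rep2) == 1

    def test_positions_within_match_bp_fully_match(self, rng):
        a = self.make_loci([("Chr1", int(p)) for p in rng.integers(10_000, 1_000_000, 8)])
        b = []
        for l in a:
            shift = int(rng.integers(-500, 501))
            lead = sig.SigSnp(l.chrom, l.lead.pos + shift, "x", 1e-9)
            b.append(sig.Locus(l.trait, l.chrom, lead.pos - 100, lead.pos + 100, [lead] * 5, lead))
        r = sig.intersect_replicates(a, b, match_bp=500)
        assert len(r.matched) == len(a)

    def test_different_metabolites_never_match(self):
        a = self.make_loci([("Chr1", 1000)], trait="m1")
        b = self.make_loci([("Chr1", 1000)], trait="m2")
        assert not sig.intersect_replicates(a, b).matched


class TestHotspots:
    def test_extreme_enrichment_is_flagged(self):
        genome = {"Chr1": 50_000_000}
        signals = [("Chr1", 123_456)] * 200
        t = sig.detect_hotspots(signals, genome, bin_bp=1_000_000, n_perm=200, seed=1)
        row = t.data[(t.data.bin_start <= 123_456) & (t.data.bin_end >= 123_456)]
        assert bool(row.flagged.iloc[0])
        assert t.data["count"].sum() == 200

    def test_flag_iff_count_reaches_threshold(self, rng):
        genome = {"Chr1": 10_000_000, "Chr2": 10_000_000}
        signals = [("Chr1", int(p)) for p in rng.integers(1, 10_000_000, 100)]
        t = sig.detect_hotspots(signals, genome, bin_bp=1_000_000, n_perm=300, seed=5)
        assert (t.data.flagged == (t.data["count"] >= t.threshold)).all()

    def test_seed_reproducibility(self, rng):
        genome = {"Chr1": 20_000_000}
        signals = [("Chr1", int(p)) for p in rng.integers(1, 20_000_000, 300)]
        a = sig.detect_hotspots(signals, genome, n_perm=300, seed=7)
        b = sig.detect_hotspots(signals, genome, n_perm=300, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_threshold_matches_binomial_oracle(self):
        # S = 1000 signals over B = 1000 bins: compare with Binomial(S, 1/B)
        rng = np.random.default_rng(0)
        genome = {f"C{i}": 100_000_000 for i in range(10)}
        chroms = list(genome)
        signals = [
            (chroms[int(rng.integers(10))], int(rng.integers(1, 100_000_001)))
            for _ in range(1000)
        ]
        t = sig.detect_hotspots(signals, genome, bin_bp=1_000_000, n_perm=1000,
                                alpha=0.01, seed=11)
        c = 0
        while stats.binom.sf(c - 1, 1000, 1 / 1000) >= 0.01:
            c += 1
        assert abs(t.threshold - c) <= 1

    def test_empty_signals_give_empty_flags(self):
        t = sig.detect_hotspots([], {"Chr1": 5_000_000}, seed=0)
        assert not t.data.flagged.any() and t.threshold == 0

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            sig.detect_hotspots([("Chr1", 5)], {"Chr1": 100}, bin_bp=0)


class TestColocalize:
    def locus(self, trait, chrom, start, end, lead_pos):
        lead = sig.SigSnp(chrom, lead_pos, f"{chrom}:{lead_pos}", 1e-9)
        return sig.Locus(trait, chrom, start, end, [lead] * 5, lead)

    def test_identical_lead_positions_reported_at_distance_zero(self):
        a = [self.locus("m", "Chr1", 900, 1100, 1000)]
        b = [self.locus("p", "Chr1", 950, 1050, 1000)]
        pairs = sig.colocalize(a, b)
        assert len(pairs) == 1 and pairs[0].distance_bp == 0

    def test_distant_non_overlapping_loci_not_reported(self):
        a = [self.locus("m", "Chr1", 1, 100, 50)]
        b = [self.locus("p", "Chr1", 2_000_000, 2_000_100, 2_000_050)]
        assert sig.colocalize(a, b, window_bp=1_000_000) == []

    def test_matches_brute_force_all_pairs(self, rng):
        def random_loci(trait, n):
            out = []
            for _ in range(n):
                chrom = str(rng.choice(["Chr1", "Chr2"]))
                start = int(rng.integers(1, 5_000_000))
                end = start + int(rng.integers(100, 500_000))
                lead = int(rng.integers(start, end + 1))
                out.append(self.locus(trait, chrom, start, end, lead))
            return out

        a, b = random_loci("m", 25), random_loci("p", 25)
        w = 300_000
        got = {(p.metabolite_locus.lead.pos, p.phenotype_locus.lead.pos)
               for p in sig.colocalize(a, b, w)}
        expected = set()
        for x in a:
            for y in b:
                if x.chrom != y.chrom:
                    continue
                if abs(x.lead.pos - y.lead.pos) <= w or (
                    x.start <= y.end and y.start <= x.end
                ):
                    expected.add((x.lead.pos, y.lead.pos))
        assert got == expected

    def test_input_order_invariance(self, rng):
        a = [self.locus("m", "Chr1", 100, 200, 150),
             self.locus("m2", "Chr1", 400, 900, 600)]
        b = [self.locus("p", "Chr1", 150, 350, 250)]
        f = sig.coloc_to_frame(sig.colocalize(a, b))
        g = sig.coloc_to_frame(sig.colocalize(a[::-1], b))
        assert set(map(tuple, f.values.tolist())) == set(map(tuple, g.values.tolist()))
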