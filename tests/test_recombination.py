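"""Oracle and behaviour tests for the five recombination statistics.

Every statistic is checked against an independent brute-force oracle
(exhaustive cut/run/walk enumeration written from the definitions, not from
the implementation) on randomized instances, plus hand-computable examples.
"""

import numpy as np
import pytest

from phagewo.core_io import AlignedSet, RunConfig, SequenceRecord
from phagewo.recombination import (
    MethodResult,
    Triplet,
    TripletResult,
    _support_profile,
    _triplet_seed,
    bootscan,
    build_triplets,
    chi2_2x2,
    chimaera,
    consensus_events,
    detect_recombination,
    geneconv_like,
    informative_sites,
    maxchi,
    threeseq_walk,
)
from phagewo.typing import PhageType, encode_alignment

# ---------------------------------------------------------------------------
# Brute-force oracles (definition-level, loop-everything implementations)
# ---------------------------------------------------------------------------


def oracle_chi2(a, b, c, d):
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return 0.0 if den == 0 else n * (a * d - b * c) ** 2 / den


def oracle_maxchi_stat(cs, p1s, p2s):
    """Max chi-square over parents and eligible cuts, from raw strings."""
    var, inf = [], []
    for k, (x, y, z) in enumerate(zip(cs, p1s, p2s)):
        if "-" in (x, y, z) or "N" in (x, y, z):
            continue
        if not (x == y == z):
            var.append(k)
        if y != z and (x == y) != (x == z):
            inf.append(k)
    best = 0.0
    inf_set = set(inf)
    inf_in_var = [i for i, k in enumerate(var) if k in inf_set]
    for parent in (p1s, p2s):
        m = [cs[k] == parent[k] for k in var]
        for cut in inf_in_var[:-1]:  # after each informative site but the last
            left, right = m[: cut + 1], m[cut + 1:]
            chi = oracle_chi2(
                sum(left), len(left) - sum(left), sum(right), len(right) - sum(right)
            )
            best = max(best, chi)
    return best


def oracle_chimaera_stat(cs, p1s, p2s):
    lab = []
    for x, y, z in zip(cs, p1s, p2s):
        if "-" in (x, y, z) or "N" in (x, y, z) or y == z:
            continue
        if (x == y) != (x == z):
            lab.append(x == y)
    best = 0.0
    for cut in range(1, len(lab)):
        l, r = lab[:cut], lab[cut:]
        best = max(
            best,
            oracle_chi2(sum(l), len(l) - sum(l), sum(r), len(r) - sum(r)),
        )
    return best


def oracle_walk_stat(x):
    """O(n^2) maximum of S_j - S_i over 0 <= i < j <= n, both directions."""
    s = np.concatenate([[0], np.cumsum(x)])
    best = 0.0
    for i in range(len(s)):
        for j in range(i + 1, len(s)):
            best = max(best, s[j] - s[i], s[i] - s[j])
    return best


def oracle_run_stat(z, pos):
    """Enumerate maximal equal-label runs; score = n_sites * column span."""
    best = 0.0
    i = 0
    while i < len(z):
        j = i
        while j + 1 < len(z) and z[j + 1] == z[i]:
            j += 1
        best = max(best, (j - i + 1) * (pos[j] - pos[i] + 1))
        i = j + 1
    return best


def _triplet_aln(cs, p1s, p2s, out=None):
    rows = [("c", cs), ("p1", p1s), ("p2", p2s)]
    if out is not None:
        rows.append(("o", out))
    aln = AlignedSet(
        [SequenceRecord(i, s, species="Testus sp.") for i, s in rows], len(cs)
    )
    enc = encode_alignment(aln)
    info = informative_sites(enc[0], enc[1], enc[2])
    trip = Triplet("c", "p1", "p2", (info + 1).tolist())
    return trip, aln


def _random_triplet(rng, L=120, mosaic=False):
    base = rng.choice(list("ACGT"), size=L)
    p1 = base.copy()
    p2 = base.copy()
    for arr in (p1, p2):
        idx = rng.choice(L, size=int(rng.integers(5, 14)), replace=False)
        arr[idx] = rng.choice(list("ACGT"), size=idx.size)
    if mosaic:
        bp = int(rng.integers(L // 3, 2 * L // 3))
        c = np.concatenate([p1[:bp], p2[bp:]])
    else:
        c = base.copy()
        idx = rng.choice(L, size=int(rng.integers(0, 10)), replace=False)
        c[idx] = rng.choice(list("ACGT"), size=idx.size)
    return "".join(c), "".join(p1), "".join(p2)


# ---------------------------------------------------------------------------
# Statistic == oracle on randomized instances
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("mosaic", [False, True])
def test_statistics_match_oracles_randomized(fast_cfg, mosaic):
    rng = np.random.default_rng(11 + mosaic)
    checked = 0
    for _ in range(120):
        cs, p1s, p2s = _random_triplet(rng, mosaic=mosaic)
        trip, aln = _triplet_aln(cs, p1s, p2s)
        if len(trip.informative_sites) < 2 or len(trip.informative_sites) > 30:
            continue
        checked += 1
        assert maxchi(trip, aln, fast_cfg).statistic == pytest.approx(
            oracle_maxchi_stat(cs, p1s, p2s), abs=1e-10
        )
        assert chimaera(trip, aln, fast_cfg).statistic == pytest.approx(
            oracle_chimaera_stat(cs, p1s, p2s), abs=1e-10
        )
        enc = encode_alignment(aln)
        info = np.asarray(trip.informative_sites) - 1
        x = np.where((enc[0] == enc[2])[info], 1.0, -1.0)
        assert threeseq_walk(trip, aln, fast_cfg).statistic == oracle_walk_stat(x)
        z = (enc[0] == enc[1])[info].astype(int)
        assert geneconv_like(trip, aln, fast_cfg).statistic == oracle_run_stat(
            z, info + 1
        )
    assert checked >= 50


def test_bootscan_matches_naive_reimplementation(fast_cfg):
    """Same seeded draws, statistic recomputed with explicit loops."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        cs, p1s, p2s = _random_triplet(rng, L=160, mosaic=True)
        out = "".join(rng.choice(list("ACGT"), size=160))
        trip, aln = _triplet_aln(cs, p1s, p2s, out=out)
        cfg = RunConfig(window=60, step=20, bootscan_reps=25,
                        bootscan_n_perm=5, rng_seed=9)
        got = bootscan(trip, aln, cfg, outgroup="o")

        # naive: explicit pattern counting and per-replicate loops
        enc = encode_alignment(aln)
        seqs = [enc[0], enc[1], enc[2], enc[3]]
        pair_idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        L = aln.length
        patt = np.zeros(L, dtype=int)
        for k, (i, j) in enumerate(pair_idx):
            patt += (seqs[i] != seqs[j]).astype(int) << k
        upatt, pidx = np.unique(patt, return_inverse=True)
        K = upatt.size
        bits = np.array([[(u >> k) & 1 for k in range(6)] for u in upatt])
        starts = np.arange(0, L - 60 + 1, 20)
        rng2 = np.random.default_rng(_triplet_seed(9, trip, "BOOTSCAN"))
        counts = np.array(
            [np.bincount(pidx[s:s + 60], minlength=K) for s in starts]
        )
        draws = rng2.multinomial(60, counts / 60, size=(25, starts.size))
        sup = np.zeros((starts.size, 2))
        for r in range(25):
            for w in range(starts.size):
                pair = [sum(draws[r, w, u] * bits[u, k] for u in range(K))
                        for k in range(6)]
                sums = [pair[0] + pair[5], pair[1] + pair[4], pair[2] + pair[3]]
                g = int(np.argmin(sums))
                if g < 2:
                    sup[w, g] += 1
        sup = sup / 25 * 100
        expected = float(min(sup[:, 0].max(), sup[:, 1].max()))
        assert got.statistic == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Hand-computable examples and degenerate inputs
# ---------------------------------------------------------------------------


class TestExamples:
    def test_chi2_2x2_no_continuity_correction(self):
        assert chi2_2x2(10, 0, 0, 10) == 20.0
        assert chi2_2x2(5, 5, 5, 5) == 0.0
        assert chi2_2x2(10, 0, 10, 0) == 0.0  # empty margin

    def _spliced(self, n_left=10, n_right=10, spacing=6):
        """Child = parent1 on the left block, parent2 on the right block."""
        L = (n_left + n_right) * spacing + 20
        base = list("A" * L)
        p1 = base.copy()
        p2 = base.copy()
        sites = [10 + k * spacing for k in range(n_left + n_right)]
        for s in sites:
            p2[s] = "G"  # parents differ at every planted site
        split = sites[n_left - 1]
        c = [
            (p1[k] if k <= split else p2[k]) for k in range(L)
        ]
        return "".join(c), "".join(p1), "".join(p2), sites

    def test_chimaera_perfect_split_is_20(self):
        cs, p1s, p2s, _ = self._spliced(10, 10)
        trip, aln = _triplet_aln(cs, p1s, p2s)
        cfg = RunConfig(rng_seed=1)
        res = chimaera(trip, aln, cfg)
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value <= 0.005

    def test_maxchi_cut_at_splice_column(self):
        cs, p1s, p2s, sites = self._spliced(10, 10)
        trip, aln = _triplet_aln(cs, p1s, p2s)
        res = maxchi(trip, aln, RunConfig(rng_seed=1))
        splice = (sites[9] + 1 + sites[10] + 1) / 2
        assert res.breakpoints[0] == pytest.approx(splice, abs=1)
        assert res.p_value <= 0.005

    def test_threeseq_block_labels(self):
        cs, p1s, p2s, sites = self._spliced(10, 10)
        trip, aln = _triplet_aln(cs, p1s, p2s)
        res = threeseq_walk(trip, aln, RunConfig(rng_seed=1))
        assert res.statistic == 10.0  # -1 x10 then +1 x10: max ascent 10
        assert res.p_value <= 0.005

    def test_threeseq_alternating_no_signal(self):
        # child matches p1 and p2 alternately
        L = 120
        base = list("A" * L)
        p1, p2, c = base.copy(), base.copy(), base.copy()
        for k, s in enumerate(range(10, 90, 8)):
            p2[s] = "G"
            if k % 2:
                c[s] = "G"
        trip, aln = _triplet_aln("".join(c), "".join(p1), "".join(p2))
        res = threeseq_walk(trip, aln, RunConfig(rng_seed=1))
        assert res.statistic <= 2.0
        assert res.p_value >= 0.9

    def test_geneconv_run_brackets_splice(self):
        cs, p1s, p2s, sites = self._spliced(10, 10)
        trip, aln = _triplet_aln(cs, p1s, p2s)
        res = geneconv_like(trip, aln, RunConfig(rng_seed=1))
        assert res.p_value <= 0.01
        lo, hi = res.breakpoints
        assert lo in (sites[0] + 1, sites[10] + 1)
        assert hi in (sites[9] + 1, sites[19] + 1)

    def test_homogeneous_child_no_signal(self):
        # child identical to parent1 everywhere
        L = 150
        p1 = list("A" * L)
        p2 = list("A" * L)
        for s in range(10, 130, 10):
            p2[s] = "C"
        cs = "".join(p1)
        trip, aln = _triplet_aln(cs, "".join(p1), "".join(p2))
        for fn in (maxchi, chimaera, threeseq_walk, geneconv_like):
            assert fn(trip, aln, RunConfig(rng_seed=1)).p_value >= 0.99

    @pytest.mark.parametrize("fn", [maxchi, chimaera, threeseq_walk, geneconv_like])
    def test_fewer_than_two_informative_sites(self, fn, fast_cfg):
        p1 = "A" * 60
        p2 = "A" * 30 + "G" + "A" * 29
        c = p1
        trip, aln = _triplet_aln(c, p1, p2)
        assert len(trip.informative_sites) == 1
        res = fn(trip, aln, fast_cfg)
        assert res.p_value == 1.0 and res.breakpoints == []

    def test_identical_parents_degenerate(self, fast_cfg):
        p = "ACGT" * 30
        c = "TGCA" * 30
        trip, aln = _triplet_aln(c, p, p)
        assert trip.informative_sites == []
        for fn in (maxchi, chimaera, threeseq_walk, geneconv_like):
            assert fn(trip, aln, fast_cfg).p_value == 1.0


class TestBootscan:
    def test_switch_near_planted_breakpoint(self):
        rng = np.random.default_rng(0)
        L = 400
        base = rng.choice(list("ACGT"), size=L)
        p1, p2, out = base.copy(), base.copy(), base.copy()
        for arr in (p1, p2, out):
            idx = rng.choice(L, size=16, replace=False)  # ~8% pairwise
            arr[idx] = rng.choice(list("ACGT"), size=16)
        c = np.concatenate([p1[:200], p2[200:]])
        trip, aln = _triplet_aln(
            "".join(c), "".join(p1), "".join(p2), out="".join(out)
        )
        res = bootscan(trip, aln, RunConfig(rng_seed=4), outgroup="o")
        assert res.statistic >= 70.0
        assert res.breakpoints and abs(res.breakpoints[0] - 200) <= 60
        assert res.p_value <= 0.05

    def test_clonal_triplets_mostly_silent(self):
        """Independent lineages: no supported switch, p >= 0.5, in >=90%."""
        rng = np.random.default_rng(12)
        quiet = 0
        n_rep = 50
        for _ in range(n_rep):
            L = 400
            base = rng.choice(list("ACGT"), size=L)
            seqs = []
            for _k in range(4):
                arr = base.copy()
                idx = rng.choice(L, size=16, replace=False)
                arr[idx] = rng.choice(list("ACGT"), size=16)
                seqs.append("".join(arr))
            trip, aln = _triplet_aln(*seqs[:3], out=seqs[3])
            res = bootscan(trip, aln, RunConfig(rng_seed=4), outgroup="o")
            quiet += res.p_value >= 0.5
        assert quiet >= 0.9 * n_rep

    def test_window_shrunk_with_warning(self, fast_cfg):
        cs, p1s, p2s = _random_triplet(np.random.default_rng(2), L=100, mosaic=True)
        out = "".join(np.random.default_rng(5).choice(list("ACGT"), size=100))
        trip, aln = _triplet_aln(cs, p1s, p2s, out=out)
        cfg = RunConfig(window=500, step=5, bootscan_reps=10,
                        bootscan_n_perm=5, rng_seed=1)
        with pytest.warns(UserWarning, match="shrunk"):
            bootscan(trip, aln, cfg, outgroup="o")

    def test_no_outgroup_skipped(self, fast_cfg):
        cs, p1s, p2s = _random_triplet(np.random.default_rng(2))
        trip, aln = _triplet_aln(cs, p1s, p2s)
        res = bootscan(trip, aln, fast_cfg, outgroup=None)
        assert res.p_value == 1.0


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------


class TestProperties:
    def test_monotone_under_agreeing_extension(self, fast_cfg):
        """Appending sites that agree with the maximal segment never
        decreases the MaxChi / GENECONV-like statistics."""
        L = 240
        base = list("A" * L)
        p1, p2 = base.copy(), base.copy()
        sites = list(range(10, 130, 8))
        for s in sites:
            p2[s] = "G"
        c = [p1[k] if k <= sites[7] else p2[k] for k in range(L)]
        trip, aln = _triplet_aln("".join(c), "".join(p1), "".join(p2))
        g0 = geneconv_like(trip, aln, fast_cfg).statistic
        m0 = maxchi(trip, aln, fast_cfg).statistic
        # extend the parent2-matching tail with more agreeing sites
        for s in range(140, 220, 8):
            p2[s] = "G"
            c[s] = "G"
        trip2, aln2 = _triplet_aln("".join(c), "".join(p1), "".join(p2))
        assert geneconv_like(trip2, aln2, fast_cfg).statistic >= g0
        assert maxchi(trip2, aln2, fast_cfg).statistic >= m0

    def test_pvalues_reproducible_and_order_invariant(self):
        rng = np.random.default_rng(8)
        cs, p1s, p2s = _random_triplet(rng, mosaic=True)
        trip, aln = _triplet_aln(cs, p1s, p2s)
        cfg = RunConfig(n_perm=200, rng_seed=33)
        ref = {f.__name__: f(trip, aln, cfg).p_value
               for f in (maxchi, chimaera, threeseq_walk, geneconv_like)}
        again = {f.__name__: f(trip, aln, cfg).p_value
                 for f in (maxchi, chimaera, threeseq_walk, geneconv_like)}
        assert ref == again
        # record order must not matter: rebuild alignment reversed
        aln_rev = AlignedSet(aln.records[::-1], aln.length)
        rev = {f.__name__: f(trip, aln_rev, cfg).p_value
               for f in (maxchi, chimaera, threeseq_walk, geneconv_like)}
        assert ref == rev

    def test_geneconv_null_p_approximately_uniform(self):
        """On label-shuffled (signal-free) inputs the permutation p-value is
        approximately uniform (KS sanity bound)."""
        from scipy import stats

        rng = np.random.default_rng(21)
        pvals = []
        cfg = RunConfig(n_perm=400, rng_seed=77)
        for k in range(200):
            L = 150
            base = list("A" * L)
            p1, p2, c = base.copy(), base.copy(), base.copy()
            sites = sorted(rng.choice(range(5, L - 5), size=18, replace=False))
            for s in sites:
                p2[s] = "G"
                if rng.random() < 0.5:
                    c[s] = "G"
            trip, aln = _triplet_aln("".join(c), "".join(p1), "".join(p2))
            trip = Triplet(f"c{k}", "p1", "p2", trip.informative_sites)
            aln.records[0].id = f"c{k}"  # vary the permutation seed per case
            pvals.append(geneconv_like(trip, aln, cfg).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# Triplets and consensus
# ---------------------------------------------------------------------------


class TestTriplets:
    def test_counts(self):
        aln = AlignedSet(
            [SequenceRecord(f"r{i}", "ACGT" * 10, species="T x") for i in range(5)],
            40,
        )
        assert len(build_triplets([f"r{i}" for i in range(3)], aln)) == 3
        assert len(build_triplets([f"r{i}" for i in range(5)], aln)) == 5 * 6

    def test_informative_sites_sorted_one_based(self, seed1_typed):
        types = [t for t in seed1_typed["local_types"]]
        reps = [t.representative_id for t in types[:4]]
        trips = build_triplets(reps, seed1_typed["functional"])
        for trip in trips:
            s = trip.informative_sites
            assert s == sorted(s)
            assert all(1 <= x <= seed1_typed["functional"].length for x in s)


def _mk_type(name, rep):
    return PhageType(name=name, member_ids=[rep], representative_id=rep,
                     hosts={("T x", "ST-1")})


class TestConsensus:
    def test_min_methods_threshold(self):
        trip = Triplet("c", "p1", "p2", [10, 20, 30])
        mk = lambda m, p: MethodResult(m, 5.0, p, [100])
        types = [_mk_type("A", "c"), _mk_type("B", "p1"), _mk_type("C", "p2")]
        cfg = RunConfig(consensus_min_methods=3)
        two = TripletResult(trip, {m: mk(m, 0.001) for m in ("MAXCHI", "CHIMAERA")}
                            | {"THREESEQ": mk("THREESEQ", 0.9)})
        assert consensus_events([two], types, cfg) == []
        three = TripletResult(trip, {m: mk(m, 0.001)
                                     for m in ("MAXCHI", "CHIMAERA", "THREESEQ")})
        (ev,) = consensus_events([three], types, cfg)
        assert ev.recombinant == "A" and ev.n_methods == 3
        assert ev.breakpoints == [100]

    def test_bonferroni_over_triplet_count(self):
        trip = Triplet("c", "p1", "p2", [10, 20, 30])
        mk = lambda p: {m: MethodResult(m, 5.0, p, [100])
                        for m in ("MAXCHI", "CHIMAERA", "THREESEQ")}
        types = [_mk_type("A", "c"), _mk_type("B", "p1"), _mk_type("C", "p2")]
        cfg = RunConfig()
        # p=0.02 raw passes alone but fails once corrected for 10 triplets
        results = [TripletResult(trip, mk(0.02))] + [
            TripletResult(Triplet(f"c{k}", "p1", "p2", [10, 20]), mk(1.0))
            for k in range(9)
        ]
        assert consensus_events(results, types, cfg) == []
        assert len(consensus_events([TripletResult(trip, mk(0.02))], types, cfg)) == 1

    def test_merge_same_child_same_breakpoint(self):
        types = [_mk_type(n, n.lower()) for n in ("A", "B", "C", "D")]
        mk = lambda bp: {m: MethodResult(m, 5.0, 0.0005, [bp])
                         for m in ("MAXCHI", "CHIMAERA", "THREESEQ")}
        r1 = TripletResult(Triplet("a", "b", "c", [1, 2]), mk(100))
        r2 = TripletResult(Triplet("a", "b", "d", [1, 2]), mk(105))
        (ev,) = consensus_events([r1, r2], types, RunConfig())
        assert ev.recombinant == "A"
        assert ev.major_parent == "B"  # partner in both candidates
        assert set(ev.minor_parents) == {"C", "D"}

    def test_planted_recombinant_recovered(self, seed1_typed):
        truth = seed1_typed["truth"]
        events = detect_recombination(
            seed1_typed["local_types"], seed1_typed["functional"],
            seed1_typed["cfg"],
        )
        child_tid, parent_tids, (bp,) = truth.recombinants[0]
        name_of = {
            m: t.name for t in seed1_typed["local_types"] for m in t.member_ids
        }
        members = [
            r for r, t in truth.type_assignment.items() if t == child_tid
        ]
        child_name = name_of[members[0]]
        hits = [e for e in events if e.recombinant == child_name]
        assert hits, "planted recombinant not recovered"
        ev = hits[0]
        parent_names = {
            name_of[next(r for r, t in truth.type_assignment.items() if t == p)]
            for p in parent_tids
        }
        assert parent_names == {ev.major_parent, *ev.minor_parents}
        assert min(abs(b - bp) for b in ev.breakpoints) <= 30
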