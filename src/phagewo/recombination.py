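"""Intragenic recombination detection among phage WO types.

Five independently implemented detection statistics are run on every
(child, parent-pair) triplet of one species' type representatives:

* MaxChi   — maximum 2x2 chi-square of match/mismatch vs left/right of a cut,
             child against each parent over triplet-variable sites;
* Chimaera — same cut scan on the binary "child matches parent1 vs parent2"
             vector over informative sites;
* 3Seq-walk — maximum ascent/descent of the +/-1 cumulative walk over
             informative sites (Monte-Carlo permutation null, not the exact
             hypergeometric tables of the original method);
* GENECONV-like — longest exclusive-match run, weighted by its column span;
* BootScan — sliding-window bootstrap support for the (child,parent1) vs
             (child,parent2) grouping, requiring a supported partner switch.

Significance is uniform permutation machinery: per-method p-values are the
proportion of seeded site/label shuffles reaching the observed statistic,
Bonferroni-corrected over the species' triplet count.  A triplet called by at
least ``consensus_min_methods`` methods (default 3) becomes a candidate
event; candidates with the same child and breakpoint (+/-10 columns) are
merged, the parent appearing most often becoming the major parent.

All coordinates are 1-based alignment columns; an informative site is a
column where the parents differ and the child matches exactly one of them.
Chi-squares carry no continuity correction.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .core_io import AlignedSet, RunConfig
from .typing import PhageType, encode_alignment

METHODS = ("MAXCHI", "CHIMAERA", "THREESEQ", "GENECONV_LIKE", "BOOTSCAN")


@dataclass
class Triplet:
    """A candidate recombinant (child) and an unordered parent pair."""

    child: str
    parent1: str
    parent2: str
    informative_sites: list[int]  # 1-based, strictly increasing

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.child, *sorted((self.parent1, self.parent2)))


@dataclass
class MethodResult:
    method: str
    statistic: float
    p_value: float
    breakpoints: list[int] = field(default_factory=list)


@dataclass
class TripletResult:
    triplet: Triplet
    results: dict  # method -> MethodResult

    def n_significant(self, alpha: float, n_tests: int) -> int:
        return sum(
            1
            for r in self.results.values()
            if min(1.0, r.p_value * n_tests) <= alpha
        )


@dataclass
class RecombinationEvent:
    """One consensus recombination call, Table-2 shaped."""

    species: str
    recombinant: str
    major_parent: str
    minor_parents: list[str]
    breakpoints: list[int]
    supporting: list[MethodResult]
    n_methods: int


def _triplet_seed(base_seed: int, trip: Triplet, method: str) -> int:
    tag = "|".join(trip.key) + "|" + method
    h = zlib.crc32(tag.encode())
    return (h ^ ((base_seed * 2654435761) & 0xFFFFFFFF)) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Triplet construction
# ---------------------------------------------------------------------------

def _encoded(aln: AlignedSet) -> dict:
    mat = encode_alignment(aln)
    return {r.id: mat[i] for i, r in enumerate(aln.records)}


def informative_sites(c: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """0-based columns where parents differ and the child matches exactly one."""
    valid = (c < 4) & (p1 < 4) & (p2 < 4)
    m1 = c == p1
    m2 = c == p2
    return np.flatnonzero(valid & (p1 != p2) & (m1 ^ m2))


def build_triplets(rep_ids: list[str], aln: AlignedSet) -> list[Triplet]:
    """All child-in-unordered-parent-pair triplets over type representatives.

    With ``n`` representatives this yields n * C(n-1, 2) triplets; callers
    skip species with fewer than three functional types.
    """
    enc = _encoded(aln)
    trips = []
    for child in rep_ids:
        others = [r for r in rep_ids if r != child]
        for i, a in enumerate(others):
            for b in others[i + 1:]:
                sites = informative_sites(enc[child], enc[a], enc[b])
                trips.append(
                    Triplet(
                        child=child,
                        parent1=a,
                        parent2=b,
                        informative_sites=(sites + 1).tolist(),
                    )
                )
    return trips


# ---------------------------------------------------------------------------
# 2x2 chi-square machinery (MaxChi / Chimaera)
# ---------------------------------------------------------------------------

def chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square of [[a, b], [c, d]], no continuity correction;
    zero when any margin is empty."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def _prefix_chi2(M: np.ndarray) -> np.ndarray:
    """Chi-square of the match/mismatch x left/right table at every prefix
    cut, for a batch of boolean match vectors.

    ``M``: (n_rows, n_sites); a cut at index k (0..n-2) places sites 0..k on
    the left.  Returns (n_rows, n_sites - 1).
    """
    M = M.astype(np.float64)
    n = M.shape[1]
    cs = np.cumsum(M, axis=1)
    tot = cs[:, -1:]
    A = cs[:, :-1]
    left = np.arange(1, n, dtype=np.float64)[None, :]
    B = left - A
    C = tot - A
    D = (n - left) - C
    denom = (A + B) * (C + D) * (A + C) * (B + D)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(denom > 0, n * (A * D - B * C) ** 2 / denom, 0.0)
    return chi


def _informative_cut_mask(F: np.ndarray) -> np.ndarray:
    """Eligible cuts: right after an informative site that is not the last
    informative one.  ``F``: (n_rows, n_sites) boolean informative flags;
    returns (n_rows, n_sites - 1)."""
    remaining = np.cumsum(F[:, ::-1], axis=1)[:, ::-1]
    return F[:, :-1] & (remaining[:, 1:] > 0)


def _perm_matrix(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    return np.argsort(rng.random((n_perm, n)), axis=1)


def _perm_pvalue(obs: float, null: np.ndarray) -> float:
    return (1.0 + int(np.sum(null >= obs - 1e-12))) / (1.0 + null.size)


def maxchi(
    trip: Triplet, aln: AlignedSet, cfg: RunConfig, _enc: dict | None = None
) -> MethodResult:
    """MaxChi: chi-square contrast of child/parent mismatch rates across cuts.

    The scan runs over triplet-variable sites (columns where the three
    sequences are not all identical); cut positions sit between consecutive
    informative sites, each cut placing all variable sites up to and
    including the flanking informative site on the left.  The null permutes
    the order of the variable-site data (both parents jointly).
    """
    enc = _enc or _encoded(aln)
    c, p1, p2 = enc[trip.child], enc[trip.parent1], enc[trip.parent2]
    valid = (c < 4) & (p1 < 4) & (p2 < 4)
    var = np.flatnonzero(valid & ~((c == p1) & (c == p2)))
    info0 = np.asarray(trip.informative_sites, dtype=int) - 1
    if info0.size < 2:
        return MethodResult("MAXCHI", 0.0, 1.0)
    m1 = (c == p1)[var]
    m2 = (c == p2)[var]
    isinf = np.isin(var, info0)

    chi = np.maximum(
        _prefix_chi2(m1[None, :]), _prefix_chi2(m2[None, :])
    )[0]
    mask = _informative_cut_mask(isinf[None, :])[0]
    chi = np.where(mask, chi, 0.0)
    cut_at = int(np.argmax(chi))
    obs = float(chi[cut_at])

    rng = np.random.default_rng(_triplet_seed(cfg.rng_seed, trip, "MAXCHI"))
    P = _perm_matrix(rng, cfg.n_perm, var.size)
    chi_n = np.maximum(_prefix_chi2(m1[P]), _prefix_chi2(m2[P]))
    null = np.where(_informative_cut_mask(isinf[P]), chi_n, 0.0).max(axis=1)
    p = _perm_pvalue(obs, null)

    bps = []
    if obs > 0:
        idx = np.flatnonzero(isinf)
        nxt = idx[np.searchsorted(idx, cut_at, side="right")]
        bps = [int(round((var[cut_at] + 1 + var[nxt] + 1) / 2))]
    return MethodResult("MAXCHI", obs, p, bps)


def chimaera(
    trip: Triplet, aln: AlignedSet, cfg: RunConfig, _enc: dict | None = None
) -> MethodResult:
    """Chimaera: same cut scan on the parent1-vs-parent2 label vector
    restricted to informative sites."""
    enc = _enc or _encoded(aln)
    c, p1 = enc[trip.child], enc[trip.parent1]
    info0 = np.asarray(trip.informative_sites, dtype=int) - 1
    if info0.size < 2:
        return MethodResult("CHIMAERA", 0.0, 1.0)
    z = (c == p1)[info0]  # True: matches parent1

    chi = _prefix_chi2(z[None, :])[0]
    k = int(np.argmax(chi))
    obs = float(chi[k])
    rng = np.random.default_rng(_triplet_seed(cfg.rng_seed, trip, "CHIMAERA"))
    P = _perm_matrix(rng, cfg.n_perm, z.size)
    null = _prefix_chi2(z[P]).max(axis=1)
    p = _perm_pvalue(obs, null)
    bps = [int(round((info0[k] + 1 + info0[k + 1] + 1) / 2))] if obs > 0 else []
    return MethodResult("CHIMAERA", obs, p, bps)


# ---------------------------------------------------------------------------
# 3Seq-style maximum-descent walk
# ---------------------------------------------------------------------------

def walk_extrema(x) -> tuple[float, int, int]:
    """Maximum subarray sum of +/-1 labels with its (i, j) span.

    Returns (max over 0<=i<j<=n of S_j - S_i, i*, j*) on the cumulative walk
    S (S_0 = 0); equivalently the best run-up of child/parent2 matches.
    """
    best, besti, bestj = -np.inf, 0, 0
    s = 0
    mn, mni = 0, 0
    for j, v in enumerate(x, start=1):
        s += v
        if s - mn > best:
            best, besti, bestj = s - mn, mni, j
        if s < mn:
            mn, mni = s, j
    return float(best), besti, bestj


@njit(cache=False)
def _walk_stat(x):
    best = -1e18
    s = 0.0
    mn = 0.0
    for v in x:
        s += v
        if s - mn > best:
            best = s - mn
        if s < mn:
            mn = s
    return best


@njit(cache=False)
def _null_walk(x, n_perm, seed):
    np.random.seed(seed)
    out = np.empty(n_perm)
    y = x.copy()
    for t in range(n_perm):
        np.random.shuffle(y)
        a = _walk_stat(y)
        b = _walk_stat(-y)
        out[t] = a if a > b else b
    return out


def threeseq_walk(
    trip: Triplet, aln: AlignedSet, cfg: RunConfig, _enc: dict | None = None
) -> MethodResult:
    """Maximum ascent/descent of the informative-site walk, permutation null.

    Labels are +1 where the child matches parent2 and -1 where it matches
    parent1; a recombinant shows a long monotone stretch.  The p-value is
    Monte-Carlo over label-order shuffles rather than the closed-form tables
    of the original method.
    """
    enc = _enc or _encoded(aln)
    c, p2 = enc[trip.child], enc[trip.parent2]
    info0 = np.asarray(trip.informative_sites, dtype=int) - 1
    if info0.size < 2:
        return MethodResult("THREESEQ", 0.0, 1.0)
    x = np.where((c == p2)[info0], 1.0, -1.0)

    up, ui, uj = walk_extrema(x)
    dn, di, dj = walk_extrema(-x)
    if up >= dn:
        obs, i, j = up, ui, uj
    else:
        obs, i, j = dn, di, dj
    null = _null_walk(x, cfg.n_perm, _triplet_seed(cfg.rng_seed, trip, "THREESEQ"))
    p = _perm_pvalue(obs, null)
    bps = [int(info0[i] + 1), int(info0[j - 1] + 1)] if obs > 0 else []
    return MethodResult("THREESEQ", obs, p, bps)


# ---------------------------------------------------------------------------
# GENECONV-like longest exclusive run
# ---------------------------------------------------------------------------

def best_run(labels, pos) -> tuple[float, int, int]:
    """Best maximal equal-label run, scored as n_sites * column span.

    Returns (score, start index, end index) over informative sites.
    """
    best, bs, be = 0.0, 0, 0
    s = 0
    for e in range(len(labels)):
        if labels[e] != labels[s]:
            s = e
        score = (e - s + 1) * (pos[e] - pos[s] + 1)
        if score > best:
            best, bs, be = float(score), s, e
    return best, bs, be


@njit(cache=False)
def _best_run_score(z, pos):
    best = 0.0
    s = 0
    for e in range(z.size):
        if z[e] != z[s]:
            s = e
        sc = (e - s + 1) * (pos[e] - pos[s] + 1)
        if sc > best:
            best = sc
    return best


@njit(cache=False)
def _null_run(z, pos, n_perm, seed):
    np.random.seed(seed)
    out = np.empty(n_perm)
    y = z.copy()
    for t in range(n_perm):
        np.random.shuffle(y)
        out[t] = _best_run_score(y, pos)
    return out


def geneconv_like(
    trip: Triplet, aln: AlignedSet, cfg: RunConfig, _enc: dict | None = None
) -> MethodResult:
    """Longest run of informative sites matching one parent exclusively,
    weighted by the run's span in alignment columns; null shuffles the
    labels over the fixed site positions."""
    enc = _enc or _encoded(aln)
    c, p1 = enc[trip.child], enc[trip.parent1]
    info0 = np.asarray(trip.informative_sites, dtype=int) - 1
    if info0.size < 2:
        return MethodResult("GENECONV_LIKE", 0.0, 1.0)
    z = (c == p1)[info0].astype(np.int64)
    pos = (info0 + 1).astype(np.int64)

    obs, bs, be = best_run(z, pos)
    null = _null_run(
        z, pos, cfg.n_perm, _triplet_seed(cfg.rng_seed, trip, "GENECONV_LIKE")
    )
    p = _perm_pvalue(obs, null)
    return MethodResult("GENECONV_LIKE", obs, p, [int(pos[bs]), int(pos[be])])


# ---------------------------------------------------------------------------
# BootScan
# ---------------------------------------------------------------------------

def _support_profile(
    pp: np.ndarray,
    K: int,
    bits: np.ndarray,
    starts: np.ndarray,
    W: int,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap support (%) per window for the three 4-taxon pairings.

    ``pp`` maps each column (in scan order) to its mismatch-pattern index;
    each bootstrap replicate draws W columns with replacement (a multinomial
    over the window's pattern frequencies) and the pairing minimising the
    four-point sum wins.  Returns (n_windows, 3).
    """
    onehot = (pp[:, None] == np.arange(K)[None, :]).astype(np.int64)
    cs = np.vstack([np.zeros((1, K), dtype=np.int64), np.cumsum(onehot, axis=0)])
    counts = cs[starts + W] - cs[starts]  # (nw, K)
    draws = rng.multinomial(W, counts / W, size=(reps, starts.size))
    pair = draws @ bits  # (reps, nw, 6)
    sums = np.stack(
        [
            pair[..., 0] + pair[..., 5],  # (c,p1)+(p2,o)
            pair[..., 1] + pair[..., 4],  # (c,p2)+(p1,o)
            pair[..., 2] + pair[..., 3],  # (c,o)+(p1,p2)
        ],
        axis=-1,
    )
    grouping = np.argmin(sums, axis=-1)  # (reps, nw)
    out = np.empty((starts.size, 3))
    for g in range(3):
        out[:, g] = (grouping == g).mean(axis=0) * 100.0
    return out


def _bootscan_null(
    pidx: np.ndarray,
    K: int,
    bits: np.ndarray,
    starts: np.ndarray,
    W: int,
    reps: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null distribution of the switch statistic under column-order
    permutation, computed in memory-bounded chunks of permutations."""
    L = pidx.size
    nw = starts.size
    out = np.empty(n_perm)
    eye = np.eye(K, dtype=np.int64)
    chunk = max(1, int(8e7 // max(reps * nw * K * 8, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        pp = np.empty((m, L), dtype=np.int64)
        for i in range(m):
            pp[i] = pidx[rng.permutation(L)]
        cs = np.concatenate(
            [np.zeros((m, 1, K), dtype=np.int64), eye[pp].cumsum(axis=1)],
            axis=1,
        )
        counts = cs[:, starts + W] - cs[:, starts]  # (m, nw, K)
        draws = rng.multinomial(
            W, counts.reshape(m * nw, K) / W, size=(reps, m * nw)
        )
        pair = draws @ bits
        sums = np.stack(
            [
                pair[..., 0] + pair[..., 5],
                pair[..., 1] + pair[..., 4],
                pair[..., 2] + pair[..., 3],
            ],
            axis=-1,
        )
        g = np.argmin(sums, axis=-1)  # (reps, m * nw)
        sup1 = (g == 0).mean(axis=0).reshape(m, nw) * 100.0
        sup2 = (g == 1).mean(axis=0).reshape(m, nw) * 100.0
        out[done:done + m] = np.minimum(sup1.max(axis=1), sup2.max(axis=1))
        done += m
    return out


def bootscan(
    trip: Triplet,
    aln: AlignedSet,
    cfg: RunConfig,
    outgroup: str | None = None,
    _enc: dict | None = None,
) -> MethodResult:
    """Sliding-window bootstrap scan for a supported partner switch.

    In each window the grouping of the child with parent1 vs parent2 (against
    an outgroup; the four-point condition stands in for 4-taxon neighbor
    joining, to which it is equivalent) is bootstrapped over columns.  The
    recombination signal is both partners reaching >= ``support_threshold`` %
    support somewhere along the alignment; the statistic is min(max support
    for parent1, max support for parent2) and the null permutes column order,
    destroying spatial structure while preserving composition.  Skipped
    (p = 1) when no outgroup exists.
    """
    if outgroup is None:
        return MethodResult("BOOTSCAN", 0.0, 1.0)
    enc = _enc or _encoded(aln)
    seqs = [enc[trip.child], enc[trip.parent1], enc[trip.parent2], enc[outgroup]]
    valid = np.ones(aln.length, dtype=bool)
    for s in seqs:
        valid &= s < 4
    cols = np.flatnonzero(valid)
    L = cols.size
    if L < 8:
        return MethodResult("BOOTSCAN", 0.0, 1.0)
    W = cfg.window
    if W > L:
        W = max(L // 4, 2)
        warnings.warn(
            f"bootscan window larger than alignment; shrunk to {W}",
            stacklevel=2,
        )
    # per-column mismatch pattern over the 6 pairs
    pair_idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    patt = np.zeros(L, dtype=np.int16)
    for k, (i, j) in enumerate(pair_idx):
        patt |= ((seqs[i][cols] != seqs[j][cols]).astype(np.int16)) << k
    upatt, pidx = np.unique(patt, return_inverse=True)
    K = upatt.size
    bits = ((upatt[:, None] >> np.arange(6)[None, :]) & 1).astype(np.int64)

    starts = np.arange(0, L - W + 1, cfg.step)
    if starts.size < 2:
        return MethodResult("BOOTSCAN", 0.0, 1.0)
    rng = np.random.default_rng(_triplet_seed(cfg.rng_seed, trip, "BOOTSCAN"))
    sup = _support_profile(pidx, K, bits, starts, W, cfg.bootscan_reps, rng)
    obs = float(min(sup[:, 0].max(), sup[:, 1].max()))

    if obs < cfg.support_threshold:
        # no supported partner switch: no recombination signal to calibrate
        return MethodResult("BOOTSCAN", obs, 1.0)
    null = _bootscan_null(
        pidx, K, bits, starts, W, cfg.bootscan_reps, cfg.bootscan_n_perm, rng
    )
    p = _perm_pvalue(obs, null)

    bps: list[int] = []
    if obs >= cfg.support_threshold:
        dominant = np.where(
            sup[:, 0] >= cfg.support_threshold,
            1,
            np.where(sup[:, 1] >= cfg.support_threshold, 2, 0),
        )
        hit = np.flatnonzero(dominant)
        for a, b in zip(hit[:-1], hit[1:]):
            if dominant[a] != dominant[b]:
                ca = cols[starts[a] + W // 2]
                cb = cols[starts[b] + W // 2]
                bps = [int(round((ca + cb) / 2)) + 1]
                break
    return MethodResult("BOOTSCAN", obs, p, bps)


# ---------------------------------------------------------------------------
# Per-species orchestration and consensus
# ---------------------------------------------------------------------------

_DISPATCH = {
    "MAXCHI": maxchi,
    "CHIMAERA": chimaera,
    "THREESEQ": threeseq_walk,
    "GENECONV_LIKE": geneconv_like,
}


def analyze_species(
    species_types: list[PhageType], aln: AlignedSet, cfg: RunConfig
) -> list[TripletResult]:
    """Run all five methods on every triplet of one species' representatives.

    Species with fewer than three functional types yield no triplets.  The
    BootScan outgroup is the first remaining type representative outside the
    triplet (input order), or absent (method skipped) with exactly three.
    """
    reps = [t.representative_id for t in species_types]
    if len(reps) < 3:
        return []
    enc = _encoded(aln)
    trips = build_triplets(reps, aln)
    out = []
    for trip in trips:
        used = {trip.child, trip.parent1, trip.parent2}
        outgroup = next((r for r in reps if r not in used), None)
        results = {
            m: fn(trip, aln, cfg, _enc=enc) for m, fn in _DISPATCH.items()
        }
        results["BOOTSCAN"] = bootscan(trip, aln, cfg, outgroup=outgroup, _enc=enc)
        out.append(TripletResult(trip, results))
    return out


def _cut_estimate(result: MethodResult, info_sites: list[int]) -> int | None:
    """A method's single begin-breakpoint estimate for consensus merging.

    Cut-scan methods (MaxChi, Chimaera, BootScan) already report the switch
    column.  Segment methods (3Seq-walk, GENECONV-like) report the parental
    segment's two edges; when the segment touches the first or last
    informative site the informative boundary is the *other* edge — the
    splice point — so the edge-touching end is discarded.
    """
    if not result.breakpoints:
        return None
    if len(result.breakpoints) == 1:
        return result.breakpoints[0]
    lo, hi = result.breakpoints[0], result.breakpoints[-1]
    first, last = info_sites[0], info_sites[-1]
    if lo <= first and hi >= last:
        return None  # segment spans everything: no internal boundary
    if lo <= first:
        return hi
    if hi >= last:
        return lo
    return lo  # true internal segment: begin edge, the field's convention


def consensus_events(
    triplet_results: list[TripletResult],
    species_types: list[PhageType],
    cfg: RunConfig,
    species: str = "",
) -> list[RecombinationEvent]:
    """Combine per-method calls into consensus recombination events.

    Each method's p-value is Bonferroni-adjusted over the species' triplet
    count; a triplet with >= ``consensus_min_methods`` adjusted calls at
    ``alpha`` is a candidate.  Candidates sharing the child and a begin
    breakpoint within +/-10 columns merge into one event; the parent seen in
    the most candidates becomes the major parent, the rest minor parents
    (at most four), mirroring the one-major/one-to-four-minor event shapes.
    """
    n_tests = max(len(triplet_results), 1)
    type_of = {t.representative_id: t.name for t in species_types}
    candidates = []
    for tr in triplet_results:
        supporting = [
            r
            for r in tr.results.values()
            if min(1.0, r.p_value * n_tests) <= cfg.alpha
        ]
        if len(supporting) < cfg.consensus_min_methods:
            continue
        begins = [
            b
            for r in supporting
            for b in [_cut_estimate(r, tr.triplet.informative_sites)]
            if b is not None
        ]
        bp = int(np.median(begins)) if begins else -1
        candidates.append((tr, supporting, bp))

    # group by (child, breakpoint +/- 10)
    events: list[RecombinationEvent] = []
    used = [False] * len(candidates)
    for i, (tr_i, sup_i, bp_i) in enumerate(candidates):
        if used[i]:
            continue
        group = [(tr_i, sup_i, bp_i)]
        used[i] = True
        for j in range(i + 1, len(candidates)):
            tr_j, sup_j, bp_j = candidates[j]
            if used[j]:
                continue
            if tr_j.triplet.child == tr_i.triplet.child and abs(bp_j - bp_i) <= 10:
                group.append((tr_j, sup_j, bp_j))
                used[j] = True
        partner_counts: dict[str, int] = {}
        for tr, _, _ in group:
            for pid in (tr.triplet.parent1, tr.triplet.parent2):
                partner_counts[pid] = partner_counts.get(pid, 0) + 1
        ranked = sorted(partner_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        major = ranked[0][0]
        minors = [pid for pid, _ in ranked[1:5]] or [ranked[0][0]]
        best = max(
            group, key=lambda g: (len(g[1]), -min(r.p_value for r in g[1]))
        )
        events.append(
            RecombinationEvent(
                species=species,
                recombinant=type_of.get(tr_i.triplet.child, tr_i.triplet.child),
                major_parent=type_of.get(major, major),
                minor_parents=[type_of.get(m, m) for m in minors],
                breakpoints=sorted({g[2] for g in group if g[2] >= 0}),
                supporting=best[1],
                n_methods=len(best[1]),
            )
        )
    events.sort(key=lambda e: e.recombinant)
    return events


def detect_recombination(
    types: list[PhageType], aln: AlignedSet, cfg: RunConfig
) -> list[RecombinationEvent]:
    """Per-species recombination screen over functional type representatives.

    The scan runs within species by default — recombination is sought among
    the phage complement of a single host — skipping (and implicitly
    reporting, via zero events) species with fewer than three types.
    """
    by_species: dict[str, list[PhageType]] = {}
    for t in types:
        for sp in t.species:
            by_species.setdefault(sp, []).append(t)
    events = []
    for sp in sorted(by_species):
        sp_types = by_species[sp]
        if len(sp_types) < 3:
            continue
        ids = {m for t in sp_types for m in t.member_ids}
        sub = aln.subset(ids)
        res = analyze_species(sp_types, sub, cfg)
        events.extend(consensus_events(res, sp_types, cfg, species=sp))
    return events


def events_table(events: list[RecombinationEvent]) -> pd.DataFrame:
    """Table-2-style report: one row per event."""
    rows = []
    for e in events:
        rows.append(
            {
                "Insect": e.species,
                "Recombinant": e.recombinant,
                "Major parent": e.major_parent,
                "Minor parent(s)": " ".join(e.minor_parents),
                "Breakpoint": "/".join(str(b) for b in e.breakpoints),
                "Methods": " ".join(r.method for r in e.supporting),
                "P-values": " ".join(f"{r.p_value:.3g}" for r in e.supporting),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "Insect", "Recombinant", "Major parent", "Minor parent(s)",
            "Breakpoint", "Methods", "P-values",
        ],
    )
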