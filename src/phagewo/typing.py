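"""Phage WO typing: pseudogene filtering, K2P distances, type clustering.

A phage WO *type* (haplotype) is a cluster of orf7 sequences within 1.5%
Kimura 2-parameter divergence (equivalently >=98.5% identity).  Sequences with
internal stop codons are orf7-like pseudogenes and are excluded from typing
but retained in reports.  Types are named ``WO`` + a host abbreviation +
an index (e.g. ``WOPma-15``); a species carrying a single type gets no index.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform

from .core_io import AlignedSet, RunConfig, SequenceRecord, UNKNOWN

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: sentinel for a K2P distance whose log argument is non-positive
UNDEFINED = math.inf

# nucleotide encoding used throughout: A=0, C=1, G=2, T=3, N=4, -=5
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_PURINE = (0, 2)


class FrameError(ValueError):
    """No reading frame yields a stop-free consensus."""


class UndefinedDistanceError(ValueError):
    """A pairwise distance could not be computed (no effective sites)."""


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy().view(np.uint8)


_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _v in _ENC.items():
    _LUT[ord(_c)] = _v


def encode_alignment(aln: AlignedSet) -> np.ndarray:
    """(n_records, length) uint8 matrix with the A/C/G/T/N/- encoding."""
    mat = np.empty((len(aln.records), aln.length), dtype=np.uint8)
    for i, r in enumerate(aln.records):
        mat[i] = _LUT[np.frombuffer(r.seq.encode(), dtype=np.uint8)]
    return mat


# ---------------------------------------------------------------------------
# Pseudogene filter
# ---------------------------------------------------------------------------

def _has_internal_stop(seq: str, frame: int) -> bool:
    """Internal stop in `frame` (1..3 on alignment columns), own gaps removed."""
    coding = seq[frame - 1:].replace("-", "")
    n_codons = len(coding) // 3
    for k in range(n_codons - 1):  # final (complete) codon is not internal
        if coding[3 * k: 3 * k + 3] in STOP_CODONS:
            return True
    return False


def consensus_sequence(aln: AlignedSet) -> str:
    """Column-wise majority consensus (gaps/N lose ties to real bases)."""
    mat = encode_alignment(aln)
    cons = []
    for col in mat.T:
        counts = np.bincount(col, minlength=6)
        counts[4] = 0  # N never wins
        counts[5] = 0  # gap never wins
        if counts[:4].sum() == 0:
            cons.append("-")
        else:
            cons.append("ACGT"[int(np.argmax(counts[:4]))])
    return "".join(cons)


def detect_frame(aln: AlignedSet) -> int:
    """Reading frame (1..3) in which the majority consensus is stop-free."""
    cons = consensus_sequence(aln)
    for frame in (1, 2, 3):
        if not _has_internal_stop(cons, frame):
            return frame
    raise FrameError(
        "no reading frame gives a stop-free consensus; "
        "specify the frame manually"
    )


def flag_pseudogenes(aln: AlignedSet, frame: int | None = None) -> AlignedSet:
    """Flag orf7-like sequences with internal stop codons as pseudogenes.

    The amplicon is an internal gene fragment, so a stop in the final codon
    does not disqualify a sequence.  Pseudogenes are excluded from typing and
    all downstream stages but retained in output reports.
    """
    if frame is None:
        frame = detect_frame(aln)
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2 or 3")
    out = [
        replace(r, is_pseudogene=_has_internal_stop(r.seq, frame))
        for r in aln
    ]
    return AlignedSet(out, aln.length)


# ---------------------------------------------------------------------------
# Kimura 2-parameter distance
# ---------------------------------------------------------------------------

def k2p_distance(a: str, b: str) -> tuple[float, float, float, int]:
    """K2P distance between two aligned sequences, pairwise deletion.

    Columns where either sequence carries a gap or ``N`` are dropped; over the
    remaining ``n_eff`` columns, ``P`` is the transition proportion (A<->G,
    C<->T), ``Q`` the transversion proportion, and

        d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)).

    When the log argument is non-positive the distance is saturated and
    returned as ``UNDEFINED`` (infinity, greater than any threshold).

    Returns ``(d, P, Q, n_eff)``; raises :class:`UndefinedDistanceError`
    when no effective sites remain.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    xa = _LUT[np.frombuffer(a.upper().encode(), dtype=np.uint8)]
    xb = _LUT[np.frombuffer(b.upper().encode(), dtype=np.uint8)]
    return _k2p_encoded(xa, xb)


def _k2p_encoded(xa: np.ndarray, xb: np.ndarray) -> tuple[float, float, float, int]:
    valid = (xa < 4) & (xb < 4)
    n_eff = int(valid.sum())
    if n_eff == 0:
        raise UndefinedDistanceError("no effective (ungapped, unambiguous) sites")
    va, vb = xa[valid], xb[valid]
    diff = va != vb
    # transitions: both purines (A,G) or both pyrimidines (C,T)
    ts = diff & ((va % 2) == (vb % 2))
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    P = n_ts / n_eff
    Q = n_tv / n_eff
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return UNDEFINED, P, Q, n_eff
    return -0.5 * math.log(w1 * math.sqrt(w2)), P, Q, n_eff


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Uncorrected proportion of differing effective sites."""
    xa = _LUT[np.frombuffer(a.upper().encode(), dtype=np.uint8)]
    xb = _LUT[np.frombuffer(b.upper().encode(), dtype=np.uint8)]
    valid = (xa < 4) & (xb < 4)
    n_eff = int(valid.sum())
    if n_eff == 0:
        raise UndefinedDistanceError("no effective sites")
    return float((xa[valid] != xb[valid]).sum()) / n_eff, n_eff


@dataclass
class DistanceMatrix:
    """Pairwise K2P distances with their transition/transversion parts.

    ``d[i, j]`` is infinity when the K2P log argument was non-positive
    (saturated pair); such pairs never merge during clustering.
    """

    ids: list[str]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    n_eff: np.ndarray

    def index(self, rec_id: str) -> int:
        return self.ids.index(rec_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.d[self.index(id_a), self.index(id_b)])


def distance_matrix(aln: AlignedSet, mode: str = "k2p_distance") -> DistanceMatrix:
    """All pairwise distances over an alignment (pairwise deletion).

    ``mode='p_identity'`` stores uncorrected p-distances in ``d`` (and zeros
    in P/Q); clustering against the same threshold then realises the
    "identity >= 98.5%" reading of the type definition.
    """
    mat = encode_alignment(aln)
    n = len(aln.records)
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    n_eff = np.zeros((n, n), dtype=int)
    for i in range(n):
        n_eff[i, i] = int((mat[i] < 4).sum())
        for j in range(i + 1, n):
            if mode == "p_identity":
                pd_, ne = p_distance(aln.records[i].seq, aln.records[j].seq)
                dij, pij, qij, neij = pd_, 0.0, 0.0, ne
            else:
                dij, pij, qij, neij = _k2p_encoded(mat[i], mat[j])
            d[i, j] = d[j, i] = dij
            P[i, j] = P[j, i] = pij
            Q[i, j] = Q[j, i] = qij
            n_eff[i, j] = n_eff[j, i] = neij
    return DistanceMatrix([r.id for r in aln.records], d, P, Q, n_eff)


# ---------------------------------------------------------------------------
# Clustering into phage types
# ---------------------------------------------------------------------------

@dataclass
class PhageType:
    """One phage WO type: a cluster of orf7 sequences.

    ``name`` follows the field convention WO + host abbreviation + haplotype
    index; for global-scope clusters spanning several species, ``name`` is
    the cluster id and per-species names are listed in ``species_names``.
    """

    name: str
    member_ids: list[str]
    representative_id: str
    hosts: set = field(default_factory=set)  # {(species, strain_st)}
    species_names: dict = field(default_factory=dict)  # species -> local name

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def species(self) -> set:
        return {sp for sp, _ in self.hosts}


def host_abbreviation(species: str) -> str:
    """Genus initial + first two letters of the epithet (Pma, Ebl, Ssp...)."""
    parts = species.split()
    if len(parts) < 2:
        return re.sub(r"[^A-Za-z]", "", species)[:3].capitalize()
    genus = parts[0]
    epithet_letters = re.sub(r"[^A-Za-z]", "", " ".join(parts[1:]))
    return genus[0].upper() + epithet_letters[:2].lower()


def _component_labels(d: np.ndarray, threshold: float, method: str) -> np.ndarray:
    n = d.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)
    if method == "single":
        adj = csr_matrix((d <= threshold).astype(np.int8))
        _, labels = connected_components(adj, directed=False)
        return labels
    # complete linkage: saturate undefined distances so they never merge
    dd = np.where(np.isfinite(d), d, 1e6)
    condensed = squareform(dd, checks=False)
    z = _scipy_linkage(condensed, method="complete")
    return fcluster(z, t=threshold, criterion="distance") - 1


def cluster_types(
    dm: DistanceMatrix,
    aln: AlignedSet,
    cfg: RunConfig | None = None,
    scope: str = "per_species",
) -> list[PhageType]:
    """Cluster functional sequences into phage WO types.

    With the default single linkage, a type is a connected component of the
    graph whose edges join pairs with d <= ``type_threshold``; with complete
    linkage, agglomerative clustering is cut at the threshold (so all
    intra-type pairs satisfy it).  Undefined (saturated) distances never
    merge.  Output is deterministic: types ordered by (size desc, first-seen
    member id), per-species names numbered in that order; a species carrying
    exactly one type gets the bare ``WO<abbr>`` name.

    ``scope='global'`` clusters all species jointly — the mode used for
    horizontal-transfer detection — while names remain species-local, held
    as cross-references on each cluster.
    """
    cfg = cfg or RunConfig()
    if any(r.is_pseudogene for r in aln.records):
        raise ValueError("pseudogenes must be excluded before typing")
    if not aln.records:
        return []
    by_id = {r.id: r for r in aln.records}
    order = {rid: k for k, rid in enumerate(dm.ids)}

    if scope == "per_species":
        types: list[PhageType] = []
        for sp in sorted({r.species for r in aln.records}):
            ids = [rid for rid in dm.ids if by_id[rid].species == sp]
            idx = np.array([dm.index(r) for r in ids])
            sub = dm.d[np.ix_(idx, idx)]
            labels = _component_labels(sub, cfg.type_threshold, cfg.linkage)
            clusters = _ordered_clusters(labels, ids, order)
            abbr = host_abbreviation(sp)
            single = len(clusters) == 1
            for k, members in enumerate(clusters, start=1):
                name = f"WO{abbr}" if single else f"WO{abbr}-{k}"
                types.append(_make_type(name, members, by_id))
        types.sort(key=lambda t: (-t.size, t.member_ids[0]))
        return types

    if scope != "global":
        raise ValueError(f"unknown scope {scope!r}")

    labels = _component_labels(dm.d, cfg.type_threshold, cfg.linkage)
    clusters = _ordered_clusters(labels, list(dm.ids), order)
    # species-local names come from per-species clustering of the same data
    local = cluster_types(dm, aln, cfg, scope="per_species")
    local_name = {m: t.name for t in local for m in t.member_ids}
    types = []
    for k, members in enumerate(clusters, start=1):
        t = _make_type(f"G{k}", members, by_id)
        for m in members:
            sp = by_id[m].species
            t.species_names.setdefault(sp, local_name.get(m, ""))
        types.append(t)
    return types


def _ordered_clusters(labels, ids, global_order):
    groups: dict[int, list[str]] = {}
    for lab, rid in zip(labels, ids):
        groups.setdefault(int(lab), []).append(rid)
    clusters = [sorted(g, key=lambda r: global_order[r]) for g in groups.values()]
    clusters.sort(key=lambda g: (-len(g), g[0]))
    return clusters


def _make_type(name, members, by_id) -> PhageType:
    hosts = {(by_id[m].species, by_id[m].strain_st) for m in members}
    return PhageType(
        name=name,
        member_ids=list(members),
        representative_id=members[0],
        hosts=hosts,
    )


def intra_type_violations(
    types: list[PhageType], dm: DistanceMatrix, threshold: float
) -> list[tuple[str, str, str, float]]:
    """Intra-type pairs exceeding the threshold (possible under single linkage
    via chaining); reported so the transitivity cost is visible."""
    out = []
    for t in types:
        for i, a in enumerate(t.member_ids):
            for b in t.member_ids[i + 1:]:
                dab = dm.get(a, b)
                if dab > threshold:
                    out.append((t.name, a, b, dab))
    return out


# ---------------------------------------------------------------------------
# Per-host summary
# ---------------------------------------------------------------------------

def summarize_types(types: list[PhageType], aln: AlignedSet):
    """One :class:`~phagewo.core_io.HostRecord` per species with its type
    count; a host is multi-infected when it carries more than two types."""
    from .core_io import HostRecord

    meta = {}
    for r in aln.records:
        meta.setdefault(
            r.species, (r.family, r.strain_st, r.wsp_allele, r.supergroup)
        )
    counts: dict[str, int] = {sp: 0 for sp in meta}
    for t in types:
        for sp in t.species:
            counts[sp] = counts.get(sp, 0) + 1
    return [
        HostRecord(
            species=sp,
            family=meta[sp][0],
            strain_st=meta[sp][1],
            wsp_allele=meta[sp][2],
            supergroup=meta[sp][3],
            n_types=counts[sp],
        )
        for sp in sorted(meta)
    ]
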