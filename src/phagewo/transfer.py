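"""Horizontal-transfer enumeration for phage WO.

A transfer event is one *global* phage type whose member sequences occur in
hosts carrying at least two distinct *Wolbachia* strains: the phage moved
between symbiont lineages (directionality is not inferred).  Hosts whose ST
could not be resolved participate through pseudo-strain keys; events whose
strain contrast rests only on pseudo-strains are flagged ``st_unresolved``
rather than dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import UNKNOWN, AlignedSet, strain_key
from .typing import DistanceMatrix, PhageType, encode_alignment


@dataclass
class TransferEvent:
    """One phage type observed across >=2 distinct Wolbachia strains."""

    global_type_id: str
    member_type_names: set
    strains: set
    species: set
    supergroups: Counter
    cross_supergroup: bool
    min_interhost_distance: float
    st_unresolved: bool = False

    @property
    def n_strains(self) -> int:
        return len(self.strains)


def enumerate_transfers(
    global_types: list[PhageType],
    aln: AlignedSet,
    dm: DistanceMatrix | None = None,
) -> list[TransferEvent]:
    """Events = global types spanning >=2 strain keys, sorted by
    (strain count desc, type id).

    ``min_interhost_distance`` (smallest K2P between members from different
    strains) is recorded when a distance matrix is supplied; under single
    linkage it is bounded by the clustering threshold.
    """
    by_id = {r.id: r for r in aln.records}
    events = []
    for t in global_types:
        members = [by_id[m] for m in t.member_ids]
        keys = {strain_key(r) for r in members}
        if len(keys) < 2:
            continue
        resolved = {r.strain_st for r in members if r.strain_st != UNKNOWN}
        supergroups = Counter(r.supergroup for r in members)
        min_d = float("nan")
        if dm is not None:
            dists = [
                dm.get(a.id, b.id)
                for i, a in enumerate(members)
                for b in members[i + 1:]
                if strain_key(a) != strain_key(b)
            ]
            if dists:
                min_d = float(min(dists))
        names = {
            t.species_names.get(sp) or t.name
            for sp in {r.species for r in members}
        }
        events.append(
            TransferEvent(
                global_type_id=t.name,
                member_type_names=names,
                strains=keys,
                species={r.species for r in members},
                supergroups=supergroups,
                cross_supergroup=("A" in supergroups and "B" in supergroups),
                min_interhost_distance=min_d,
                st_unresolved=len(resolved) < 2,
            )
        )
    events.sort(key=lambda e: (-e.n_strains, e.global_type_id))
    return events


def strict_identity_transfers(
    aln: AlignedSet, max_diff: int = 1
) -> list[TransferEvent]:
    """Alternate tally under strict near-identity.

    Groups sequences whose raw mismatch count (pairwise deletion) is
    <= ``max_diff`` — the "identical orf7 sequences or one base substitution"
    reading — by single linkage, then enumerates cross-strain groups.  Emitted
    alongside the cluster-threshold tally because the two criteria need not
    agree.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    mat = encode_alignment(aln)
    n = len(aln.records)
    adj = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        for j in range(i + 1, n):
            valid = (mat[i] < 4) & (mat[j] < 4)
            if valid.any():
                nd = int((mat[i][valid] != mat[j][valid]).sum())
                if nd <= max_diff:
                    adj[i, j] = adj[j, i] = 1
    _, labels = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[int]] = {}
    for k, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(k)
    types = []
    for gi, idxs in sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[1][0])):
        members = [aln.records[i].id for i in idxs]
        t = PhageType(
            name=f"S{gi + 1}",
            member_ids=members,
            representative_id=members[0],
            hosts={(aln.records[i].species, aln.records[i].strain_st) for i in idxs},
        )
        types.append(t)
    return enumerate_transfers(types, aln)


def shared_types_within_strain(
    global_types: list[PhageType], aln: AlignedSet, strain: str
) -> pd.DataFrame:
    """For one strain, which global types are shared by >=2 of its host
    species and which are private to a single species.

    Raises ``KeyError`` if no sequence carries the strain.
    """
    strains_present = {strain_key(r) for r in aln.records}
    if strain not in strains_present:
        raise KeyError(f"strain {strain!r} not present in dataset")
    by_id = {r.id: r for r in aln.records}
    rows = []
    for t in global_types:
        sp_in_strain = {
            by_id[m].species
            for m in t.member_ids
            if strain_key(by_id[m]) == strain
        }
        if not sp_in_strain:
            continue
        rows.append(
            {
                "type": t.name,
                "species": ";".join(sorted(sp_in_strain)),
                "n_species": len(sp_in_strain),
                "status": "shared" if len(sp_in_strain) >= 2 else "private",
            }
        )
    return pd.DataFrame(rows, columns=["type", "species", "n_species", "status"])


def incidence_matrix(
    global_types: list[PhageType], aln: AlignedSet
) -> pd.DataFrame:
    """Type x strain 0/1 incidence table (TSV-friendly)."""
    by_id = {r.id: r for r in aln.records}
    strains = sorted({strain_key(r) for r in aln.records})
    data = {}
    for t in global_types:
        present = {strain_key(by_id[m]) for m in t.member_ids}
        data[t.name] = [int(s in present) for s in strains]
    return pd.DataFrame.from_dict(data, orient="index", columns=strains)
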