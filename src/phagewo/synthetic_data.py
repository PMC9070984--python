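"""Synthetic aligned orf7-like datasets with planted ground truth.

The generator emulates the structure of the butterfly survey: several host
species, each carrying a single *Wolbachia* strain, each strain hosting a
pool of phage WO types that diverge well beyond the 1.5% typing threshold
between types and well below it within types.  On top of that baseline it
plants the three signals the pipeline must recover:

* horizontal transfers — a donor type's ancestor copied into a host with a
  different strain, so the transferred type is identical or nearly identical
  across strains;
* recombinants — a child type spliced from two parent-type ancestors at a
  known (codon-aligned) breakpoint;
* pseudogenes — members of real types given one internal stop codon, so they
  would co-cluster with their source type if the filter missed them.

Sequences evolve under the K80 two-parameter substitution model (transition/
transversion ratio ``kappa``), the model whose distance the typing stage
assumes, so distance estimation is unbiased by construction.  Everything is
seeded and byte-reproducible.  No indels: the output is aligned by
construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import AlignedSet, HostRecord, SequenceRecord
from .typing import STOP_CODONS, host_abbreviation

_NUC = "ACGT"
#: transition partner: A<->G, C<->T (index arithmetic on "ACGT")
_TS_PARTNER = {0: 2, 1: 3, 2: 0, 3: 1}

_DEFAULT_SPECIES = {
    # species: (family, strain, wsp allele, supergroup, n baseline types)
    "Pseudozizeeria maha": ("Lycaenidae", "ST-41", "wsp-10", "B", 4),
    "Eurema hecabe": ("Pieridae", "ST-41", "wsp-10", "B", 3),
    "Ypthima praenubila": ("Nymphalidae", "ST-19", "wsp-108", "A", 3),
    "Junonia almana": ("Nymphalidae", "ST-125", "wsp-10", "B", 3),
    "Colias croceus": ("Pieridae", "ST-141", "wsp-61", "B", 3),
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic datasets.

    Defaults mirror the survey's structure at desk scale: five butterfly
    species, one strain each (two strains shared, supergroups A and B both
    present), 3–4 phage types per species, one planted cross-strain transfer,
    one planted recombinant and two planted pseudogenes.  ``seq_length`` is
    the orf7 amplicon scale (399 columns; must be divisible by 3 so that the
    in-frame stop machinery is well defined).  Divergences are expected K2P
    distances: within-type far below the 1.5% typing threshold, between-type
    far above it.
    """

    species: dict = field(default_factory=lambda: dict(_DEFAULT_SPECIES))
    seq_length: int = 399
    kappa: float = 2.0
    within_type_div: float = 0.003
    between_type_div: float = 0.08
    members_per_type: int = 3
    n_transfers: int = 1
    n_recombinants: int = 1
    recombinant_breakpoints: list[int] | str = "random central"
    n_pseudogenes: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length % 3:
            raise ValueError("seq_length must be divisible by 3")
        if not self.within_type_div < 0.015 < self.between_type_div:
            raise ValueError(
                "need within_type_div < type threshold (0.015) "
                "< between_type_div"
            )
        for sp, tup in self.species.items():
            if len(tup) != 5:
                raise ValueError(f"species entry for {sp!r} malformed")


@dataclass
class SyntheticTruth:
    """Planted signals, the recovery oracle for every pipeline stage."""

    type_assignment: dict  # functional sequence id -> planted type id
    transfer_events: list  # [(type id, sorted list of strains)]
    recombinants: list  # [(child type id, [parent type ids], [breakpoints])]
    pseudogene_ids: list
    n_transitions: int = 0
    n_transversions: int = 0

    def types_per_species(self, aln: AlignedSet) -> dict:
        by_id = {r.id: r for r in aln.records}
        out: dict[str, set] = {}
        for rid, t in self.type_assignment.items():
            out.setdefault(by_id[rid].species, set()).add(t)
        return {sp: len(ts) for sp, ts in out.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


class _K80:
    """Poisson-events K80 mutator; counts realised transition/transversion
    events so the kappa calibration is checkable."""

    def __init__(self, kappa: float, rng: np.random.Generator):
        self.p_ts = kappa / (kappa + 2.0)
        self.rng = rng
        self.n_ts = 0
        self.n_tv = 0

    def evolve(self, seq: np.ndarray, d: float) -> np.ndarray:
        """Apply Poisson(d * L) substitution events (multiple hits allowed;
        the K2P estimator corrects for them downstream)."""
        out = seq.copy()
        n_events = int(self.rng.poisson(d * seq.size))
        for _ in range(n_events):
            site = int(self.rng.integers(seq.size))
            base = int(out[site])
            if self.rng.random() < self.p_ts:
                out[site] = _TS_PARTNER[base]
                self.n_ts += 1
            else:
                others = [b for b in range(4) if b != base and b != _TS_PARTNER[base]]
                out[site] = others[int(self.rng.integers(2))]
                self.n_tv += 1
        return out


def _decode(arr: np.ndarray) -> str:
    return "".join(_NUC[b] for b in arr)


def _has_internal_stop_arr(arr: np.ndarray) -> bool:
    s = _decode(arr)
    n = len(s) // 3
    return any(s[3 * k: 3 * k + 3] in STOP_CODONS for k in range(n - 1))


def _evolve_stop_free(mut: _K80, seq: np.ndarray, d: float) -> np.ndarray:
    # keep functional sequences genuinely functional (frame-1 ORF fragment)
    for _ in range(100):
        cand = mut.evolve(seq, d)
        if not _has_internal_stop_arr(cand):
            return cand
    raise RuntimeError("could not evolve a stop-free sequence")


def _root_orf(length: int, rng: np.random.Generator) -> np.ndarray:
    codons = []
    while len(codons) * 3 < length:
        c = rng.integers(0, 4, size=3)
        if _decode(c) in STOP_CODONS:
            continue
        codons.append(c)
    return np.concatenate(codons)[:length]


def simulate(cfg: SimConfig | None = None) -> tuple[AlignedSet, SyntheticTruth]:
    """Generate an annotated aligned dataset plus its planted truth.

    Type ancestors sit at ``between_type_div / 2`` from a shared stop-free
    root (so pairs of types are ~``between_type_div`` apart); members sit at
    ``within_type_div / 2`` from their ancestor.  Transfers copy a donor
    ancestor into a recipient species with a different strain before member
    noise, so the transferred type shows the identical-or-one-substitution
    signature across strains.  Recombinant breakpoints are snapped to codon
    starts so the splice cannot create a stop codon.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    mut = _K80(cfg.kappa, rng)
    root = _root_orf(cfg.seq_length, rng)

    species = sorted(cfg.species)
    ancestors: dict[str, np.ndarray] = {}  # planted type id -> ancestor
    type_host: dict[str, list[str]] = {}  # planted type id -> species list
    counter = 0
    for sp in species:
        n_types = cfg.species[sp][4]
        for _ in range(n_types):
            counter += 1
            tid = f"T{counter:02d}"
            ancestors[tid] = _evolve_stop_free(
                mut, root, cfg.between_type_div / 2.0
            )
            type_host[tid] = [sp]

    truth_transfers = []
    strain_of = {sp: cfg.species[sp][1] for sp in species}
    for _ in range(cfg.n_transfers):
        donor_tid = str(rng.choice(sorted(ancestors)))
        donor_sp = type_host[donor_tid][0]
        recipients = [
            sp for sp in species
            if strain_of[sp] != strain_of[donor_sp] and sp not in type_host[donor_tid]
        ]
        if not recipients:
            raise ValueError("no valid transfer recipient: all strains equal")
        rec_sp = str(rng.choice(recipients))
        type_host[donor_tid].append(rec_sp)
        truth_transfers.append(
            (donor_tid, sorted({strain_of[donor_sp], strain_of[rec_sp]}))
        )

    truth_recomb = []
    for _ in range(cfg.n_recombinants):
        eligible = [
            sp for sp in species
            if sum(sp in hosts for hosts in type_host.values()) >= 2
        ]
        sp = str(rng.choice(sorted(eligible)))
        sp_tids = sorted(
            t for t, hosts in type_host.items()
            if sp in hosts and not any(t == r[0] for r in truth_recomb)
        )
        p1, p2 = (str(t) for t in rng.choice(sp_tids, size=2, replace=False))
        if cfg.recombinant_breakpoints == "random central":
            bp = int(rng.integers(cfg.seq_length // 3, 2 * cfg.seq_length // 3))
        else:
            bp = int(cfg.recombinant_breakpoints[len(truth_recomb)])
        bp = 3 * ((bp - 1) // 3) + 1  # snap to a codon start (1-based)
        child = np.concatenate(
            [ancestors[p1][: bp - 1], ancestors[p2][bp - 1:]]
        )
        counter += 1
        tid = f"T{counter:02d}"
        ancestors[tid] = child
        type_host[tid] = [sp]
        truth_recomb.append((tid, [p1, p2], [bp]))

    # emit members
    records: list[SequenceRecord] = []
    type_assignment: dict[str, str] = {}
    for tid in sorted(ancestors):
        for sp in type_host[tid]:
            abbr = host_abbreviation(sp)
            fam, st, wsp, sg, _ = cfg.species[sp]
            for m in range(1, cfg.members_per_type + 1):
                seq = _evolve_stop_free(
                    mut, ancestors[tid], cfg.within_type_div / 2.0
                )
                rid = f"{abbr}_{tid}_m{m}"
                records.append(
                    SequenceRecord(
                        id=rid, seq=_decode(seq), species=sp, family=fam,
                        strain_st=st, wsp_allele=wsp, supergroup=sg,
                    )
                )
                type_assignment[rid] = tid

    pseudogene_ids = []
    source_tids = sorted(ancestors)
    for k in range(cfg.n_pseudogenes):
        tid = str(rng.choice(source_tids))
        sp = type_host[tid][0]
        abbr = host_abbreviation(sp)
        fam, st, wsp, sg, _ = cfg.species[sp]
        seq = mut.evolve(ancestors[tid], cfg.within_type_div / 2.0)
        n_codons = cfg.seq_length // 3
        codon = int(rng.integers(1, n_codons - 1))  # strictly internal
        stop = list("TAA")
        seq[3 * codon: 3 * codon + 3] = [_NUC.index(c) for c in stop]
        rid = f"{abbr}_{tid}_ps{k + 1}"
        records.append(
            SequenceRecord(
                id=rid, seq=_decode(seq), species=sp, family=fam,
                strain_st=st, wsp_allele=wsp, supergroup=sg,
            )
        )
        pseudogene_ids.append(rid)

    aln = AlignedSet(records, cfg.seq_length)
    truth = SyntheticTruth(
        type_assignment=type_assignment,
        transfer_events=truth_transfers,
        recombinants=truth_recomb,
        pseudogene_ids=pseudogene_ids,
        n_transitions=mut.n_ts,
        n_transversions=mut.n_tv,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Packaged survey fixture (the 19 Wolbachia-infected butterfly hosts)
# ---------------------------------------------------------------------------

_TABLE1 = [
    # family, species, ST, wsp allele, supergroup, n phage WO types
    ("Hesperiidae", "Isoteinon sp.", "ST-41", "wsp-10", "B", 9),
    ("Hesperiidae", "Notocrypta sp.", "ST-41", "wsp-10", "B", 8),
    ("Hesperiidae", "Ochlodes thibetana", "ST-374", "wsp-64", "B", 5),
    ("Lycaenidae", "Pseudozizeeria maha", "ST-41", "wsp-10", "B", 17),
    ("Nymphalidae", "Ariadne ariadne", "ST-41", "wsp-10", "B", 3),
    ("Nymphalidae", "Junonia almana", "ST-125", "wsp-10", "B", 8),
    ("Nymphalidae", "Limenitis doerriesi", "ST-297", "wsp-61", "B", 1),
    ("Nymphalidae", "Mycalesis francisca", "UNKNOWN", "wsp-10", "B", 9),
    ("Nymphalidae", "Polygonia c-aureum", "ST-wPcau", "wsp-266", "B", 1),
    ("Nymphalidae", "Stichophthalma sp.", "ST-374", "wsp-64", "B", 2),
    ("Nymphalidae", "Vanessa indica", "ST-125", "wsp-10", "B", 8),
    ("Nymphalidae", "Ypthima praenubila", "ST-19", "wsp-108", "A", 10),
    ("Nymphalidae", "Ypthima sp.", "ST-19", "wsp-108", "A", 6),
    ("Papilionidae", "Parnassius stubbendorfii", "UNKNOWN", "wsp-369", "B", 7),
    ("Pieridae", "Colias croceus", "ST-141", "wsp-61", "B", 8),
    ("Pieridae", "Delias agostina", "UNKNOWN", "wsp-10", "B", 7),
    ("Pieridae", "Eurema blanda", "ST-41", "wsp-10", "B", 8),
    ("Pieridae", "Eurema hecabe", "ST-41", "wsp-10", "B", 5),
    ("Pieridae", "Leptosia nina", "ST-41", "wsp-10", "B", 4),
]


def fixture_table1() -> list[HostRecord]:
    """The 19 surveyed Wolbachia-infected butterfly hosts: family, MLST
    sequence type, wsp allele, supergroup and observed phage WO type count.
    Strain cells the survey could not resolve are ``UNKNOWN``."""
    return [
        HostRecord(
            species=sp, family=fam, strain_st=st,
            wsp_allele=wsp, supergroup=sg, n_types=n,
        )
        for fam, sp, st, wsp, sg, n in _TABLE1
    ]
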