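"""Shared domain types and I/O for the phage WO typing pipeline.

The pipeline operates on an *aligned* multi-FASTA of orf7 marker sequences
(the phage WO minor capsid gene fragment used for typing) plus a tab-separated
host-metadata table mapping each sequence to its butterfly host and the host's
*Wolbachia* strain (MLST sequence type, wsp allele, supergroup).  Alignment is
an input contract: the pipeline never aligns, and unequal-length input is an
error.  All coordinates are 1-based inclusive alignment columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

UNKNOWN = "UNKNOWN"

#: nucleotide alphabet accepted in aligned input (gap and ambiguity included)
ALPHABET = frozenset("ACGTN-")


class AlignmentError(ValueError):
    """Input sequences are not a valid alignment (unequal lengths)."""


class ParseError(ValueError):
    """Malformed FASTA/TSV input."""


class MetadataError(KeyError):
    """A sequence in the alignment has no host-metadata row."""


@dataclass
class SequenceRecord:
    """One orf7 (or MLST) sequence with its host/strain annotations.

    ``strain_st`` is the *Wolbachia* MLST sequence type (e.g. ``ST-41``) or
    ``UNKNOWN`` when MLST loci failed to amplify; such hosts still participate
    in transfer enumeration via a pseudo-strain key (see :func:`strain_key`).
    """

    id: str
    seq: str
    species: str = UNKNOWN
    family: str = UNKNOWN
    strain_st: str = UNKNOWN
    wsp_allele: str = UNKNOWN
    supergroup: str = UNKNOWN  # "A", "B" or UNKNOWN
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ParseError(f"record {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = [(i, c) for i, c in enumerate(self.seq, 1) if c not in ALPHABET]
        if bad:
            i, c = bad[0]
            raise ParseError(
                f"record {self.id!r}: illegal character {c!r} at position {i}"
            )


def strain_key(rec: SequenceRecord) -> str:
    """Strain identifier used for transfer enumeration.

    Hosts whose ST could not be resolved are kept as their own pseudo-strain
    keyed by (species, wsp allele) so that they can still anchor transfer
    events, mirroring how hosts with incomplete MLST profiles were retained
    in the source analysis.
    """
    if rec.strain_st != UNKNOWN:
        return rec.strain_st
    return f"{rec.species}|wsp:{rec.wsp_allele}"


@dataclass
class AlignedSet:
    """An alignment: equal-length records, 1-based column coordinates."""

    records: list[SequenceRecord]
    length: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        offenders = []
        for r in self.records:
            if r.id in seen:
                raise ParseError(f"duplicate sequence id {r.id!r}")
            seen.add(r.id)
            if len(r.seq) != self.length:
                offenders.append(f"{r.id} ({len(r.seq)} != {self.length})")
        if offenders:
            raise AlignmentError(
                "unequal sequence lengths: " + ", ".join(offenders)
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def functional(self) -> "AlignedSet":
        """Records not flagged as pseudogenes."""
        return AlignedSet(
            [r for r in self.records if not r.is_pseudogene], self.length
        )

    def subset(self, ids) -> "AlignedSet":
        wanted = set(ids)
        return AlignedSet(
            [r for r in self.records if r.id in wanted], self.length
        )


@dataclass
class HostRecord:
    """One host species row: its Wolbachia strain and phage-type count."""

    species: str
    family: str
    strain_st: str
    wsp_allele: str
    supergroup: str
    n_types: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 0:
            raise ValueError("n_types must be >= 0")

    @property
    def multi_infected(self) -> bool:
        """More than two phage types — the multiple-infection criterion."""
        return self.n_types > 2


@dataclass
class RunConfig:
    """Pipeline parameters.

    type_threshold
        K2P distance above which two orf7 sequences belong to different phage
        types (1.5% divergence, equivalently 98.5% identity).
    identity_mode
        ``k2p_distance`` (default) clusters on K2P distance <= threshold;
        ``p_identity`` clusters on uncorrected identity >= 1 - threshold.
    linkage
        ``single`` (default): types are connected components of the
        <=threshold graph; ``complete``: agglomerative complete linkage cut at
        the threshold.
    consensus_min_methods
        Minimum number of detection methods (of 5) that must call a triplet
        significant for a recombination event to be reported.
    alpha
        Per-method significance cutoff (Bonferroni-adjusted over a species'
        triplet count before comparison).
    bootstrap_reps
        Column resamples for tree branch support.
    window, step
        BootScan sliding-window size and stride, in alignment columns.
    n_perm
        Permutation replicates for the label-permutation nulls (MaxChi,
        Chimaera, 3Seq-walk, GENECONV-like).
    bootscan_reps, bootscan_n_perm, support_threshold
        Per-window bootstrap replicates, column-order permutations and the
        percent support required on both flanks for the BootScan signal.
    """

    type_threshold: float = 0.015
    identity_mode: str = "k2p_distance"
    linkage: str = "single"
    consensus_min_methods: int = 3
    alpha: float = 0.05
    bootstrap_reps: int = 1000
    window: int = 200
    step: int = 20
    n_perm: int = 1000
    bootscan_reps: int = 1000
    bootscan_n_perm: int = 100
    support_threshold: float = 70.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.type_threshold < 1:
            raise ValueError("type_threshold must be in (0, 1)")
        if self.identity_mode not in ("k2p_distance", "p_identity"):
            raise ValueError(f"unknown identity_mode {self.identity_mode!r}")
        if self.linkage not in ("single", "complete"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if not 1 <= self.consensus_min_methods <= 5:
            raise ValueError("consensus_min_methods must be in 1..5")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> AlignedSet:
    """Read an aligned multi-FASTA into an :class:`AlignedSet`.

    Record ids are the first whitespace-delimited token of each header.
    Case-insensitive nucleotides; ``U`` is rejected (DNA marker data).
    Unequal lengths raise :class:`AlignmentError` naming the offending ids.
    """
    records = []
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=bio_rec.id, seq=str(bio_rec.seq)))
    if not records:
        raise ParseError(f"no records in {path}")
    length = len(records[0].seq)
    return AlignedSet(records, length)


def write_fasta(aln: AlignedSet, path, line_width: int = 70) -> None:
    """Write the alignment back to FASTA (ids only, no descriptions)."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in aln
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ["id", "species", "family", "strain_st", "wsp_allele", "supergroup"]


def read_metadata(path, aln: AlignedSet) -> AlignedSet:
    """Join a host-metadata TSV onto the alignment by sequence id.

    The TSV must carry the header columns id, species, family, strain_st,
    wsp_allele, supergroup.  A ``-``/``–`` or empty strain cell means "no
    data obtained" and is recorded as ``UNKNOWN``.  Metadata ids absent from
    the alignment only warn; alignment ids absent from the metadata are an
    error — every typed sequence needs a host.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing_cols = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"metadata missing columns: {missing_cols}")
    meta = {}
    for row in df.itertuples(index=False):
        meta[row.id] = row
    aln_ids = {r.id for r in aln.records}
    extra = sorted(set(meta) - aln_ids)
    if extra:
        warnings.warn(
            f"metadata rows with no matching sequence: {extra}", stacklevel=2
        )
    absent = sorted(aln_ids - set(meta))
    if absent:
        raise MetadataError(
            f"alignment ids missing from metadata: {absent}"
        )

    def _norm(cell: str) -> str:
        cell = cell.strip()
        return UNKNOWN if cell in ("", "-", "–") else cell

    out = []
    for r in aln.records:
        m = meta[r.id]
        out.append(
            replace(
                r,
                species=_norm(m.species),
                family=_norm(m.family),
                strain_st=_norm(m.strain_st),
                wsp_allele=_norm(m.wsp_allele),
                supergroup=_norm(m.supergroup),
            )
        )
    return AlignedSet(out, aln.length)


def write_metadata(aln: AlignedSet, path) -> None:
    """Emit the host-metadata TSV for an annotated alignment."""
    rows = [
        {
            "id": r.id,
            "species": r.species,
            "family": r.family,
            "strain_st": "" if r.strain_st == UNKNOWN else r.strain_st,
            "wsp_allele": r.wsp_allele,
            "supergroup": r.supergroup,
        }
        for r in aln
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)
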