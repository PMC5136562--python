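"""Aligned-FASTA input/output, marker concatenation and alignment site statistics.

Every downstream analysis consumes an :class:`AlignedMarkerSet`: one marker's
multiple sequence alignment in which each record carries a sample identifier
and a species label. Headers follow the voucher-style convention
``>Species_name<delimiter>sample_id`` (default delimiter ``|``); underscores
inside species names are preserved, so the species label is everything before
the *last* delimiter occurrence.

Column coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, InputError, InsufficientDataError, LabelingError

# Storage alphabet: unambiguous bases, IUPAC ambiguity codes, gap and missing.
UNAMBIGUOUS = frozenset("ACGT")
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")
GAP_OR_MISSING = frozenset("-?")
ALPHABET = UNAMBIGUOUS | IUPAC_AMBIGUOUS | GAP_OR_MISSING


@dataclass(frozen=True)
class SampleRecord:
    """One aligned sequence with its sample identity and species label."""

    sample_id: str
    species: str
    sequence: str


@dataclass(frozen=True)
class AlignedMarkerSet:
    """A species-labeled alignment for one marker (or one concatenation).

    ``boundaries`` records, for concatenated supermatrices, the half-open
    column span contributed by each input marker.
    """

    marker_name: str
    records: tuple[SampleRecord, ...]
    boundaries: tuple[tuple[str, int, int], ...] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError(f"marker set {self.marker_name!r} has no records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"marker set {self.marker_name!r}: unequal sequence lengths {sorted(lengths)}"
            )
        if len(self.records[0].sequence) < 1:
            raise AlignmentError(f"marker set {self.marker_name!r}: zero-length alignment")
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LabelingError(f"duplicate sample ids in {self.marker_name!r}: {dup}")
        bad = {c for r in self.records for c in r.sequence} - ALPHABET
        if bad:
            raise AlignmentError(
                f"marker set {self.marker_name!r}: non-IUPAC characters {sorted(bad)}"
            )

    @property
    def aligned_length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(r.sample_id for r in self.records)

    @property
    def species_of(self) -> dict[str, str]:
        return {r.sample_id: r.species for r in self.records}

    def record(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)


@dataclass(frozen=True)
class SiteSummary:
    """Counts and proportions of variable / parsimony-informative columns."""

    n_sites: int
    n_variable: int
    n_parsimony_informative: int

    @property
    def prop_variable(self) -> float:
        return self.n_variable / self.n_sites

    @property
    def prop_parsimony(self) -> float:
        return self.n_parsimony_informative / self.n_sites


def parse_header(header: str, delimiter: str = "|") -> tuple[str, str]:
    """Split a FASTA header into (species, sample_id) at the last delimiter."""
    if delimiter not in header:
        raise LabelingError(f"header {header!r} lacks delimiter {delimiter!r}")
    species, _, sample_id = header.rpartition(delimiter)
    species, sample_id = species.strip(), sample_id.strip()
    if not species or not sample_id:
        raise LabelingError(f"header {header!r} has empty species or sample id")
    return species, sample_id


def read_aligned_fasta(
    path: str | Path, delimiter: str = "|", marker_name: str | None = None
) -> AlignedMarkerSet:
    """Read an aligned FASTA whose headers carry species and sample labels.

    Sequences are uppercased and validated against the IUPAC DNA alphabet
    (plus ``-`` gap and ``?`` missing). Record order follows file order.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species, sample_id = parse_header(rec.description, delimiter)
        records.append(SampleRecord(sample_id, species, str(rec.seq).upper()))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return AlignedMarkerSet(marker_name or path.stem, tuple(records))


def write_aligned_fasta(
    ms: AlignedMarkerSet, path: str | Path, delimiter: str = "|", wrap: int = 70
) -> None:
    """Write the alignment back out; inverse of :func:`read_aligned_fasta`."""
    with open(path, "w") as fh:
        for r in ms.records:
            fh.write(f">{r.species}{delimiter}{r.sample_id}\n")
            if wrap and wrap > 0:
                for i in range(0, len(r.sequence), wrap):
                    fh.write(r.sequence[i : i + wrap] + "\n")
            else:
                fh.write(r.sequence + "\n")


def concatenate(
    marker_sets: Sequence[AlignedMarkerSet],
    policy: str = "complete_case",
    name: str | None = None,
) -> AlignedMarkerSet:
    """Concatenate markers into a multi-locus supermatrix.

    ``complete_case`` keeps only samples present in every marker set;
    ``pad_missing`` keeps the union, filling absent markers with ``?`` runs.
    Marker boundaries are recorded on the result for audit.
    """
    if len(marker_sets) < 2:
        raise InputError("concatenate needs at least 2 marker sets")
    if policy not in ("complete_case", "pad_missing"):
        raise InputError(f"unknown concatenation policy {policy!r}")

    species_of: dict[str, str] = {}
    for ms in marker_sets:
        for r in ms.records:
            prev = species_of.setdefault(r.sample_id, r.species)
            if prev != r.species:
                raise LabelingError(
                    f"sample {r.sample_id!r} labeled {prev!r} and {r.species!r} "
                    "in different marker sets"
                )

    id_sets = [set(ms.sample_ids) for ms in marker_sets]
    if policy == "complete_case":
        keep = set.intersection(*id_sets)
        if not keep:
            raise InputError("complete_case concatenation: no shared sample ids")
    else:
        keep = set.union(*id_sets)

    # Stable output order: first-appearance order across inputs.
    order = []
    for ms in marker_sets:
        for sid in ms.sample_ids:
            if sid in keep and sid not in order:
                order.append(sid)

    boundaries = []
    start = 0
    for ms in marker_sets:
        boundaries.append((ms.marker_name, start, start + ms.aligned_length))
        start += ms.aligned_length

    pieces = {sid: [] for sid in order}
    for ms in marker_sets:
        by_id = {r.sample_id: r.sequence for r in ms.records}
        filler = "?" * ms.aligned_length
        for sid in order:
            pieces[sid].append(by_id.get(sid, filler))

    records = tuple(
        SampleRecord(sid, species_of[sid], "".join(pieces[sid])) for sid in order
    )
    combined_name = name or "+".join(ms.marker_name for ms in marker_sets)
    return AlignedMarkerSet(combined_name, records, tuple(boundaries))


def write_boundary_table(ms: AlignedMarkerSet, path: str | Path) -> None:
    """Dump the marker-boundary audit (marker, start, end) as TSV."""
    with open(path, "w") as fh:
        fh.write("marker\tstart\tend\n")
        for marker, start, end in ms.boundaries or ((ms.marker_name, 0, ms.aligned_length),):
            fh.write(f"{marker}\t{start}\t{end}\n")


def site_summary(ms: AlignedMarkerSet) -> SiteSummary:
    """Count variable and parsimony-informative columns.

    Only unambiguous nucleotides (A, C, G, T) define column states; gaps,
    ``?`` and IUPAC ambiguity codes are ignored. A column is variable with
    >= 2 distinct states, and parsimony-informative with >= 2 states each
    carried by >= 2 records.
    """
    if len(ms.records) < 2:
        raise InsufficientDataError("site_summary needs at least 2 records")
    arr = np.frombuffer(
        "".join(r.sequence for r in ms.records).encode(), dtype="S1"
    ).reshape(len(ms.records), ms.aligned_length)
    n_var = 0
    n_pi = 0
    for j in range(ms.aligned_length):
        col = arr[:, j]
        counts = [int((col == b).sum()) for b in (b"A", b"C", b"G", b"T")]
        states = [c for c in counts if c > 0]
        if len(states) >= 2:
            n_var += 1
            if sum(1 for c in states if c >= 2) >= 2:
                n_pi += 1
    return SiteSummary(ms.aligned_length, n_var, n_pi)


def slice_subregion(ms: AlignedMarkerSet, start: int, end: int, name: str | None = None) -> AlignedMarkerSet:
    """Cut an alignment column range [start, end) — e.g. ITS2 out of full ITS.

    Coordinates are 0-based half-open and must be supplied explicitly; no
    annotation heuristic is applied.
    """
    if not (0 <= start < end <= ms.aligned_length):
        raise InputError(
            f"slice [{start}, {end}) out of range for alignment of length {ms.aligned_length}"
        )
    records = tuple(
        SampleRecord(r.sample_id, r.species, r.sequence[start:end]) for r in ms.records
    )
    return AlignedMarkerSet(name or f"{ms.marker_name}[{start}:{end}]", records)
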