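"""Reading, writing and quality control of barcode data sets.

A *barcode data set* joins an aligned FASTA file of COI sequences with a
tab-separated specimen-metadata table (id, species/genus/family labels,
coordinates, locality).  Records that lack a species label are retained —
they appear in trees and as library sequences where allowed — but are
excluded from species-level statistics downstream.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SpecimenRecord",
    "BarcodeDataset",
    "read_fasta_with_metadata",
    "write_dataset",
    "qc_filter",
    "check_reading_frame",
    "METADATA_COLUMNS",
]

#: canonical metadata column names; a column mapping may rename them on read
METADATA_COLUMNS = (
    "specimen_id",
    "species_label",
    "genus",
    "family",
    "latitude",
    "longitude",
    "locality_tag",
)

GAP_CHARS = frozenset("-.")
UNAMBIGUOUS = frozenset("ACGT")
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN") | GAP_CHARS


@dataclass(frozen=True)
class SpecimenRecord:
    """One sequenced voucher specimen.

    ``species_label`` may be a morphospecies placeholder ("Calycopis sp. 2")
    or empty for specimens that could not be identified to species.
    """

    specimen_id: str
    species_label: str
    genus: str
    family: str
    sequence: str
    latitude: float | None = None
    longitude: float | None = None
    locality_tag: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - IUPAC_CHARS
        if bad:
            raise ValueError(
                f"{self.specimen_id}: non-IUPAC symbols in sequence: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.specimen_id}: latitude {self.latitude} out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.specimen_id}: longitude {self.longitude} out of range")

    @property
    def is_identified(self) -> bool:
        return bool(self.species_label.strip())

    def ambiguous_fraction(self) -> float:
        """Fraction of non-gap positions that are not A/C/G/T."""
        seq = self.sequence
        nongap = [c for c in seq if c not in GAP_CHARS]
        if not nongap:
            return 0.0
        n_amb = sum(c not in UNAMBIGUOUS for c in nongap)
        return n_amb / len(nongap)

    def unambiguous_length(self) -> int:
        """Number of A/C/G/T positions (non-gap, non-ambiguous)."""
        return sum(c in UNAMBIGUOUS for c in self.sequence)


@dataclass
class BarcodeDataset:
    """An aligned collection of specimen records with consistent taxonomy."""

    records: list[SpecimenRecord]
    provenance: str = ""
    whitelist: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        self._check_taxonomy()

    def _check_taxonomy(self) -> None:
        species_genus: dict[str, str] = {}
        genus_family: dict[str, str] = {}
        for r in self.records:
            if r.is_identified:
                prev = species_genus.setdefault(r.species_label, r.genus)
                if prev != r.genus:
                    raise ValueError(
                        f"species {r.species_label!r} mapped to genera {prev!r} and {r.genus!r}"
                    )
            if r.genus:
                prev = genus_family.setdefault(r.genus, r.family)
                if prev != r.family:
                    raise ValueError(
                        f"genus {r.genus!r} mapped to families {prev!r} and {r.family!r}"
                    )

    # -- container conveniences -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    @property
    def ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence) if self.records else 0

    def species_map(self) -> dict[str, str]:
        """specimen_id -> species label ('' for unidentified)."""
        return {r.specimen_id: r.species_label for r in self.records}

    def genus_map(self) -> dict[str, str]:
        return {r.specimen_id: r.genus for r in self.records}

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def subset(self, ids: Iterable[str]) -> "BarcodeDataset":
        keep = set(ids)
        return BarcodeDataset(
            records=[r for r in self.records if r.specimen_id in keep],
            provenance=self.provenance,
            whitelist=self.whitelist,
        )

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "specimen_id": r.specimen_id,
                "species_label": r.species_label,
                "genus": r.genus,
                "family": r.family,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "locality_tag": r.locality_tag,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


def _coerce_coord(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_fasta_with_metadata(
    fasta_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    column_mapping: Mapping[str, str] | None = None,
    provenance: str = "",
) -> BarcodeDataset:
    """Join an aligned FASTA with a TSV metadata table on specimen id.

    ``column_mapping`` maps canonical column names to the names used in the
    file (so BOLD-style exports can be ingested without editing them).
    Every FASTA id must have a metadata row; a missing row is a hard error
    naming the offending ids.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(os.fspath(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {fasta_path}")

    table = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    mapping = dict(column_mapping or {})
    rename = {mapping.get(c, c): c for c in METADATA_COLUMNS if mapping.get(c, c) in table.columns}
    table = table.rename(columns=rename)
    missing_cols = [c for c in ("specimen_id", "species_label", "genus", "family") if c not in table.columns]
    if missing_cols:
        raise ValueError(f"metadata table missing required columns: {missing_cols}")
    for optional in ("latitude", "longitude", "locality_tag"):
        if optional not in table.columns:
            table[optional] = ""

    meta = table.set_index("specimen_id", verify_integrity=True)
    unmatched = sorted(set(seqs) - set(meta.index))
    if unmatched:
        raise ValueError(f"FASTA ids with no metadata row: {unmatched}")

    records = []
    for sid, seq in seqs.items():
        row = meta.loc[sid]
        records.append(
            SpecimenRecord(
                specimen_id=sid,
                species_label=str(row["species_label"]).strip(),
                genus=str(row["genus"]).strip(),
                family=str(row["family"]).strip(),
                sequence=seq,
                latitude=_coerce_coord(row["latitude"]),
                longitude=_coerce_coord(row["longitude"]),
                locality_tag=str(row["locality_tag"]).strip(),
            )
        )
    return BarcodeDataset(records=records, provenance=provenance or str(fasta_path))


def write_dataset(ds: BarcodeDataset, fasta_path: str | os.PathLike, metadata_path: str | os.PathLike) -> None:
    """Write the FASTA + TSV pair that :func:`read_fasta_with_metadata` reads."""
    recs = [SeqRecord(Seq(r.sequence), id=r.specimen_id, description="") for r in ds.records]
    with open(fasta_path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    ds.metadata_frame().to_csv(metadata_path, sep="\t", index=False, na_rep="")


def qc_filter(
    ds: BarcodeDataset,
    min_length: int = 500,
    max_ambiguous_frac: float = 0.01,
    whitelist: Iterable[str] = (),
) -> tuple[BarcodeDataset, pd.DataFrame]:
    """Apply the standard barcode quality filter.

    Retains records with at least ``min_length`` unambiguous (A/C/G/T)
    positions and an ambiguous-call fraction below ``max_ambiguous_frac``.
    Whitelisted ids are retained regardless (the deposited-data convention for
    a species whose only record narrowly fails the filter).  Returns the
    filtered data set and a rejection report (one row per rejected record).
    """
    wl = frozenset(whitelist) | ds.whitelist
    kept: list[SpecimenRecord] = []
    rejected: list[dict] = []
    for r in ds.records:
        reasons = []
        if r.unambiguous_length() < min_length:
            reasons.append("length")
        if r.ambiguous_fraction() >= max_ambiguous_frac:
            reasons.append("ambiguity")
        if reasons and r.specimen_id not in wl:
            rejected.append(
                {
                    "specimen_id": r.specimen_id,
                    "reason": "+".join(reasons),
                    "unambiguous_length": r.unambiguous_length(),
                    "ambiguous_fraction": r.ambiguous_fraction(),
                }
            )
        else:
            kept.append(r)
    report = pd.DataFrame(
        rejected, columns=["specimen_id", "reason", "unambiguous_length", "ambiguous_fraction"]
    )
    out = BarcodeDataset(records=kept, provenance=ds.provenance, whitelist=wl)
    return out, report


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """(start, length) of each internal run of gap characters."""
    runs = []
    i = 0
    n = len(seq)
    # leading/trailing gaps are read-length artifacts, not indels
    lead = 0
    while lead < n and seq[lead] in GAP_CHARS:
        lead += 1
    trail = n
    while trail > lead and seq[trail - 1] in GAP_CHARS:
        trail -= 1
    i = lead
    while i < trail:
        if seq[i] in GAP_CHARS:
            j = i
            while j < trail and seq[j] in GAP_CHARS:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def check_reading_frame(
    ds: BarcodeDataset,
    frame_offset: int = 1,
    genetic_code: int = 5,
) -> pd.DataFrame:
    """Translate each sequence and report stop codons and frame-shifting indels.

    ``genetic_code`` is an NCBI translation table id (5 = invertebrate
    mitochondrial, the appropriate code for insect COI).  ``frame_offset``
    in {0, 1, 2} gives the position of the first complete codon.  A gap run
    whose length is a multiple of three (a codon-sized deletion) is reported
    but not flagged as frame-shifting.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    try:
        table = CodonTable.unambiguous_dna_by_id[genetic_code]
    except KeyError as exc:
        raise ValueError(f"unknown genetic code id: {genetic_code}") from exc
    stop_codons = set(table.stop_codons)

    rows = []
    for r in ds.records:
        runs = _gap_runs(r.sequence)
        frameshifts = [(s, l) for s, l in runs if l % 3 != 0]
        inframe_deletions = [(s, l) for s, l in runs if l % 3 == 0]
        ungapped = "".join(c for c in r.sequence if c not in GAP_CHARS)
        coding = ungapped[frame_offset:]
        stops = []
        for i in range(0, len(coding) - 2, 3):
            codon = coding[i : i + 3]
            if codon in stop_codons:
                stops.append(i + frame_offset)
        # a stop in the final codon is the natural end, not an error
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "stop_codon_positions": stops,
                "frameshift_gap_runs": frameshifts,
                "inframe_gap_runs": inframe_deletions,
                "flagged": bool(stops) or bool(frameshifts),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "specimen_id",
            "stop_codon_positions",
            "frameshift_gap_runs",
            "inframe_gap_runs",
            "flagged",
        ],
    )
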