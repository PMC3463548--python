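"""Reading, validating and writing labeled barcode alignments.

A barcode library is an aligned FASTA file (one marker per file) plus a
sample-metadata table (TSV with columns ``seq_id``, ``species``, ``genus``,
``tribe``, ``marker``) mapping every sequence to its taxon.  All downstream
computation runs on the :class:`BarcodeAlignment` built here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlignmentError",
    "MetadataError",
    "BarcodeRecord",
    "BarcodeAlignment",
    "read_alignment",
    "write_alignment",
    "species_partition",
]

#: unambiguous DNA states
UNAMBIGUOUS = "ACGT"
#: residues accepted in input alignments: DNA + IUPAC ambiguity + gap
ALLOWED_RESIDUES = frozenset("ACGTRYSWKMBDHVN-")

#: marker -> alignment lengths seen in practice for the mitochondrial
#: barcodes this toolbox targets (two COI conventions are in circulation)
EXPECTED_MARKER_LENGTHS = {"COI": (657, 658), "COII": (671,), "Cytb": (730,)}

METADATA_COLUMNS = ("seq_id", "species", "genus", "tribe", "marker")


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment (unequal lengths, bad residues)."""


class MetadataError(ValueError):
    """Metadata table does not match the FASTA records."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One aligned barcode sequence with its taxonomic labels."""

    seq_id: str
    species: str
    genus: str
    tribe: str
    marker: str
    residues: str

    def __post_init__(self) -> None:
        res = self.residues.upper()
        if "U" in res:
            raise AlignmentError(
                f"record {self.seq_id!r} contains 'U'; only DNA is accepted"
            )
        bad = set(res) - ALLOWED_RESIDUES
        if bad:
            raise AlignmentError(
                f"record {self.seq_id!r} contains invalid residues {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)


@dataclass
class BarcodeAlignment:
    """An aligned set of labeled barcode sequences for a single marker.

    Invariants: all records share one alignment length; ``seq_id`` values are
    unique.  Alignment length is validated against the marker's conventional
    length with a warning only -- trimmed or extended alignments are legal.
    """

    marker: str
    records: list[BarcodeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise AlignmentError(
                f"records have unequal lengths {sorted(lengths)}; input must be aligned"
            )
        ids = [r.seq_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise AlignmentError(f"duplicate seq_ids: {sorted(dupes)}")
        expected = EXPECTED_MARKER_LENGTHS.get(self.marker)
        if self.records and expected and self.length not in expected:
            warnings.warn(
                f"{self.marker} alignment length {self.length} differs from the "
                f"conventional {'/'.join(map(str, expected))} bp",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0].residues) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def record(self, seq_id: str) -> BarcodeRecord:
        for r in self.records:
            if r.seq_id == seq_id:
                return r
        raise KeyError(seq_id)

    def species_labels(self) -> dict[str, str]:
        """seq_id -> species map."""
        return {r.seq_id: r.species for r in self.records}

    def genus_labels(self) -> dict[str, str]:
        return {r.seq_id: r.genus for r in self.records}

    def tribe_labels(self) -> dict[str, str]:
        return {r.seq_id: r.tribe for r in self.records}

    def to_array(self) -> np.ndarray:
        """Alignment as an (n_records, length) byte matrix of residue codes.

        A, C, G, T -> 0..3; every other state (gaps, N, IUPAC ambiguity)
        -> 255, i.e. "not comparable".  Purines are codes {0, 2} and
        pyrimidines {1, 3} so a transition is a change within a parity class.
        """
        return encode_residues([r.residues for r in self.records])

    def subset(self, seq_ids: list[str]) -> "BarcodeAlignment":
        """New alignment restricted to ``seq_ids`` (order preserved)."""
        wanted = set(seq_ids)
        return BarcodeAlignment(
            marker=self.marker, records=[r for r in self.records if r.seq_id in wanted]
        )

    def drop_columns(self, positions_1based: list[int]) -> "BarcodeAlignment":
        """New alignment with the given 1-based columns removed."""
        L = self.length
        drop = set(positions_1based)
        out_of_range = [p for p in drop if not 1 <= p <= L]
        if out_of_range:
            raise AlignmentError(
                f"column positions out of range 1..{L}: {sorted(out_of_range)}"
            )
        keep = [i for i in range(L) if (i + 1) not in drop]
        recs = [
            BarcodeRecord(
                seq_id=r.seq_id,
                species=r.species,
                genus=r.genus,
                tribe=r.tribe,
                marker=r.marker,
                residues="".join(r.residues[i] for i in keep),
            )
            for r in self.records
        ]
        return BarcodeAlignment(marker=self.marker, records=recs)


# residue -> code lookup table used by to_array
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode_residues(seqs: list[str]) -> np.ndarray:
    """Encode equal-length residue strings as a byte code matrix (see to_array)."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[raw.reshape(len(seqs), len(seqs[0]))]


def read_alignment(fasta_path, metadata_path, marker: str) -> BarcodeAlignment:
    """Read an aligned FASTA plus its metadata table into a BarcodeAlignment.

    Every FASTA record must have exactly one metadata row (matched on
    ``seq_id``); FASTA order is preserved.  Lowercase residues are upcased.

    Raises
    ------
    AlignmentError
        Unequal sequence lengths or invalid residues.
    MetadataError
        Missing/duplicated ids or malformed metadata.
    """
    fasta_path, metadata_path = Path(fasta_path), Path(metadata_path)
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    meta = pd.read_csv(
        metadata_path,
        sep="," if metadata_path.suffix.lower() == ".csv" else "\t",
        dtype=str,
        keep_default_na=False,
    )
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise MetadataError(f"metadata lacks columns {sorted(missing_cols)}")
    meta = meta.map(lambda s: s.strip())
    if meta["seq_id"].duplicated().any():
        dup = meta.loc[meta["seq_id"].duplicated(), "seq_id"].tolist()
        raise MetadataError(f"duplicate seq_ids in metadata: {dup}")
    by_id = meta.set_index("seq_id")

    records = []
    for s in seqs:
        if s.id not in by_id.index:
            raise MetadataError(f"FASTA id {s.id!r} missing from metadata")
        row = by_id.loc[s.id]
        records.append(
            BarcodeRecord(
                seq_id=s.id,
                species=row["species"],
                genus=row["genus"],
                tribe=row["tribe"],
                marker=row["marker"] or marker,
                residues=str(s.seq),
            )
        )
    return BarcodeAlignment(marker=marker, records=records)


def write_alignment(aln: BarcodeAlignment, fasta_path, metadata_path) -> None:
    """Write FASTA + metadata TSV in the dialect read_alignment consumes."""
    recs = [
        SeqRecord(Seq(r.residues), id=r.seq_id, description="") for r in aln.records
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    pd.DataFrame(
        [
            {
                "seq_id": r.seq_id,
                "species": r.species,
                "genus": r.genus,
                "tribe": r.tribe,
                "marker": r.marker,
            }
            for r in aln.records
        ]
    ).to_csv(metadata_path, sep="\t", index=False)


def species_partition(aln: BarcodeAlignment) -> dict[str, list[str]]:
    """Partition seq_ids by species; bins keyed in lexicographic order."""
    bins: dict[str, list[str]] = {}
    for r in aln.records:
        bins.setdefault(r.species, []).append(r.seq_id)
    return {sp: bins[sp] for sp in sorted(bins)}
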