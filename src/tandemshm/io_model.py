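"""Domain types and readers/writers for the tandem substitution pipeline.

Coordinates are 0-based, half-open, and live in UNGAPPED germline space.
IMGT-style ``.`` gap columns carry no position number; every type that
stores a position refers to the ungapped germline sequence of its allele.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
GAP_CHARS = ".-"
#: sentinel recorded as a flank when an event touches the first/last position
BOUNDARY_SENTINEL = "-"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TandemShmError(Exception):
    """Base class for all package errors."""


class ParseError(TandemShmError):
    """A file could not be parsed."""


class SchemaError(TandemShmError):
    """A tabular input is missing required columns."""


class ValidationError(TandemShmError):
    """An input violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GermlineAllele:
    """A reference V nucleotide sequence with frame and region annotation.

    Parameters
    ----------
    name
        Allele identifier, e.g. ``"IGHV3-23*01"``.
    sequence
        Nucleotide string over ``{A,C,G,T}`` plus the gap character ``.``.
    frame_offset
        Index (0..2) of the first base of codon 1 in ungapped coordinates.
    regions
        Ordered ``(label, (start, end))`` pairs over half-open codon-position
        intervals, labels in ``{FR1, CDR1, FR2, CDR2, FR3}``.
    """

    name: str
    sequence: str
    frame_offset: int = 0
    regions: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValidationError(f"allele {self.name!r}: empty sequence")
        bad = set(self.sequence) - set(NUCLEOTIDES + ".")
        if bad:
            raise ValidationError(
                f"allele {self.name!r}: invalid characters {sorted(bad)}"
            )
        if not 0 <= self.frame_offset <= 2:
            raise ValidationError(
                f"allele {self.name!r}: frame_offset {self.frame_offset} not in 0..2"
            )
        if len(self.ungapped) < 3:
            raise ValidationError(f"allele {self.name!r}: ungapped length < 3")
        prev_end = None
        for label, (start, end) in self.regions:
            if start >= end:
                raise ValidationError(
                    f"allele {self.name!r}: empty region interval {label}"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"allele {self.name!r}: overlapping/unordered region {label}"
                )
            prev_end = end

    @property
    def ungapped(self) -> str:
        return self.sequence.replace(".", "")

    @property
    def ungapped_length(self) -> int:
        return len(self.ungapped)

    def gapped_to_ungapped(self) -> np.ndarray:
        """Per gapped column: ungapped position, or -1 for gap columns."""
        out = np.full(len(self.sequence), -1, dtype=int)
        pos = 0
        for i, c in enumerate(self.sequence):
            if c != ".":
                out[i] = pos
                pos += 1
        return out

    def ungapped_to_gapped(self) -> np.ndarray:
        return np.flatnonzero(np.frombuffer(self.sequence.encode(), dtype="S1") != b".")

    def region_of_codon(self, codon_position: int) -> str | None:
        for label, (start, end) in self.regions:
            if start <= codon_position < end:
                return label
        return None


@dataclass
class RepertoireRecord:
    """One annotated, germline-aligned rearrangement.

    ``v_alignment`` is the observed gapped nucleotide string in the same
    coordinate frame as the matched :class:`GermlineAllele`.
    ``mutation_count`` is derived by the caller (number of mutated
    ungapped positions) and is ``None`` until computed.
    """

    sequence_id: str
    v_call: str
    v_alignment: str
    cdr3_nt: str = ""
    d_call: str = ""
    j_call: str = ""
    isotype: str = ""
    mutation_count: int | None = None
    germline_alignment: str | None = None

    def __post_init__(self) -> None:
        if self.germline_alignment is not None and len(self.germline_alignment) != len(
            self.v_alignment
        ):
            raise ValidationError(
                f"record {self.sequence_id!r}: alignment length mismatch "
                f"({len(self.v_alignment)} vs {len(self.germline_alignment)})"
            )


@dataclass
class SubstitutionEvent:
    """A maximal run of ``k >= 1`` adjacent mutated positions.

    ``start`` is the 0-based ungapped germline position of the 5'-most
    mutated base.  ``flank5``/``flank3`` hold one germline base each, the
    boundary sentinel ``-`` at sequence ends, or ``N`` next to an ambiguous
    observed base.
    """

    allele_name: str
    start: int
    germline_bases: str
    observed_bases: str
    flank5: str = BOUNDARY_SENTINEL
    flank3: str = BOUNDARY_SENTINEL
    sequence_id: str = ""

    def __post_init__(self) -> None:
        if len(self.germline_bases) != len(self.observed_bases):
            raise ValidationError(
                f"event at {self.start}: germline/observed length mismatch"
            )
        if not self.germline_bases:
            raise ValidationError(f"event at {self.start}: empty run")
        if self.start < 0:
            raise ValidationError(f"event start {self.start} < 0")
        for g, o in zip(self.germline_bases, self.observed_bases):
            if g == o:
                raise ValidationError(
                    f"event at {self.start}: position with identical "
                    f"germline/observed base {g!r}"
                )

    @property
    def k(self) -> int:
        return len(self.germline_bases)

    @property
    def end(self) -> int:
        """One past the 3'-most mutated position (half-open)."""
        return self.start + self.k


def legal_outcomes(ref: str) -> list[str]:
    """The 9 double-base outcomes of a reference dinucleotide, sorted.

    An outcome ``X'Y'`` is legal iff ``X' != X`` and ``Y' != Y``.
    """
    if len(ref) != 2 or any(c not in NUCLEOTIDES for c in ref):
        raise ValidationError(f"not a dinucleotide over ACGT: {ref!r}")
    return [
        a + b
        for a in sorted(set(NUCLEOTIDES) - {ref[0]})
        for b in sorted(set(NUCLEOTIDES) - {ref[1]})
    ]


ALL_DINUCLEOTIDES = [a + b for a in NUCLEOTIDES for b in NUCLEOTIDES]


class DinucSubstitutionTable:
    """Counts over the 144 legal (reference, outcome) dinucleotide pairs.

    Counts may become fractional after in-silico correction.
    """

    def __init__(self, counts: Mapping[tuple[str, str], float] | None = None):
        self.counts: dict[tuple[str, str], float] = {
            (ref, alt): 0.0 for ref in ALL_DINUCLEOTIDES for alt in legal_outcomes(ref)
        }
        if counts:
            for key, value in counts.items():
                self[key] = value

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.counts[key]

    def __setitem__(self, key: tuple[str, str], value: float) -> None:
        if key not in self.counts:
            raise ValidationError(f"illegal dinucleotide substitution cell {key}")
        self.counts[key] = float(value)

    def increment(self, ref: str, alt: str, by: float = 1.0) -> None:
        self[(ref, alt)] = self[(ref, alt)] + by

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DinucSubstitutionTable):
            return NotImplemented
        return all(
            np.isclose(self.counts[k], other.counts[k]) for k in self.counts
        )

    def reverse_complemented(self) -> "DinucSubstitutionTable":
        """The strandwise reverse-complemented table."""
        out = DinucSubstitutionTable()
        for (ref, alt), v in self.counts.items():
            out.increment(reverse_complement(ref), reverse_complement(alt), v)
        return out


#: COSMIC's 10 canonical reference doublets for the DBS-78 classification.
CANONICAL_DOUBLETS = ("AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT")

#: The 78 doublet-base-substitution classes, in catalog order.
DBS78_CLASSES = (
    "AC>CA", "AC>CG", "AC>CT", "AC>GA", "AC>GG", "AC>GT", "AC>TA", "AC>TG", "AC>TT",
    "AT>CA", "AT>CC", "AT>CG", "AT>GA", "AT>GC", "AT>TA",
    "CC>AA", "CC>AG", "CC>AT", "CC>GA", "CC>GG", "CC>GT", "CC>TA", "CC>TG", "CC>TT",
    "CG>AT", "CG>GC", "CG>GT", "CG>TA", "CG>TC", "CG>TT",
    "CT>AA", "CT>AC", "CT>AG", "CT>GA", "CT>GC", "CT>GG", "CT>TA", "CT>TC", "CT>TG",
    "GC>AA", "GC>AG", "GC>AT", "GC>CA", "GC>CG", "GC>TA",
    "TA>AT", "TA>CG", "TA>CT", "TA>GC", "TA>GG", "TA>GT",
    "TC>AA", "TC>AG", "TC>AT", "TC>CA", "TC>CG", "TC>CT", "TC>GA", "TC>GG", "TC>GT",
    "TG>AA", "TG>AC", "TG>AT", "TG>CA", "TG>CC", "TG>CT", "TG>GA", "TG>GC", "TG>GT",
    "TT>AA", "TT>AC", "TT>AG", "TT>CA", "TT>CC", "TT>CG", "TT>GA", "TT>GC", "TT>GG",
)

_DBS78_INDEX = {label: i for i, label in enumerate(DBS78_CLASSES)}


def dbs78_class(ref: str, alt: str) -> str:
    """Map a (reference, outcome) dinucleotide pair to its DBS-78 class.

    Non-canonical references are reverse-complemented together with their
    outcome; for palindromic references the outcome alone is collapsed.
    """
    for r, a in ((ref, alt), (reverse_complement(ref), reverse_complement(alt))):
        label = f"{r}>{a}"
        if label in _DBS78_INDEX:
            return label
    raise ValidationError(f"no DBS-78 class for {ref}>{alt}")


@dataclass
class DbsCatalog:
    """A vector over the 78 canonical doublet-base-substitution classes."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (78,):
            raise ValidationError(
                f"DBS catalog must have exactly 78 entries, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValidationError("DBS catalog entries must be non-negative")

    @classmethod
    def zeros(cls) -> "DbsCatalog":
        return cls(np.zeros(78))

    def __getitem__(self, label: str) -> float:
        return float(self.values[_DBS78_INDEX[label]])

    def increment(self, label: str, by: float = 1.0) -> None:
        self.values[_DBS78_INDEX[label]] += by

    @property
    def total(self) -> float:
        return float(self.values.sum())


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _load_allele_config(config_path: str | Path | None) -> dict:
    if config_path is None:
        return {}
    import tomllib

    with open(config_path, "rb") as fh:
        return tomllib.load(fh)


def read_germline_fasta(
    path: str | Path, config_path: str | Path | None = None
) -> list[GermlineAllele]:
    """Read germline V alleles from FASTA.

    Sequences are uppercased; ``.`` gap columns are preserved.  Frame offsets
    and region annotations come from an optional TOML companion config keyed
    by allele name (``frame_offset`` integer, ``regions`` list of
    ``[label, start, end]`` codon intervals); the default frame offset is 0.
    """
    path = Path(path)
    config = _load_allele_config(config_path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        first_bad = next(
            i for i, line in enumerate(text.splitlines(), 1) if line.strip()
        )
        raise ParseError(f"{path}: line {first_bad}: expected FASTA header '>'")
    alleles = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set(NUCLEOTIDES + ".")
        if bad:
            raise ValidationError(
                f"allele {rec.id!r}: non-ACGT. characters {sorted(bad)}"
            )
        entry = config.get(rec.id, {})
        regions = [
            (label, (int(start), int(end)))
            for label, start, end in entry.get("regions", [])
        ]
        alleles.append(
            GermlineAllele(
                name=rec.id,
                sequence=seq,
                frame_offset=int(entry.get("frame_offset", 0)),
                regions=regions,
            )
        )
    return alleles


def write_germline_fasta(alleles: Iterable[GermlineAllele], path: str | Path) -> None:
    with open(path, "w") as fh:
        for allele in alleles:
            fh.write(f">{allele.name}\n{allele.sequence}\n")


REARRANGEMENT_COLUMNS = (
    "sequence_id",
    "v_call",
    "d_call",
    "j_call",
    "sequence_alignment",
    "germline_alignment",
    "cdr3",
    "isotype",
)
_REQUIRED_COLUMNS = ("sequence_id", "v_call", "sequence_alignment", "germline_alignment", "cdr3")


def read_rearrangements(path: str | Path) -> list[RepertoireRecord]:
    """Read an AIRR-style rearrangement TSV.

    Rows with a missing ``v_call`` or ``sequence_alignment`` are dropped and
    counted in a log summary; a row whose observed and germline alignments
    differ in length raises :class:`ValidationError` naming the sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = []
    dropped = 0
    for row in df.itertuples(index=False):
        if not row.v_call.strip() or not row.sequence_alignment.strip():
            dropped += 1
            continue
        germ = row.germline_alignment
        if len(germ) != len(row.sequence_alignment):
            raise ValidationError(
                f"record {row.sequence_id!r}: alignment length mismatch "
                f"({len(row.sequence_alignment)} vs {len(germ)})"
            )
        records.append(
            RepertoireRecord(
                sequence_id=row.sequence_id,
                v_call=row.v_call,
                v_alignment=row.sequence_alignment.upper(),
                germline_alignment=germ.upper(),
                cdr3_nt=row.cdr3.upper(),
                d_call=getattr(row, "d_call", ""),
                j_call=getattr(row, "j_call", ""),
                isotype=getattr(row, "isotype", ""),
            )
        )
    if dropped:
        logger.info("read_rearrangements: dropped %d incomplete rows", dropped)
    return records


def write_rearrangements(records: Iterable[RepertoireRecord], path: str | Path) -> None:
    rows = [
        {
            "sequence_id": r.sequence_id,
            "v_call": r.v_call,
            "d_call": r.d_call,
            "j_call": r.j_call,
            "sequence_alignment": r.v_alignment,
            "germline_alignment": r.germline_alignment or "",
            "cdr3": r.cdr3_nt,
            "isotype": r.isotype,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REARRANGEMENT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def write_substitution_table(table: DinucSubstitutionTable, path: str | Path) -> None:
    """Write the 144-cell table as CSV: 16 reference rows x 9 outcome columns.

    Row labels are the 16 reference dinucleotides in alphabetical order.
    Column ``o1``..``o9`` of row ``XY`` holds the count for the j-th
    alphabetically sorted legal outcome of ``XY`` (see
    :func:`legal_outcomes`); the mapping is deterministic, so the format
    round-trips losslessly.
    """
    rows = {
        ref: [table[(ref, alt)] for alt in legal_outcomes(ref)]
        for ref in ALL_DINUCLEOTIDES
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"o{i}" for i in range(1, 10)]
    )
    df.index.name = "ref"
    df.to_csv(path)


def read_substitution_table(path: str | Path) -> DinucSubstitutionTable:
    df = pd.read_csv(path, index_col=0)
    table = DinucSubstitutionTable()
    for ref in ALL_DINUCLEOTIDES:
        for j, alt in enumerate(legal_outcomes(ref)):
            table[(ref, alt)] = float(df.loc[ref, f"o{j + 1}"])
    return table


def write_dbs_catalog(catalog: DbsCatalog, path: str | Path) -> None:
    pd.DataFrame({"class": DBS78_CLASSES, "value": catalog.values}).to_csv(
        path, index=False
    )


def read_dbs_catalog(path: str | Path) -> DbsCatalog:
    df = pd.read_csv(path)
    if "class" not in df.columns:
        raise SchemaError(f"{path}: missing 'class' column")
    value_cols = [c for c in df.columns if c != "class"]
    if not value_cols:
        raise SchemaError(f"{path}: no value column")
    series = df.set_index("class")[value_cols[0]]
    try:
        values = series.loc[list(DBS78_CLASSES)].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValidationError(f"{path}: missing DBS-78 classes: {exc}") from exc
    return DbsCatalog(values)


def read_dbs_catalogs(path: str | Path) -> dict[str, DbsCatalog]:
    """Read a multi-signature DBS-78 CSV (one column per signature)."""
    df = pd.read_csv(path)
    if "class" not in df.columns:
        raise SchemaError(f"{path}: missing 'class' column")
    df = df.set_index("class")
    out = {}
    for col in df.columns:
        out[col] = DbsCatalog(df[col].loc[list(DBS78_CLASSES)].to_numpy(dtype=float))
    return out


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, cls=_ReportEncoder)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_events(events: Sequence[SubstitutionEvent], path: str | Path) -> None:
    rows = [
        {
            "sequence_id": e.sequence_id,
            "allele": e.allele_name,
            "start": e.start,
            "k": e.k,
            "germline": e.germline_bases,
            "observed": e.observed_bases,
            "flank5": e.flank5,
            "flank3": e.flank3,
        }
        for e in events
    ]
    pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "allele", "start", "k",
            "germline", "observed", "flank5", "flank3",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[SubstitutionEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str}, keep_default_na=False)
    return [
        SubstitutionEvent(
            allele_name=row.allele,
            start=int(row.start),
            germline_bases=row.germline,
            observed_bases=row.observed,
            flank5=row.flank5,
            flank3=row.flank3,
            sequence_id=str(row.sequence_id),
        )
        for row in df.itertuples(index=False)
    ]
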