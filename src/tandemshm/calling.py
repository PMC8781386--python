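"""Substitution calling: maximal runs of adjacent mutated positions.

Runs are called on ungapped germline coordinates.  Germline ``.`` gap
columns never receive a position number, observed ``N`` (or gap) positions
are never counted as mutated and split runs, and indels are disregarded.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

from tandemshm.io_model import (
    BOUNDARY_SENTINEL,
    GermlineAllele,
    NUCLEOTIDES,
    RepertoireRecord,
    SubstitutionEvent,
    ValidationError,
)

_VALID_ALIGNMENT_CHARS = set(NUCLEOTIDES + "N.-")

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def call_substitutions(
    record: RepertoireRecord,
    allele: GermlineAllele,
    end: int | None = None,
) -> list[SubstitutionEvent]:
    """Call all maximal substitution runs of a record against its germline.

    Parameters
    ----------
    record
        Record whose ``v_alignment`` shares the allele's gapped coordinates.
    allele
        The matched germline allele.
    end
        Optional exclusive ungapped scan bound (e.g. the position after the
        second conserved cysteine codon); ``None`` scans the whole V region.

    Returns
    -------
    Events sorted by start position. Flanks are read from the germline,
    with the boundary sentinel at sequence ends and ``N`` next to an
    ambiguous observed base.
    """
    obs_gapped = record.v_alignment.upper()
    if len(obs_gapped) != len(allele.sequence):
        raise ValidationError(
            f"record {record.sequence_id!r}: alignment length "
            f"{len(obs_gapped)} != germline length {len(allele.sequence)} "
            f"for allele {allele.name!r}"
        )
    bad = set(obs_gapped) - _VALID_ALIGNMENT_CHARS
    if bad:
        raise ValidationError(
            f"record {record.sequence_id!r}: invalid alignment characters "
            f"{sorted(bad)}"
        )

    germ = allele.ungapped
    # observed base per ungapped germline position (gap columns dropped)
    obs = [o for o, g in zip(obs_gapped, allele.sequence) if g != "."]
    limit = len(germ) if end is None else min(end, len(germ))

    mutated = [
        obs[p] in NUCLEOTIDES and obs[p] != germ[p] for p in range(limit)
    ]

    events: list[SubstitutionEvent] = []
    p = 0
    while p < limit:
        if not mutated[p]:
            p += 1
            continue
        q = p
        while q + 1 < limit and mutated[q + 1]:
            q += 1
        flank5 = BOUNDARY_SENTINEL if p == 0 else ("N" if obs[p - 1] == "N" else germ[p - 1])
        if q == len(germ) - 1:
            flank3 = BOUNDARY_SENTINEL
        elif q + 1 < len(obs) and obs[q + 1] == "N":
            flank3 = "N"
        else:
            flank3 = germ[q + 1]
        events.append(
            SubstitutionEvent(
                allele_name=allele.name,
                start=p,
                germline_bases=germ[p : q + 1],
                observed_bases="".join(obs[p : q + 1]),
                flank5=flank5,
                flank3=flank3,
                sequence_id=record.sequence_id,
            )
        )
        p = q + 1
    return events


def count_mutated_positions(
    record: RepertoireRecord, allele: GermlineAllele, end: int | None = None
) -> int:
    """Total number of mutated ungapped positions (sum of run lengths)."""
    return sum(e.k for e in call_substitutions(record, allele, end=end))


def tabulate_run_lengths(events: Iterable[SubstitutionEvent]) -> dict[int, int]:
    """Count events per run length ``k``."""
    counts: dict[int, int] = {}
    for e in events:
        counts[e.k] = counts.get(e.k, 0) + 1
    return counts


def compute_ts_tv(events: Iterable[SubstitutionEvent]) -> float:
    """Transition/transversion ratio over single-nucleotide substitutions.

    Transitions are A<->G and C<->T.  Returns ``inf`` when there are
    transitions but no transversions, and ``nan`` when there are no
    single-nucleotide substitutions at all.
    """
    ts = tv = 0
    for e in events:
        if e.k != 1:
            continue
        if (e.germline_bases, e.observed_bases) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if ts + tv == 0:
        return math.nan
    if tv == 0:
        return math.inf
    return ts / tv
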