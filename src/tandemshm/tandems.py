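"""Tandem substitution classification, motif annotation, and DBS catalogs.

A tandem dinucleotide substitution replaces a reference dinucleotide ``XY``
by ``X'Y'`` with both bases changed.  The classifier distinguishes
inversions (``X'=Y`` and ``Y'=X``), juxtalocations of a single germline
base (the 5' base reappearing downstream, or the 3' base upstream), and
everything else.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy import stats

from tandemshm.io_model import (
    DbsCatalog,
    DinucSubstitutionTable,
    GermlineAllele,
    NUCLEOTIDES,
    SubstitutionEvent,
    ValidationError,
    dbs78_class,
    legal_outcomes,
)

logger = logging.getLogger(__name__)

INVERSION = "inversion"
JUXTALOCATION_5P = "juxtalocation_5p"
JUXTALOCATION_3P = "juxtalocation_3p"
OTHER = "other"

CATEGORIES = (INVERSION, JUXTALOCATION_5P, JUXTALOCATION_3P, OTHER)

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONSENSE = "nonsense"
DOUBLE_SYNONYMOUS = "double_synonymous"
DOUBLE_REPLACEMENT = "double_replacement"


def classify_outcome(ref: str, alt: str) -> str:
    """Classify a (reference, outcome) dinucleotide pair.

    Inversion takes precedence over the juxtalocation classes (it satisfies
    both single-base equalities).  For homodimer references the only
    possible category is ``other``.
    """
    if len(ref) != 2 or len(alt) != 2:
        raise ValidationError(f"not a dinucleotide pair: {ref!r} -> {alt!r}")
    if alt[0] == ref[0] or alt[1] == ref[1]:
        raise ValidationError(f"{ref}->{alt}: both bases must be substituted")
    five_prime_moved = alt[1] == ref[0]  # germline 5' base reappears at the 3' slot
    three_prime_moved = alt[0] == ref[1]  # germline 3' base reappears at the 5' slot
    if five_prime_moved and three_prime_moved:
        return INVERSION
    if five_prime_moved:
        return JUXTALOCATION_5P
    if three_prime_moved:
        return JUXTALOCATION_3P
    return OTHER


def classify_tdns(event: SubstitutionEvent) -> str:
    """Classify a tandem dinucleotide substitution event (k must be 2)."""
    if event.k != 2:
        raise ValidationError(f"classify_tdns requires k=2, got k={event.k}")
    return classify_outcome(event.germline_bases, event.observed_bases)


def expected_category_fractions() -> dict[str, float]:
    """Null category fractions for a heterodimer reference.

    Under a uniform distribution over the 9 legal outcomes: 1/9 inversion,
    4/9 pooled juxtalocation, 4/9 other.
    """
    return {
        INVERSION: 1 / 9,
        "juxtalocation": 4 / 9,
        OTHER: 4 / 9,
    }


def compare_fraction_to_expected(
    observed_count: int, total: int, expected_fraction: float
) -> tuple[float, float]:
    """One-sample two-sided z-test of a proportion against an expectation.

    This normal-approximation test stands in for the fraction comparison
    reported with the source analysis; returns ``(statistic, p_value)``.
    """
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 < expected_fraction < 1:
        raise ValidationError("expected_fraction must lie in (0,1)")
    p_hat = observed_count / total
    se = math.sqrt(expected_fraction * (1 - expected_fraction) / total)
    z = (p_hat - expected_fraction) / se
    p = 2 * stats.norm.sf(abs(z))
    return z, min(p, 1.0)


# ---------------------------------------------------------------------------
# Codon frame and amino-acid effects
# ---------------------------------------------------------------------------


def assign_codon_slot(event: SubstitutionEvent, allele: GermlineAllele) -> int:
    """Codon slot of a tandem event: 1 = bases (1,2), 2 = (2,3), 3 = base 3
    plus base 1 of the downstream codon."""
    if event.k != 2:
        raise ValidationError(f"assign_codon_slot requires k=2, got k={event.k}")
    rel = event.start - allele.frame_offset
    if rel < 0:
        raise ValidationError(
            f"event at {event.start} starts upstream of the reading frame"
        )
    return rel % 3 + 1


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass
class EffectCall:
    """Amino-acid effect of a substitution event within its codon frame."""

    codon_slot: int
    effect: str


def _codon_at(allele: GermlineAllele, codon_index: int) -> str | None:
    start = allele.frame_offset + 3 * codon_index
    codon = allele.ungapped[start : start + 3]
    if len(codon) < 3 or any(c not in NUCLEOTIDES for c in codon):
        return None
    return codon


def classify_effect(
    event: SubstitutionEvent, allele: GermlineAllele
) -> EffectCall | None:
    """Translate the codon(s) affected by an event before and after.

    Supports k=1 and k=2 events.  Returns ``None`` (with a logged reason)
    for events overlapping an incomplete trailing codon or lying upstream
    of the reading frame.
    """
    if event.k not in (1, 2):
        raise ValidationError(f"classify_effect supports k in (1,2), got {event.k}")
    rel = event.start - allele.frame_offset
    if rel < 0:
        logger.debug("event at %d upstream of frame; skipped", event.start)
        return None
    slot = rel % 3 + 1
    germ = allele.ungapped

    def mutated_codon(codon_index: int) -> tuple[str, str] | None:
        codon = _codon_at(allele, codon_index)
        if codon is None:
            return None
        codon_start = allele.frame_offset + 3 * codon_index
        chars = list(codon)
        for i in range(event.k):
            pos = event.start + i
            if codon_start <= pos < codon_start + 3:
                assert germ[pos] == codon[pos - codon_start]
                chars[pos - codon_start] = event.observed_bases[i]
        return codon, "".join(chars)

    codon_index = rel // 3
    spans_two = event.k == 2 and slot == 3
    indices = [codon_index, codon_index + 1] if spans_two else [codon_index]
    pairs = []
    for idx in indices:
        pair = mutated_codon(idx)
        if pair is None:
            logger.debug(
                "event at %d overlaps incomplete codon %d of %s; skipped",
                event.start, idx, allele.name,
            )
            return None
        pairs.append(pair)

    aa_pairs = [(_translate(before), _translate(after)) for before, after in pairs]
    if any(after == "*" for _, after in aa_pairs):
        return EffectCall(codon_slot=slot, effect=NONSENSE)
    if any(before == "*" for before, _ in aa_pairs):
        logger.debug("germline stop codon at event %d of %s", event.start, allele.name)
        return None
    if spans_two:
        syn = [before == after for before, after in aa_pairs]
        if all(syn):
            return EffectCall(codon_slot=slot, effect=DOUBLE_SYNONYMOUS)
        if not any(syn):
            return EffectCall(codon_slot=slot, effect=DOUBLE_REPLACEMENT)
        return EffectCall(codon_slot=slot, effect=NONSYNONYMOUS)
    before, after = aa_pairs[0]
    return EffectCall(
        codon_slot=slot, effect=SYNONYMOUS if before == after else NONSYNONYMOUS
    )


# ---------------------------------------------------------------------------
# Germline context containment
# ---------------------------------------------------------------------------

NOT_PRESENT = "not_present"
POS_MINUS1 = "pos_minus1"
POS_T2 = "pos_t2"
BOTH = "both"


def germline_context_containment(
    event: SubstitutionEvent, allele: GermlineAllele
) -> str:
    """Is the observed tandem already present in the +/-1 germline context?

    ``pos_minus1``: the window starting one base upstream of the event
    equals the observed dinucleotide; ``pos_t2``: the window starting at the
    event's second base equals it.  Windows extending past the sequence
    never match.
    """
    if event.k != 2:
        raise ValidationError("germline_context_containment requires k=2")
    germ = allele.ungapped
    obs = event.observed_bases

    def window(start: int) -> str | None:
        if start < 0 or start + 2 > len(germ):
            return None
        return germ[start : start + 2]

    minus1 = window(event.start - 1) == obs
    t2 = window(event.start + 1) == obs
    if minus1 and t2:
        return BOTH
    if minus1:
        return POS_MINUS1
    if t2:
        return POS_T2
    return NOT_PRESENT


# ---------------------------------------------------------------------------
# AID hotspot motifs
# ---------------------------------------------------------------------------

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "R": "AG", "Y": "CT",
}

#: (pattern searched on the coding strand, index of the hotspot base)
_MOTIF_PATTERNS = {
    ("WRCY", "forward"): ("WRCY", 2),
    ("WA", "forward"): ("WA", 1),
    ("RCG", "forward"): ("RCG", 1),
    # reverse-complement patterns represent template-strand motifs; the
    # hotspot index points at the base complementary to the C/A hotspot
    ("WRCY", "reverse_complement"): ("RGYW", 1),
    ("WA", "reverse_complement"): ("TW", 0),
    ("RCG", "reverse_complement"): ("CGY", 1),
}

MOTIFS = ("WRCY", "WA", "RCG")
MOTIF_ENDS = ("5p", "3p")
MOTIF_STRANDS = ("forward", "reverse_complement")


def _iupac_match(seq: str, pattern: str, start: int) -> bool:
    if start < 0 or start + len(pattern) > len(seq):
        return False
    return all(seq[start + i] in _IUPAC[p] for i, p in enumerate(pattern))


@dataclass
class MotifAnnotation:
    """Independent boolean flags per (motif, event end, strand)."""

    flags: dict[tuple[str, str, str], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for motif in MOTIFS:
            for end in MOTIF_ENDS:
                for strand in MOTIF_STRANDS:
                    self.flags.setdefault((motif, end, strand), False)

    def __getitem__(self, key: tuple[str, str, str]) -> bool:
        return self.flags[key]

    def any(self) -> bool:
        return any(self.flags.values())


def annotate_aid_motifs(
    event: SubstitutionEvent, allele: GermlineAllele
) -> MotifAnnotation:
    """Flag AID motifs whose hotspot base coincides with an event end.

    A flag ``(motif, end, strand)`` is set iff an occurrence of the motif
    (forward on the coding strand, or its reverse complement representing
    the template strand) has its hotspot base (the C of WRCY/RCG, the A of
    WA, or the complementary base for reverse-complement occurrences) at
    the event's 5'-most (``5p``) or 3'-most (``3p``) mutated position.
    """
    germ = allele.ungapped
    annotation = MotifAnnotation()
    anchors = {"5p": event.start, "3p": event.end - 1}
    for (motif, strand), (pattern, hotspot_idx) in _MOTIF_PATTERNS.items():
        for end_label, anchor in anchors.items():
            if _iupac_match(germ, pattern, anchor - hotspot_idx):
                annotation.flags[(motif, end_label, strand)] = True
    return annotation


# ---------------------------------------------------------------------------
# Dinucleotide tables and DBS-78 catalogs
# ---------------------------------------------------------------------------


def build_dinuc_table(events: Iterable[SubstitutionEvent]) -> DinucSubstitutionTable:
    """Tabulate tandem events into the 144-cell dinucleotide table."""
    table = DinucSubstitutionTable()
    for e in events:
        if e.k != 2:
            raise ValidationError(f"build_dinuc_table requires k=2 events, got k={e.k}")
        table.increment(e.germline_bases, e.observed_bases)
    return table


def to_dbs78(table: DinucSubstitutionTable) -> DbsCatalog:
    """Collapse the 144-cell table onto the 78 canonical DBS classes."""
    catalog = DbsCatalog.zeros()
    for (ref, alt), value in table.counts.items():
        if value:
            catalog.increment(dbs78_class(ref, alt), value)
    return catalog


def cosine_similarity(a: DbsCatalog | np.ndarray, b: DbsCatalog | np.ndarray) -> float:
    """Cosine similarity between two DBS-78 vectors, in [0, 1]."""
    va = a.values if isinstance(a, DbsCatalog) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, DbsCatalog) else np.asarray(b, dtype=float)
    if va.shape != (78,) or vb.shape != (78,):
        raise ValidationError("cosine_similarity requires two length-78 vectors")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValidationError("cosine_similarity is undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


def category_counts(events: Sequence[SubstitutionEvent]) -> dict[str, int]:
    """Count tandem events per class (heterodimer references only)."""
    counts = {c: 0 for c in CATEGORIES}
    for e in events:
        counts[classify_tdns(e)] += 1
    return counts
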