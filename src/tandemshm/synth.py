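"""Synthetic repertoires with known ground truth.

Generates toy germline V alleles and mutated rearrangement records with
hotspot-biased independent single-nucleotide substitutions plus injected
single-event tandem substitutions at a controllable rate, so every pipeline
stage can be exercised offline against a known answer.  No indels are
simulated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from tandemshm.io_model import (
    GermlineAllele,
    NUCLEOTIDES,
    RepertoireRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

_SENSE_CODONS = [
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]

TANDEM_MODELS = ("uniform", "juxtalocation")


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic repertoire.

    ``theta`` is the fraction of mutation events that are true 2-nt tandem
    events; the remainder are hotspot-weighted independent SNS.  Loads are
    event counts drawn uniformly from ``min_load..max_load``, truncated so
    the mutated-nucleotide total stays within ``max_mutation_fraction`` of
    the V length.
    """

    n_sequences: int = 500
    n_alleles: int = 4
    v_length: int = 300
    min_load: int = 1
    max_load: int = 12
    max_mutation_fraction: float = 0.05
    hotspot_multiplier: float = 5.0
    theta: float = 0.0
    tandem_model: str = "juxtalocation"
    juxtalocation_prob: float = 0.8
    clonal_factor: int = 1
    nonsense_retries: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.theta <= 1:
            raise ValidationError(f"theta {self.theta} not in [0,1]")
        if self.min_load < 1 or self.max_load < self.min_load:
            raise ValidationError("invalid load range")
        if self.tandem_model not in TANDEM_MODELS:
            raise ValidationError(f"unknown tandem model {self.tandem_model!r}")
        if self.clonal_factor < 1:
            raise ValidationError("clonal_factor must be >= 1")


@dataclass
class GroundTruthEvent:
    """One injected mutation event with its true type."""

    sequence_id: str
    allele_name: str
    start: int
    germline_bases: str
    observed_bases: str
    is_tandem: bool

    @property
    def k(self) -> int:
        return len(self.germline_bases)


def _default_regions(n_codons: int) -> list[tuple[str, tuple[int, int]]]:
    bounds = [0, int(0.25 * n_codons), int(0.35 * n_codons), int(0.50 * n_codons),
              int(0.60 * n_codons), n_codons]
    labels = ["FR1", "CDR1", "FR2", "CDR2", "FR3"]
    return [
        (label, (bounds[i], bounds[i + 1])) for i, label in enumerate(labels)
    ]


def _iupac_find(seq: str, pattern: str) -> list[int]:
    table = {"W": "AT", "R": "AG", "Y": "CT"}
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + j] in table.get(p, p) for j, p in enumerate(pattern)):
            hits.append(i)
    return hits


def hotspot_positions(sequence: str) -> set[int]:
    """Ungapped positions covered by a forward WRCY or WA occurrence."""
    covered: set[int] = set()
    for pattern in ("WRCY", "WA"):
        for start in _iupac_find(sequence, pattern):
            covered.update(range(start, start + len(pattern)))
    return covered


def generate_toy_alleles(
    n: int, length: int, seed: int, max_retries: int = 200
) -> list[GermlineAllele]:
    """Random in-frame, stop-free toy alleles with guaranteed hotspots.

    Each allele contains at least one WRCY and one WA occurrence on the
    coding strand; deterministic per seed.
    """
    if length % 3 != 0:
        raise ValidationError(f"length {length} not divisible by 3")
    rng = np.random.default_rng(seed)
    alleles = []
    n_codons = length // 3
    for i in range(n):
        for _ in range(max_retries):
            seq = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
            if _iupac_find(seq, "WRCY") and _iupac_find(seq, "WA"):
                break
        else:
            raise ValidationError(
                "could not satisfy hotspot constraints within retry budget"
            )
        alleles.append(
            GermlineAllele(
                name=f"TOYV{i + 1}-1*01",
                sequence=seq,
                frame_offset=0,
                regions=_default_regions(n_codons),
            )
        )
    return alleles


def _weighted_pick(rng: np.random.Generator, candidates: np.ndarray, weights: np.ndarray) -> int:
    p = weights / weights.sum()
    return int(rng.choice(candidates, p=p))


def _tandem_outcome(
    rng: np.random.Generator, germ: str, p: int, config: SyntheticConfig
) -> str:
    ref = germ[p : p + 2]

    def uniform() -> str:
        return "".join(
            rng.choice([b for b in NUCLEOTIDES if b != r]) for r in ref
        )

    if config.tandem_model == "uniform" or rng.random() >= config.juxtalocation_prob:
        return uniform()
    # upstream (-1) shift preferred: the adjacent 5' sequence moves down one
    if p >= 1 and germ[p - 1] != ref[0] and ref[0] != ref[1]:
        return germ[p - 1] + ref[0]
    # downstream (+1) shift
    if p + 2 < len(germ) and ref[1] != ref[0] and germ[p + 2] != ref[1]:
        return ref[1] + germ[p + 2]
    return uniform()


def simulate_repertoire(
    config: SyntheticConfig,
    alleles: Sequence[GermlineAllele] | None = None,
) -> tuple[list[RepertoireRecord], list[GroundTruthEvent]]:
    """Simulate mutated rearrangement records with ground-truth events.

    Each sequence draws an event count; each event is a true tandem with
    probability ``theta`` (adjacent pair, outcome per the tandem model),
    otherwise an SNS at a hotspot-weighted position.  Events never overlap.
    Sequences whose mutations create a stop codon are regenerated within a
    bounded retry budget to emulate negative selection of nonsense.
    """
    rng = np.random.default_rng(config.seed)
    if alleles is None:
        alleles = generate_toy_alleles(
            config.n_alleles, config.v_length, seed=config.seed
        )
    weights_by_allele = {}
    for a in alleles:
        L = a.ungapped_length
        w = np.ones(L)
        for p in hotspot_positions(a.ungapped):
            w[p] = config.hotspot_multiplier
        weights_by_allele[a.name] = w

    records: list[RepertoireRecord] = []
    ground_truth: list[GroundTruthEvent] = []
    for i in range(config.n_sequences):
        allele = alleles[int(rng.integers(len(alleles)))]
        germ = allele.ungapped
        L = len(germ)
        weights = weights_by_allele[allele.name]
        budget = int(config.max_mutation_fraction * L)
        n_events = int(rng.integers(config.min_load, config.max_load + 1))
        seq_id = f"seq{i:05d}"

        for attempt in range(config.nonsense_retries + 1):
            mutated: dict[int, str] = {}
            events: list[GroundTruthEvent] = []
            for _ in range(n_events):
                is_tandem = rng.random() < config.theta
                k = 2 if is_tandem else 1
                if len(mutated) + k > budget:
                    break
                if is_tandem:
                    cand = np.array(
                        [
                            p
                            for p in range(L - 1)
                            if p not in mutated and p + 1 not in mutated
                        ]
                    )
                    if cand.size == 0:
                        raise ValidationError(
                            f"sequence {seq_id}: no room for a tandem event"
                        )
                    p = _weighted_pick(rng, cand, weights[cand])
                    obs = _tandem_outcome(rng, germ, p, config)
                    mutated[p], mutated[p + 1] = obs[0], obs[1]
                    events.append(
                        GroundTruthEvent(
                            seq_id, allele.name, p, germ[p : p + 2], obs, True
                        )
                    )
                else:
                    cand = np.array([p for p in range(L) if p not in mutated])
                    if cand.size == 0:
                        raise ValidationError(
                            f"sequence {seq_id}: load exceeds available positions"
                        )
                    p = _weighted_pick(rng, cand, weights[cand])
                    obs = str(rng.choice([b for b in NUCLEOTIDES if b != germ[p]]))
                    mutated[p] = obs
                    events.append(
                        GroundTruthEvent(seq_id, allele.name, p, germ[p], obs, False)
                    )
            chars = list(germ)
            for p, b in mutated.items():
                chars[p] = b
            observed_seq = "".join(chars)
            frame = observed_seq[allele.frame_offset :]
            frame = frame[: 3 * (len(frame) // 3)]
            if "*" not in str(Seq(frame).translate()):
                break
        else:
            logger.warning(
                "sequence %s still carries a stop codon after %d retries",
                seq_id, config.nonsense_retries,
            )

        cdr3 = "".join(rng.choice(list(NUCLEOTIDES), size=21))
        records.append(
            RepertoireRecord(
                sequence_id=seq_id,
                v_call=allele.name,
                v_alignment=observed_seq,
                germline_alignment=allele.sequence,
                cdr3_nt=cdr3,
                d_call="TOYD1*01",
                j_call="TOYJ1*01",
                isotype=str(rng.choice(["IGM", "IGG"])),
                mutation_count=len(mutated),
            )
        )
        ground_truth.extend(events)
    return records, ground_truth


def expand_clones(
    records: Sequence[RepertoireRecord], factor: int, seed: int
) -> list[RepertoireRecord]:
    """Add clonal duplicates carrying extra SNS (original stays least mutated).

    Each record gains ``0..factor-1`` duplicates with 1-3 additional SNS in
    currently unmutated positions; CDR3 and V/D/J calls are preserved so
    clonal collapse recovers exactly the original set.
    """
    if factor < 1:
        raise ValidationError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[RepertoireRecord] = []
    for r in records:
        out.append(r)
        germ = r.germline_alignment
        if germ is None:
            raise ValidationError(
                f"record {r.sequence_id!r}: germline alignment required"
            )
        for j in range(int(rng.integers(0, factor))):
            free = [
                i
                for i, (o, g) in enumerate(zip(r.v_alignment, germ))
                if o == g and g in NUCLEOTIDES
            ]
            n_extra = int(rng.integers(1, 4))
            picks = rng.choice(free, size=min(n_extra, len(free)), replace=False)
            chars = list(r.v_alignment)
            for p in picks:
                chars[p] = str(
                    rng.choice([b for b in NUCLEOTIDES if b != chars[p]])
                )
            out.append(
                replace(
                    r,
                    sequence_id=f"{r.sequence_id}_dup{j + 1}",
                    v_alignment="".join(chars),
                    mutation_count=(r.mutation_count or 0) + len(picks),
                )
            )
    return out
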