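"""Clonal collapse and mutation-load filtering of repertoire records."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from tandemshm.io_model import GermlineAllele, RepertoireRecord, ValidationError

MUTATION_LOAD_BINS = ("(0.05,0.10]", "(0.10,0.20]", "(0.20,1]")


@dataclass(frozen=True)
class ClonotypeKey:
    """Gene-level V/D/J identifiers plus CDR3 length."""

    v_gene: str
    d_gene: str
    j_gene: str
    cdr3_length: int


def _gene_of(call: str) -> str:
    """Gene-level identifier: first listed call, allele suffix stripped."""
    return call.split(",")[0].split("*")[0].strip()


def clonotype_key(record: RepertoireRecord) -> ClonotypeKey:
    return ClonotypeKey(
        v_gene=_gene_of(record.v_call),
        d_gene=_gene_of(record.d_call),
        j_gene=_gene_of(record.j_call),
        cdr3_length=len(record.cdr3_nt),
    )


def _cdr3_identity(a: str, b: str) -> float:
    # equal lengths guaranteed within a clonotype key
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def collapse_clones(
    records: Sequence[RepertoireRecord], identity_threshold: float = 0.95
) -> list[RepertoireRecord]:
    """Collapse clonal expansions to one representative per clone.

    Records sharing a :class:`ClonotypeKey` are single-linkage clustered on
    CDR3 Hamming identity at ``identity_threshold``; each cluster is reduced
    to its member with the minimal ``mutation_count`` (ties broken by
    lexicographically smallest ``sequence_id``).
    """
    by_key: dict[ClonotypeKey, list[RepertoireRecord]] = {}
    for r in records:
        if r.mutation_count is None:
            raise ValidationError(
                f"record {r.sequence_id!r}: mutation_count not computed"
            )
        by_key.setdefault(clonotype_key(r), []).append(r)

    survivors: list[RepertoireRecord] = []
    for group in by_key.values():
        n = len(group)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                ident = _cdr3_identity(group[i].cdr3_nt, group[j].cdr3_nt)
                if ident >= identity_threshold:
                    parent[find(i)] = find(j)
        clusters: dict[int, list[RepertoireRecord]] = {}
        for i, r in enumerate(group):
            clusters.setdefault(find(i), []).append(r)
        for members in clusters.values():
            survivors.append(
                min(members, key=lambda r: (r.mutation_count, r.sequence_id))
            )
    survivors.sort(key=lambda r: r.sequence_id)
    return survivors


def _mutation_fraction(
    record: RepertoireRecord, allele_map: Mapping[str, GermlineAllele]
) -> float:
    v_call = record.v_call.split(",")[0].strip()
    if v_call not in allele_map:
        raise ValidationError(f"unknown V allele {v_call!r}")
    if record.mutation_count is None:
        raise ValidationError(
            f"record {record.sequence_id!r}: mutation_count not computed"
        )
    return record.mutation_count / allele_map[v_call].ungapped_length


def filter_by_mutation_load(
    records: Iterable[RepertoireRecord],
    allele_map: Mapping[str, GermlineAllele],
    max_fraction: float = 0.05,
) -> tuple[list[RepertoireRecord], list[RepertoireRecord], list[RepertoireRecord]]:
    """Partition records into (kept, unmutated, hypermutated).

    A record is kept iff ``0 < m/L <= max_fraction`` where ``L`` is the
    ungapped V length of its allele; the partition is exhaustive.
    """
    kept: list[RepertoireRecord] = []
    unmutated: list[RepertoireRecord] = []
    hypermutated: list[RepertoireRecord] = []
    for r in records:
        frac = _mutation_fraction(r, allele_map)
        if r.mutation_count == 0:
            unmutated.append(r)
        elif frac > max_fraction:
            hypermutated.append(r)
        else:
            kept.append(r)
    return kept, unmutated, hypermutated


def bin_by_mutation_load(
    records: Iterable[RepertoireRecord],
    allele_map: Mapping[str, GermlineAllele],
) -> dict[str, list[RepertoireRecord]]:
    """Group hypermutated records into left-open/right-closed load bins.

    Bins are ``(0.05,0.10]``, ``(0.10,0.20]`` and ``(0.20,1]``; records with
    ``m/L <= 0.05`` are not binned.
    """
    bins: dict[str, list[RepertoireRecord]] = {b: [] for b in MUTATION_LOAD_BINS}
    for r in records:
        frac = _mutation_fraction(r, allele_map)
        if frac <= 0.05:
            continue
        if frac <= 0.10:
            bins["(0.05,0.10]"].append(r)
        elif frac <= 0.20:
            bins["(0.10,0.20]"].append(r)
        else:
            bins["(0.20,1]"].append(r)
    return bins
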