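"""Monte-Carlo null model for coincidentally adjacent single substitutions.

Observed runs of adjacent mutated positions may be genuine single-event
tandems or clusters of independently acquired single-nucleotide
substitutions (SNS).  This module estimates the latter: germline sequences
are re-mutated in silico with per-position SNS frequencies and target-base
distributions taken from the data, matching each sequence's mutation load
exactly, and the resulting cluster counts per run length form the null
distribution used to correct observed tandem counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from tandemshm.io_model import (
    GermlineAllele,
    NUCLEOTIDES,
    RepertoireRecord,
    SubstitutionEvent,
    ValidationError,
)

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


@dataclass
class PositionProfile:
    """Per-position SNS statistics of one allele.

    ``frequency[p]`` is the observed SNS count at ungapped position ``p``
    divided by the number of sequences covering ``p``; ``target_counts``
    holds per-position counts of the observed target bases (columns A,C,G,T)
    and drives the target distribution ``g(p, b)``.
    """

    allele_name: str
    sns_count: np.ndarray
    coverage: np.ndarray
    target_counts: np.ndarray

    def __post_init__(self) -> None:
        self.sns_count = np.asarray(self.sns_count, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        self.target_counts = np.asarray(self.target_counts, dtype=float)
        L = len(self.sns_count)
        if self.coverage.shape != (L,) or self.target_counts.shape != (L, 4):
            raise ValidationError("profile arrays have inconsistent shapes")

    @property
    def length(self) -> int:
        return len(self.sns_count)

    @property
    def frequency(self) -> np.ndarray:
        """f(p) = SNS count / coverage, zero where coverage is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(self.coverage > 0, self.sns_count / self.coverage, 0.0)
        return f

    def target_distribution(self) -> np.ndarray:
        """g(p, b): row-normalized target-base counts (NaN rows where f=0)."""
        totals = self.target_counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.target_counts / totals

    @property
    def mutable_positions(self) -> np.ndarray:
        return np.flatnonzero(self.frequency > 0)


def build_position_profile(
    records: Sequence[RepertoireRecord],
    allele: GermlineAllele,
    events: Iterable[SubstitutionEvent],
) -> PositionProfile:
    """Build the per-position SNS profile of one allele.

    Only k=1 events contribute; positions inside observed clusters are
    deliberately left out of the null so the signal being tested does not
    contaminate it.  Coverage counts sequences with an unambiguous base at
    the position.
    """
    mine = [r for r in records if r.v_call.split(",")[0].strip() == allele.name]
    if not mine:
        raise ValidationError(f"no records for allele {allele.name!r}")
    L = allele.ungapped_length
    sns = np.zeros(L)
    coverage = np.zeros(L)
    targets = np.zeros((L, 4))

    non_gap = [i for i, c in enumerate(allele.sequence) if c != "."]
    for r in mine:
        aln = r.v_alignment.upper()
        for p, col in enumerate(non_gap):
            if aln[col] in NUCLEOTIDES:
                coverage[p] += 1

    ids = {r.sequence_id for r in mine}
    for e in events:
        if e.k != 1 or e.allele_name != allele.name:
            continue
        if e.sequence_id and e.sequence_id not in ids:
            continue
        sns[e.start] += 1
        targets[e.start, _BASE_INDEX[e.observed_bases]] += 1
    return PositionProfile(
        allele_name=allele.name, sns_count=sns, coverage=coverage, target_counts=targets
    )


def _run_length_counts(mutated: np.ndarray) -> np.ndarray:
    """bincount of maximal True-run lengths, rows separated."""
    S = mutated.shape[0]
    padded = np.concatenate(
        [mutated, np.zeros((S, 1), dtype=bool)], axis=1
    ).ravel()
    x = np.concatenate([[False], padded])
    starts = np.flatnonzero(~x[:-1] & x[1:])
    ends = np.flatnonzero(x[:-1] & ~x[1:])
    if len(starts) == 0:
        return np.zeros(0, dtype=np.int64)
    return np.bincount(ends - starts)


def simulate_replicate(
    profile: PositionProfile,
    loads: Sequence[int],
    rng: np.random.Generator,
    return_mutations: bool = False,
):
    """Mutate one in-silico replicate of a set of sequences.

    Each sequence receives exactly its observed mutation load ``m``:
    ``m`` distinct positions are drawn without replacement with probability
    proportional to ``f``, each is assigned a target base from ``g``, and
    maximal runs of adjacent mutated positions are counted per length.

    Returns a mapping run length -> cluster count; with
    ``return_mutations=True`` also a list of ``(positions, bases)`` per
    sequence.
    """
    loads_arr = np.asarray(loads, dtype=int)
    pos = profile.mutable_positions
    weights = profile.frequency[pos]
    too_big = np.flatnonzero(loads_arr > len(pos))
    if too_big.size:
        raise ValidationError(
            f"sequence {too_big[0]}: load {loads_arr[too_big[0]]} exceeds "
            f"{len(pos)} mutable positions of allele {profile.allele_name!r}"
        )
    S = len(loads_arr)
    if S == 0 or loads_arr.sum() == 0:
        return ({}, []) if return_mutations else {}

    # weighted sampling without replacement via exponential races:
    # the m smallest of Exp(1)/w_i reproduce sequential sampling
    # proportional to the weights
    keys = rng.exponential(size=(S, len(pos))) / weights
    order = np.argsort(keys, axis=1, kind="stable")
    max_m = int(loads_arr.max())
    sel = order[:, :max_m]
    mask = np.arange(max_m) < loads_arr[:, None]
    rows = np.repeat(np.arange(S), loads_arr)
    flat_local = sel[mask]
    flat_pos = pos[flat_local]

    mutated = np.zeros((S, profile.length), dtype=bool)
    mutated[rows, flat_pos] = True

    # target bases: categorical draw from g at each mutated position
    g = profile.target_distribution()
    cum = np.cumsum(g[flat_pos], axis=1)
    u = rng.random(len(flat_pos))
    base_idx = (u[:, None] >= cum).sum(axis=1)

    counts_arr = _run_length_counts(mutated)
    counts = {k: int(c) for k, c in enumerate(counts_arr) if k >= 1 and c > 0}
    if not return_mutations:
        return counts

    mutations = []
    offsets = np.concatenate([[0], np.cumsum(loads_arr)])
    for i in range(S):
        sl = slice(offsets[i], offsets[i + 1])
        p = flat_pos[sl]
        order_i = np.argsort(p)
        bases = "".join(NUCLEOTIDES[j] for j in base_idx[sl][order_i])
        mutations.append((p[order_i], bases))
    return counts, mutations


@dataclass
class RunLengthStats:
    """Observed vs simulated statistics for one run length."""

    observed: float
    sim_mean: float
    sim_sd: float
    z: float
    corrected: float

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "sim_mean": self.sim_mean,
            "sim_sd": self.sim_sd,
            "z": None if np.isnan(self.z) else self.z,
            "corrected": self.corrected,
        }


@dataclass
class NullSimulationResult:
    """Aggregated null-simulation output.

    ``stats[k]`` compares the observed count of length-``k`` runs with the
    simulated mean/sd; ``corrected = observed - sim_mean`` may be negative
    and is then reported as-is with a warning flag, never clipped.
    """

    replicates: int
    seed: int
    n_sequences: int
    stats: dict[int, RunLengthStats]
    warnings: list[str] = field(default_factory=list)

    @property
    def max_k(self) -> int:
        return max(self.stats) if self.stats else 0

    def to_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "seed": self.seed,
            "n_sequences": self.n_sequences,
            "run_lengths": {str(k): s.to_dict() for k, s in self.stats.items()},
            "warnings": list(self.warnings),
        }


def run_null_simulation(
    records: Sequence[RepertoireRecord],
    profiles: Mapping[str, PositionProfile],
    events: Sequence[SubstitutionEvent],
    reps: int = 100_000,
    seed: int = 0,
) -> NullSimulationResult:
    """Aggregate :func:`simulate_replicate` over ``reps`` replicates.

    Records are grouped by allele; only records whose allele has a profile
    are modelled, with per-sequence loads taken from their called events.
    Deterministic for a given seed (per-replicate child RNG streams are
    spawned from the master seed).
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    load_by_id: dict[str, int] = {}
    for e in events:
        load_by_id[e.sequence_id] = load_by_id.get(e.sequence_id, 0) + e.k

    groups: dict[str, list[int]] = {}
    modelled_ids: set[str] = set()
    for r in records:
        name = r.v_call.split(",")[0].strip()
        if name not in profiles:
            continue
        load = load_by_id.get(r.sequence_id, 0)
        if load == 0:
            continue
        groups.setdefault(name, []).append(load)
        modelled_ids.add(r.sequence_id)

    observed: dict[int, int] = {}
    for e in events:
        if e.sequence_id in modelled_ids:
            observed[e.k] = observed.get(e.k, 0) + 1

    allele_order = sorted(groups)
    children = np.random.SeedSequence(seed).spawn(reps)
    sim = np.zeros((reps, 1), dtype=np.int64)
    for r_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        for name in allele_order:
            counts = simulate_replicate(profiles[name], groups[name], rng)
            for k, c in counts.items():
                if k >= sim.shape[1] + 1:
                    extra = np.zeros((reps, k - sim.shape[1]), dtype=np.int64)
                    sim = np.concatenate([sim, extra], axis=1)
                sim[r_idx, k - 1] += c

    max_k = max([sim.shape[1]] + list(observed) or [1])
    stats: dict[int, RunLengthStats] = {}
    warnings: list[str] = []
    for k in range(1, max_k + 1):
        col = sim[:, k - 1] if k <= sim.shape[1] else np.zeros(reps, dtype=np.int64)
        mean = float(col.mean())
        sd = float(col.std(ddof=1)) if reps > 1 else float("nan")
        obs = float(observed.get(k, 0))
        if np.isnan(sd) or sd == 0:
            z = float("nan")
        else:
            z = (obs - mean) / sd
        corrected = obs - mean
        if k >= 2 and corrected < 0:
            warnings.append(
                f"negative corrected count for k={k}: {corrected:.3f}"
            )
        stats[k] = RunLengthStats(
            observed=obs, sim_mean=mean, sim_sd=sd, z=z, corrected=corrected
        )
    return NullSimulationResult(
        replicates=reps,
        seed=seed,
        n_sequences=len(modelled_ids),
        stats=stats,
        warnings=warnings,
    )


def corrected_incidence(result: NullSimulationResult) -> dict:
    """Correct run-length counts and express them as incidences.

    False tandems count as multiple SNS each: the adjusted SNS total is
    ``S' = O_1 + sum_k>=2 k * mu_k``; corrected event counts are
    ``C_k = O_k - mu_k``; ``incidence(k) = C_k / (S' + sum C_k)``.
    """
    stats = result.stats
    o1 = stats.get(1).observed if 1 in stats else 0.0
    adjusted_sns = o1 + sum(k * s.sim_mean for k, s in stats.items() if k >= 2)
    corrected = {k: s.corrected for k, s in stats.items() if k >= 2}
    denominator = adjusted_sns + sum(corrected.values())
    if denominator <= 0:
        raise ValidationError(
            f"corrected substitution total is non-positive ({denominator:.3f})"
        )
    incidence = {k: c / denominator for k, c in corrected.items()}
    cumulative = sum(corrected.values()) / denominator
    # Monte-Carlo standard error of the cumulative corrected incidence
    # (denominator treated as fixed)
    var_mc = sum(
        (s.sim_sd**2) / result.replicates
        for k, s in stats.items()
        if k >= 2 and not np.isnan(s.sim_sd)
    )
    return {
        "adjusted_sns": adjusted_sns,
        "corrected_counts": corrected,
        "denominator": denominator,
        "incidence": incidence,
        "cumulative_tandem_incidence": cumulative,
        "cumulative_se_mc": float(np.sqrt(var_mc)) / denominator,
    }
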