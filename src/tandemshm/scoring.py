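"""Mutational resistance scoring and quasi-Poisson regression.

Each codon position gets an expected synonymous probability from
enumerating all nine single-base substitutions of the germline codons used
there (nonsense outcomes disregarded), an observed synonymous proportion
from called SNS, and a resistance score = observed - expected.  Tandem
counts per position are then regressed on the score with a log-link
quasi-Poisson model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from Bio.Seq import Seq

from tandemshm.io_model import (
    GermlineAllele,
    NUCLEOTIDES,
    SubstitutionEvent,
    ValidationError,
)
from tandemshm import tandems

logger = logging.getLogger(__name__)


def codon_syn_profile(codon: str) -> tuple[int, int, int, float]:
    """Classify the 9 single-base substitutions of a sense codon.

    Returns ``(n_syn, n_nonsyn, n_nonsense, P_syn)`` with
    ``P_syn = n_syn / (n_syn + n_nonsyn)`` — nonsense outcomes are
    disregarded because they are purged from the repertoire.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon):
        raise ValidationError(f"not a codon over ACGT: {codon!r}")
    aa = str(Seq(codon).translate())
    if aa == "*":
        raise ValidationError(f"stop codon {codon!r} has no synonymous profile")
    n_syn = n_nonsyn = n_nonsense = 0
    for i in range(3):
        for b in NUCLEOTIDES:
            if b == codon[i]:
                continue
            mutated = codon[:i] + b + codon[i + 1 :]
            new_aa = str(Seq(mutated).translate())
            if new_aa == "*":
                n_nonsense += 1
            elif new_aa == aa:
                n_syn += 1
            else:
                n_nonsyn += 1
    p_syn = n_syn / (n_syn + n_nonsyn)
    return n_syn, n_nonsyn, n_nonsense, p_syn


def _codon_at(allele: GermlineAllele, q: int) -> str | None:
    start = allele.frame_offset + 3 * q
    codon = allele.ungapped[start : start + 3]
    if len(codon) < 3 or any(c not in NUCLEOTIDES for c in codon):
        return None
    return codon


def expected_syn_by_position(
    alleles: Sequence[GermlineAllele],
    usage_weights: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Usage-weighted expected synonymous probability per codon position.

    ``E_q = sum_c w(c|q) * P_syn(c)`` over the germline codons observed at
    position ``q``; weights renormalize over the alleles that have a
    complete codon there.  Positions absent from every allele are NaN.
    """
    if usage_weights is None:
        usage_weights = {a.name: 1.0 for a in alleles}
    total_w = sum(usage_weights.get(a.name, 0.0) for a in alleles)
    if total_w <= 0:
        raise ValidationError("usage weights sum to zero")

    n_codons = max(
        (a.ungapped_length - a.frame_offset) // 3 for a in alleles
    )
    expected = np.full(n_codons, np.nan)
    for q in range(n_codons):
        acc = 0.0
        w_here = 0.0
        for a in alleles:
            codon = _codon_at(a, q)
            if codon is None:
                continue
            if str(Seq(codon).translate()) == "*":
                raise ValidationError(
                    f"germline stop codon at codon position {q} of {a.name!r}"
                )
            w = usage_weights.get(a.name, 0.0)
            if w <= 0:
                continue
            acc += w * codon_syn_profile(codon)[3]
            w_here += w
        if w_here > 0:
            expected[q] = acc / w_here
    return expected


@dataclass
class ResistanceTrack:
    """Per-codon-position selection statistics.

    ``score[q] = s[q]/n[q] - expected[q]`` (NaN where no SNS were observed);
    higher scores mark positions with more synonymous substitutions than
    expected, i.e. more resistance to amino-acid change.
    """

    expected: np.ndarray
    n_sns: np.ndarray
    s_syn: np.ndarray
    tdns_count: np.ndarray

    @property
    def score(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            observed = np.where(self.n_sns > 0, self.s_syn / self.n_sns, np.nan)
        return observed - self.expected

    @property
    def n_positions(self) -> int:
        return len(self.expected)


def build_resistance_track(
    events: Iterable[SubstitutionEvent],
    alleles: Sequence[GermlineAllele],
    usage_weights: Mapping[str, float] | None = None,
) -> ResistanceTrack:
    """Aggregate SNS effects and tandem counts per codon position.

    SNS with a nonsense effect are excluded from both numerator and
    denominator of the observed synonymous proportion, mirroring the
    expected-side computation.  Tandem events are attributed to the codon
    containing their 5' base.
    """
    allele_map = {a.name: a for a in alleles}
    expected = expected_syn_by_position(alleles, usage_weights)
    n = np.zeros(len(expected))
    s = np.zeros(len(expected))
    t = np.zeros(len(expected))
    for e in events:
        allele = allele_map.get(e.allele_name)
        if allele is None:
            continue
        rel = e.start - allele.frame_offset
        if rel < 0:
            continue
        q = rel // 3
        if q >= len(expected):
            continue
        if e.k == 1:
            call = tandems.classify_effect(e, allele)
            if call is None or call.effect == tandems.NONSENSE:
                continue
            n[q] += 1
            if call.effect == tandems.SYNONYMOUS:
                s[q] += 1
        elif e.k == 2:
            t[q] += 1
    return ResistanceTrack(expected=expected, n_sns=n, s_syn=s, tdns_count=t)


@dataclass
class QuasiPoissonFit:
    """Log-link quasi-Poisson fit of counts on a covariate."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    dispersion: float
    p_value: float
    converged: bool
    n: int

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "se_intercept": self.se_intercept,
            "se_slope": self.se_slope,
            "dispersion": self.dispersion,
            "p_value": self.p_value,
            "converged": self.converged,
            "n": self.n,
        }


def quasipoisson_regression(
    t: Sequence[float], score: Sequence[float]
) -> QuasiPoissonFit:
    """Regress per-position tandem counts on the resistance score.

    Fits ``mu_q = exp(a + beta * S_q)`` by Poisson IRLS; the dispersion
    ``phi`` is the Pearson chi-square over ``N - 2`` degrees of freedom,
    standard errors are scaled by ``sqrt(phi)``, and the slope p-value uses
    the t distribution with ``N - 2`` df.  Pairs with undefined score are
    dropped.
    """
    t_arr = np.asarray(t, dtype=float)
    s_arr = np.asarray(score, dtype=float)
    if t_arr.shape != s_arr.shape:
        raise ValidationError("counts and scores must have equal length")
    keep = ~np.isnan(s_arr) & ~np.isnan(t_arr)
    t_arr, s_arr = t_arr[keep], s_arr[keep]
    if len(t_arr) < 3:
        raise ValidationError("need at least 3 positions with a defined score")
    if np.any(t_arr < 0):
        raise ValidationError("counts must be non-negative")
    if np.isclose(np.var(s_arr), 0):
        raise ValidationError("zero variance in the resistance score")

    X = sm.add_constant(s_arr)
    model = sm.GLM(t_arr, X, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        logger.warning("quasi-Poisson IRLS did not converge")
    # quasi-Poisson: point estimates are the Poisson IRLS estimates, the
    # dispersion is Pearson chi2 / (N - 2), and SEs scale by sqrt(phi)
    df_resid = len(t_arr) - 2
    phi = float(res.pearson_chi2) / df_resid
    se = res.bse * np.sqrt(phi)
    if se[1] > 0 and phi > 1e-12:
        t_stat = res.params[1] / se[1]
        p_value = float(2 * stats.t.sf(abs(t_stat), df_resid))
    else:
        # a (numerically) zero-dispersion, perfectly fitted model carries no
        # evidence against the null
        p_value = 1.0
    return QuasiPoissonFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        dispersion=phi,
        p_value=p_value,
        converged=bool(res.converged),
        n=len(t_arr),
    )
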