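"""Forensic and parentage power statistics for codominant STR loci.

Per-locus statistics
--------------------
PD   power of discrimination: probability two random individuals differ in
     genotype, ``1 - sum_g f_g^2`` over genotype frequencies (HWE-expected by
     default, observed tallies optionally).
PE   power of exclusion as a function of observed heterozygosity h:
     ``PE = h^2 (1 - 2 h (1-h)^2)``.
PE1  parentage exclusion probability when only the candidate parent is typed:
     the probability, for a random true parent-offspring duo and a random
     unrelated candidate (all under HWE and Mendelian transmission), that the
     candidate shares no allele with the offspring.
PE2  exclusion probability when one true parent is also typed: probability an
     unrelated candidate cannot supply the obligate paternal/maternal allele
     given the known parent and offspring.
PID  probability of identity: probability two unrelated individuals share a
     genotype, ``sum p_i^4 + sum_{i<j} (2 p_i p_j)^2``.

PE1 and PE2 are implemented as closed-form polynomials in the power sums
``a_k = sum_i p_i^k``; exhaustive genotype-enumeration oracles with explicit
Mendelian transmission are provided alongside and define the semantics.

Panel combination across independent loci: cumulative powers combine as
``1 - prod(1 - x_l)`` and the identity probability as ``prod PID_l``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np


def _check_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if (p < 0).any() or not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("frequencies must be nonnegative and sum to 1")
    return p


# ---------------------------------------------------------------------------
# per-locus statistics

def power_of_exclusion(ho: float) -> float:
    """PE from observed heterozygosity: ``h^2 (1 - 2 h (1-h)^2)``."""
    if not 0.0 <= ho <= 1.0:
        raise ValueError(f"observed heterozygosity {ho} outside [0, 1]")
    h = ho
    big_h = 1.0 - h
    return h * h * (1.0 - 2.0 * h * big_h * big_h)


def power_of_discrimination(genotype_freqs: dict[tuple[int, int], float]) -> float:
    """PD = 1 - sum of squared genotype frequencies."""
    if not genotype_freqs:
        raise ValueError("empty genotype frequency map")
    f = np.asarray(list(genotype_freqs.values()), dtype=float)
    return float(1.0 - np.sum(f**2))


def hwe_genotype_freqs(p: np.ndarray | dict[int, float]) -> dict[tuple[int, int], float]:
    """Unordered genotype frequencies expected under HWE."""
    if isinstance(p, dict):
        alleles, vec = list(p.keys()), np.asarray(list(p.values()), dtype=float)
    else:
        vec = _check_simplex(p)
        alleles = list(range(vec.size))
    out: dict[tuple[int, int], float] = {}
    for i, j in combinations_with_replacement(range(len(alleles)), 2):
        f = vec[i] ** 2 if i == j else 2 * vec[i] * vec[j]
        out[(alleles[i], alleles[j])] = float(f)
    return out


def probability_of_identity(p: np.ndarray) -> float:
    """PID = sum p_i^4 + sum_{i<j} (2 p_i p_j)^2."""
    p = _check_simplex(p)
    a2 = float(np.sum(p**2))
    a4 = float(np.sum(p**4))
    # sum_{i<j} (2 p_i p_j)^2 = 2 [(sum p^2)^2 - sum p^4]
    return a4 + 2.0 * (a2 * a2 - a4)


def exclusion_prob_duo(p: np.ndarray) -> float:
    """PE1 closed form: ``1 - 4 a2 + 4 a3 - 3 a4 + 2 a2^2``."""
    p = _check_simplex(p)
    a2 = float(np.sum(p**2))
    a3 = float(np.sum(p**3))
    a4 = float(np.sum(p**4))
    return 1.0 - 4.0 * a2 + 4.0 * a3 - 3.0 * a4 + 2.0 * a2 * a2


def exclusion_prob_trio(p: np.ndarray) -> float:
    """PE2 closed form: ``1 - 2 a2 + a3 + 2 a4 - 3 a5 - 2 a2^2 + 3 a2 a3``."""
    p = _check_simplex(p)
    a2 = float(np.sum(p**2))
    a3 = float(np.sum(p**3))
    a4 = float(np.sum(p**4))
    a5 = float(np.sum(p**5))
    return 1.0 - 2.0 * a2 + a3 + 2.0 * a4 - 3.0 * a5 - 2.0 * a2 * a2 + 3.0 * a2 * a3


# ---------------------------------------------------------------------------
# enumeration oracles: exhaustive genotype enumeration with explicit
# Mendelian transmission.  These define the exclusion semantics; the closed
# forms above must agree with them to numerical precision.

def _genotype_space(k: int) -> tuple[np.ndarray, np.ndarray]:
    """All unordered genotypes over k alleles as (g1, g2) index arrays."""
    pairs = list(combinations_with_replacement(range(k), 2))
    g = np.asarray(pairs, dtype=np.int64)
    return g[:, 0], g[:, 1]


def _hwe_weights(p: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    w = p[g1] * p[g2]
    return np.where(g1 == g2, w, 2 * w)


def pid_enumeration(p: np.ndarray) -> float:
    """PID by summing squared HWE genotype frequencies over all genotypes."""
    p = _check_simplex(p)
    g1, g2 = _genotype_space(p.size)
    return float(np.sum(_hwe_weights(p, g1, g2) ** 2))


def exclusion_duo_enumeration(p: np.ndarray) -> float:
    """PE1 oracle.

    Enumerates both true parents under HWE, all four Mendelian transmissions
    to the offspring, and every candidate genotype under HWE; accumulates the
    probability that candidate and offspring share no allele.
    """
    p = _check_simplex(p)
    k = p.size
    g1, g2 = _genotype_space(k)
    hwe = _hwe_weights(p, g1, g2)
    n_g = g1.size

    # offspring distribution by explicit transmission enumeration
    off: dict[tuple[int, int], float] = {}
    for mi in range(n_g):
        for fi in range(n_g):
            w = hwe[mi] * hwe[fi] * 0.25
            for a in (g1[mi], g2[mi]):
                for b in (g1[fi], g2[fi]):
                    key = (min(a, b), max(a, b))
                    off[key] = off.get(key, 0.0) + w

    total = 0.0
    for (a, b), w_off in off.items():
        shares = (g1 == a) | (g2 == a) | (g1 == b) | (g2 == b)
        total += w_off * float(np.sum(hwe[~shares]))
    return total


def exclusion_trio_enumeration(p: np.ndarray) -> float:
    """PE2 oracle.

    Enumerates the known parent, the true second parent, all Mendelian
    transmissions, and the unrelated candidate; the candidate is excluded when
    no pairing of one known-parent allele with one candidate allele can
    produce the offspring genotype.
    """
    p = _check_simplex(p)
    k = p.size
    g1, g2 = _genotype_space(k)
    hwe = _hwe_weights(p, g1, g2)
    n_g = g1.size

    total = 0.0
    for kp in range(n_g):  # known parent
        kp_alleles = (int(g1[kp]), int(g2[kp]))
        # offspring distribution given known parent: enumerate the true mate
        off: dict[tuple[int, int], float] = {}
        for mate in range(n_g):
            w = hwe[mate] * 0.25
            for a in kp_alleles:
                for b in (g1[mate], g2[mate]):
                    key = (min(a, b), max(a, b))
                    off[key] = off.get(key, 0.0) + w
        for (x, y), w_off in off.items():
            # candidate compatible iff some (u from known parent, v from
            # candidate) reconstructs the offspring genotype {x, y}
            compatible = np.zeros(n_g, dtype=bool)
            for u in kp_alleles:
                for cand_alleles in (g1, g2):
                    compatible |= (
                        ((u == x) & (cand_alleles == y))
                        | ((u == y) & (cand_alleles == x))
                    )
            total += hwe[kp] * w_off * float(np.sum(hwe[~compatible]))
    return total


# ---------------------------------------------------------------------------
# records and panel combination

@dataclass
class ForensicRecord:
    """Per-locus forensic power statistics."""

    locus: str
    ho: float
    he: float
    pd: float
    pe: float
    pic: float
    pe1: float
    pe2: float
    pid: float


@dataclass
class PanelSummary:
    """Cumulative and mean statistics over an independent-locus panel."""

    cpd: float
    cpe: float
    cpe1: float
    cpe2: float
    cpid: float
    mean_ho: float
    mean_he: float
    mean_pic: float
    n_loci: int


def forensic_record(
    locus: str,
    p: np.ndarray,
    ho: float,
    n_genotypes: int | None = None,
    genotype_freqs: dict[tuple[int, int], float] | None = None,
) -> ForensicRecord:
    """Build the per-locus record from allele frequencies and observed Ho.

    PD uses HWE-expected genotype frequencies unless observed tallies are
    passed via ``genotype_freqs``.
    """
    from .diversity import expected_heterozygosity, pic as pic_fn

    p = _check_simplex(p)
    gf = genotype_freqs if genotype_freqs is not None else hwe_genotype_freqs(p)
    return ForensicRecord(
        locus=locus,
        ho=ho,
        he=expected_heterozygosity(p),
        pd=power_of_discrimination(gf),
        pe=power_of_exclusion(ho),
        pic=pic_fn(p),
        pe1=exclusion_prob_duo(p),
        pe2=exclusion_prob_trio(p),
        pid=probability_of_identity(p),
    )


def combine_panel(records: list[ForensicRecord]) -> PanelSummary:
    """Combine per-locus records across an independent panel.

    Powers combine as ``1 - prod(1 - x_l)``; the identity probability as
    ``prod PID_l``; Ho/He/PIC report arithmetic means.
    """
    if not records:
        raise ValueError("empty record list")
    pd_ = np.asarray([r.pd for r in records])
    pe = np.asarray([r.pe for r in records])
    pe1 = np.asarray([r.pe1 for r in records])
    pe2 = np.asarray([r.pe2 for r in records])
    pid = np.asarray([r.pid for r in records])
    return PanelSummary(
        cpd=float(1 - np.prod(1 - pd_)),
        cpe=float(1 - np.prod(1 - pe)),
        cpe1=float(1 - np.prod(1 - pe1)),
        cpe2=float(1 - np.prod(1 - pe2)),
        cpid=float(np.prod(pid)),
        mean_ho=float(np.mean([r.ho for r in records])),
        mean_he=float(np.mean([r.he for r in records])),
        mean_pic=float(np.mean([r.pic for r in records])),
        n_loci=len(records),
    )


def cumulative_from_values(values: np.ndarray | list[float], kind: str = "power") -> float:
    """Cumulative panel value from bare per-locus numbers.

    ``kind='power'`` -> ``1 - prod(1 - v)``; ``kind='identity'`` -> ``prod v``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no per-locus values")
    if kind == "power":
        return float(1 - np.prod(1 - v))
    if kind == "identity":
        return float(np.prod(v))
    raise ValueError(f"unknown kind {kind!r}")
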