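"""Nei's DA genetic distance between populations.

DA (Nei, Tajima & Tateno) between populations with allele frequencies x and y:

    DA = 1 - (1/L) * sum_loci sum_alleles sqrt(x_a * y_a)

with L the number of loci scored in both populations.  Identical frequency
distributions give 0; fully disjoint allele sets at every locus give 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diversity import POOLED, AlleleFrequencyTable


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def max_pair(self) -> tuple[str, str, float]:
        """Most differentiated pair (row label, column label, DA)."""
        masked = np.triu(self.values, k=1)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        return self.labels[i], self.labels[j], float(self.values[i, j])


def nei_da(freqs: AlleleFrequencyTable, pop_a: str, pop_b: str) -> float:
    """DA distance between two populations; loci missing in either are dropped."""
    shared_sum = 0.0
    n_loci = 0
    for locus in freqs.loci:
        cells = freqs.freqs.get(locus, {})
        if pop_a not in cells or pop_b not in cells:
            continue
        x, y = cells[pop_a], cells[pop_b]
        shared_sum += sum(
            np.sqrt(x[a] * y[a]) for a in set(x) & set(y)
        )
        n_loci += 1
    if n_loci == 0:
        raise ValueError(f"populations {pop_a!r} and {pop_b!r} share no scored loci")
    return 1.0 - shared_sum / n_loci


def distance_matrix(freqs: AlleleFrequencyTable) -> DistanceMatrix:
    """All pairwise DA distances (symmetric, zero diagonal)."""
    labels = [p for p in freqs.populations if p != POOLED]
    if len(labels) < 2:
        raise ValueError("need >=2 populations for a distance matrix")
    k = len(labels)
    values = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = nei_da(freqs, labels[i], labels[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)
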