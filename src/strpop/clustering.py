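"""Bayesian admixture clustering (Gibbs sampler) and the Evanno delta-K rule.

The model is the classic admixture mixture model for unlinked codominant
loci: each of K clusters carries its own allele-frequency profile P_k,l with a
symmetric Dirichlet(lambda) prior; each individual i has admixture
proportions q_i ~ Dirichlet(alpha); every observed allele copy carries a
latent cluster-of-origin z.  A Gibbs sweep updates

* z for every allele copy, with P(z = k) proportional to q_ik * P_k,l,a;
* P from its Dirichlet posterior given the copies assigned to each cluster;
* q from its Dirichlet posterior given each individual's assignment counts;
* alpha by a Metropolis random walk with a uniform prior on (0, alpha_max].

The model evidence per K is estimated from the post-burn-in trace of
ln P(X | P, Q) as mean - variance/2, and replicate evidences across a ladder
of K values feed the Evanno curvature statistic
Delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeTable


@dataclass
class ClusterResult:
    """Posterior summary of one admixture run."""

    k: int
    individuals: list[str]
    populations: list[str]
    q: np.ndarray                 # (n_individuals, K) posterior-mean admixture
    p: np.ndarray                 # (K, n_loci, max_alleles) posterior-mean freqs
    allele_codes: list[np.ndarray]  # per locus, codes behind the allele axis
    lnl_trace: np.ndarray         # post-burn-in ln P(X | P, Q) samples
    lnpd: float                   # evidence estimate mean - var/2
    alpha: float                  # posterior-mean Dirichlet admixture parameter
    seed: int


@dataclass
class DeltaKRow:
    k: int
    n_replicates: int
    mean_lnpd: float
    sd_lnpd: float
    l_prime: float      # L(K) - L(K-1); NaN at the ladder edge
    l_second_abs: float  # |L(K+1) - 2 L(K) + L(K-1)|; NaN at edges
    delta_k: float       # l_second_abs / sd; NaN at edges, inf when sd == 0


@dataclass
class DeltaKTable:
    rows: list[DeltaKRow]

    def best_k(self) -> int:
        """Interior K with the largest finite-or-infinite Delta K."""
        interior = [r for r in self.rows if not math.isnan(r.delta_k)]
        if not interior:
            raise ValueError("no interior K values; need >=3 consecutive K")
        return max(interior, key=lambda r: r.delta_k).k


def _copies(table: GenotypeTable, exclude_x_linked: bool = False):
    """Flatten observed allele copies to (ind_idx, locus_idx, allele_idx)."""
    loci_keep = [
        l for l, m in enumerate(table.loci) if not (exclude_x_linked and m.x_linked)
    ]
    allele_codes: list[np.ndarray] = []
    ind_idx: list[int] = []
    loc_idx: list[int] = []
    all_idx: list[int] = []
    for new_l, l in enumerate(loci_keep):
        col = table.calls[:, l, :]
        codes = np.unique(col[col != MISSING])
        allele_codes.append(codes)
        lookup = {c: i for i, c in enumerate(codes)}
        for i in range(table.n_individuals):
            for copy in range(2):
                code = int(col[i, copy])
                if code != MISSING:
                    ind_idx.append(i)
                    loc_idx.append(new_l)
                    all_idx.append(lookup[code])
    return (
        np.asarray(ind_idx, dtype=np.int64),
        np.asarray(loc_idx, dtype=np.int64),
        np.asarray(all_idx, dtype=np.int64),
        allele_codes,
    )


def run_admixture(
    table: GenotypeTable,
    k: int,
    burnin: int = 5_000,
    iters: int = 20_000,
    seed: int = 0,
    lambda_p: float = 1.0,
    alpha_init: float = 1.0,
    alpha_sd: float = 0.025,
    alpha_max: float = 10.0,
    update_alpha: bool = True,
    admixture: bool = True,
    exclude_x_linked: bool = False,
) -> ClusterResult:
    """Run the Gibbs sampler for a fixed number of clusters.

    ``iters`` counts total sweeps including ``burnin``; the trace and the
    posterior means are accumulated over the ``iters - burnin`` final sweeps.
    ``admixture=False`` fits the no-admixture variant (one origin per
    individual, drawn from its posterior over clusters).
    Deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > table.n_individuals:
        raise ValueError(
            f"k={k} exceeds the number of individuals ({table.n_individuals})"
        )
    if iters <= burnin or burnin < 0:
        raise ValueError("need iters > burnin >= 0")

    rng = np.random.default_rng(seed)
    ind_idx, loc_idx, all_idx, allele_codes = _copies(table, exclude_x_linked)
    n = table.n_individuals
    n_loci = len(allele_codes)
    n_alleles = np.asarray([c.size for c in allele_codes])
    max_a = int(n_alleles.max())
    n_copies = ind_idx.size

    # Dirichlet shape template: lambda on real alleles, 0 on padding slots
    shape_mask = np.zeros((n_loci, max_a))
    for l, na in enumerate(n_alleles):
        shape_mask[l, :na] = 1.0

    q = np.full((n, k), 1.0 / k)
    p = np.tile((shape_mask / shape_mask.sum(axis=1, keepdims=True))[None], (k, 1, 1))
    alpha = alpha_init

    q_accum = np.zeros_like(q)
    p_accum = np.zeros_like(p)
    trace: list[float] = []
    alpha_accum = 0.0
    n_samples = 0

    for sweep in range(iters):
        # latent origins
        w = q[ind_idx] * p[:, loc_idx, all_idx].T          # (n_copies, k)
        w_sum = w.sum(axis=1, keepdims=True)
        w_sum[w_sum == 0] = 1.0
        cum = np.cumsum(w / w_sum, axis=1)
        u = rng.random((n_copies, 1))
        z = (u > cum[:, :-1]).sum(axis=1) if k > 1 else np.zeros(n_copies, dtype=np.int64)

        # cluster allele frequencies
        counts_p = np.zeros((k, n_loci, max_a))
        np.add.at(counts_p, (z, loc_idx, all_idx), 1.0)
        gam = rng.standard_gamma(counts_p + lambda_p * shape_mask[None])
        gam *= shape_mask[None]
        p = gam / np.maximum(gam.sum(axis=2, keepdims=True), 1e-300)

        # admixture proportions
        counts_q = np.zeros((n, k))
        np.add.at(counts_q, (ind_idx, z), 1.0)
        if admixture:
            gam_q = rng.standard_gamma(counts_q + alpha)
            q = gam_q / np.maximum(gam_q.sum(axis=1, keepdims=True), 1e-300)
        else:
            logw = np.log(np.maximum(counts_q, 0) + 1e-3)  # flat-ish prior over origins
            logw -= logw.max(axis=1, keepdims=True)
            wq = np.exp(logw)
            wq /= wq.sum(axis=1, keepdims=True)
            picks = (rng.random((n, 1)) > np.cumsum(wq, axis=1)[:, :-1]).sum(axis=1)
            q = np.zeros((n, k))
            q[np.arange(n), picks] = 1.0

        # Metropolis step on alpha
        if admixture and update_alpha and k > 1:
            prop = alpha + rng.normal(0.0, alpha_sd)
            if 0.0 < prop <= alpha_max:
                log_q = np.log(np.maximum(q, 1e-300)).sum()
                def _log_dir(a: float) -> float:
                    return n * (gammaln(k * a) - k * gammaln(a)) + (a - 1.0) * log_q
                if math.log(rng.random()) < _log_dir(prop) - _log_dir(alpha):
                    alpha = prop

        if sweep >= burnin:
            like = (q[ind_idx] * p[:, loc_idx, all_idx].T).sum(axis=1)
            trace.append(float(np.log(np.maximum(like, 1e-300)).sum()))
            q_accum += q
            p_accum += p
            alpha_accum += alpha
            n_samples += 1

    lnl = np.asarray(trace)
    lnpd = float(lnl.mean() - (lnl.var(ddof=1) / 2 if lnl.size > 1 else 0.0))
    return ClusterResult(
        k=k,
        individuals=list(table.individuals),
        populations=list(table.populations),
        q=q_accum / n_samples,
        p=p_accum / n_samples,
        allele_codes=allele_codes,
        lnl_trace=lnl,
        lnpd=lnpd,
        alpha=alpha_accum / n_samples,
        seed=seed,
    )


def align_labels(results: list[ClusterResult]) -> list[ClusterResult]:
    """Resolve label switching across replicate runs of the same K.

    Each replicate's cluster columns are permuted to maximise the summed
    correlation with the first replicate's Q matrix (optimal assignment, which
    for K! small coincides with the exhaustive best permutation).
    """
    if not results:
        return []
    ref = results[0]
    for r in results[1:]:
        if r.k != ref.k or r.individuals != ref.individuals:
            raise ValueError("replicates must share K and the individual set")
    aligned = [ref]
    ref_q = ref.q - ref.q.mean(axis=0, keepdims=True)
    for r in results[1:]:
        rq = r.q - r.q.mean(axis=0, keepdims=True)
        score = ref_q.T @ rq        # (K_ref, K_rep) cross-covariances
        row, col = linear_sum_assignment(-score)
        perm = np.empty(r.k, dtype=np.int64)
        perm[row] = col
        aligned.append(
            ClusterResult(
                k=r.k,
                individuals=r.individuals,
                populations=r.populations,
                q=r.q[:, perm],
                p=r.p[perm],
                allele_codes=r.allele_codes,
                lnl_trace=r.lnl_trace,
                lnpd=r.lnpd,
                alpha=r.alpha,
                seed=r.seed,
            )
        )
    return aligned


def evanno_delta_k(lnpd_replicates: dict[int, list[float]]) -> DeltaKTable:
    """Evanno curvature statistic over a ladder of K values.

    Requires >=3 consecutive K values with >=2 replicates each (for the
    standard deviation).  A zero replicate s.d. at an interior K yields an
    infinite Delta K, flagged rather than dropped.
    """
    ks = sorted(lnpd_replicates)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >=3 consecutive K values")
    for k_val in ks:
        if len(lnpd_replicates[k_val]) < 2:
            raise ValueError(f"K={k_val}: need >=2 replicates for an s.d.")
    mean_l = {k_val: float(np.mean(lnpd_replicates[k_val])) for k_val in ks}
    sd_l = {k_val: float(np.std(lnpd_replicates[k_val], ddof=1)) for k_val in ks}
    rows: list[DeltaKRow] = []
    for k_val in ks:
        l_prime = mean_l[k_val] - mean_l[k_val - 1] if k_val - 1 in mean_l else math.nan
        if k_val - 1 in mean_l and k_val + 1 in mean_l:
            l_second = abs(mean_l[k_val + 1] - 2 * mean_l[k_val] + mean_l[k_val - 1])
            delta = l_second / sd_l[k_val] if sd_l[k_val] > 0 else math.inf
        else:
            l_second = math.nan
            delta = math.nan
        rows.append(
            DeltaKRow(
                k=k_val,
                n_replicates=len(lnpd_replicates[k_val]),
                mean_lnpd=mean_l[k_val],
                sd_lnpd=sd_l[k_val],
                l_prime=l_prime,
                l_second_abs=l_second,
                delta_k=delta,
            )
        )
    return DeltaKTable(rows=rows)


def k_ladder(
    table: GenotypeTable,
    k_min: int = 1,
    k_max: int = 8,
    replicates: int = 5,
    burnin: int = 5_000,
    iters: int = 20_000,
    seed: int = 0,
    **kwargs,
) -> tuple[dict[int, list[ClusterResult]], DeltaKTable]:
    """Run replicate chains over K = k_min..k_max and compute Delta K.

    Replicate r of K uses seed ``seed + 1000*K + r`` so chains are independent
    but the whole ladder is reproducible from one seed.
    """
    results: dict[int, list[ClusterResult]] = {}
    for k_val in range(k_min, k_max + 1):
        runs = [
            run_admixture(
                table, k_val, burnin=burnin, iters=iters,
                seed=seed + 1000 * k_val + r, **kwargs,
            )
            for r in range(replicates)
        ]
        results[k_val] = align_labels(runs)
    table_dk = evanno_delta_k(
        {k_val: [r.lnpd for r in runs] for k_val, runs in results.items()}
    )
    return results, table_dk
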