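"""Numba kernel for the forward Wright-Fisher coding-locus simulation.

Each segregating mutation is tracked as a biallelic derived-allele count in a
diploid population of size N (2N haploid copies). Per generation the count is
updated by genic selection, p' = p(1+s) / (1+ps), followed by binomial
sampling of 2N copies. New mutations enter as single copies at a Poisson rate
mu * L_class * 2N per mutation class. Mutations are treated as freely
recombining (no interference), so each trajectory is independent given N(t).

Population size follows a piecewise-constant schedule; on a size change the
standing counts are binomially resampled to the new 2N. Fixations are
recorded per class, counting only those occurring at or after `burn_in`
generations.
"""

import numpy as np
from numba import njit

_CAP = 1 << 17  # max simultaneously segregating mutations


@njit(cache=True)
def _wf_kernel(seed, burn_in, epoch_len, epoch_n, rates, s_arr):
    np.random.seed(seed)
    n_class = rates.shape[0]
    counts = np.zeros(_CAP, dtype=np.int64)
    klass = np.zeros(_CAP, dtype=np.int64)
    m = 0
    fixed = np.zeros(n_class, dtype=np.int64)
    overflow = 0

    total = 0
    for e in range(epoch_len.shape[0]):
        total += epoch_len[e]

    ei = 0
    gens_in_epoch = 0
    n_dip = epoch_n[0]
    for gen in range(total):
        if gens_in_epoch >= epoch_len[ei] and ei + 1 < epoch_len.shape[0]:
            ei += 1
            gens_in_epoch = 0
            new_n = epoch_n[ei]
            if new_n != n_dip:
                two_new = 2 * new_n
                j = 0
                for i in range(m):
                    p = counts[i] / (2.0 * n_dip)
                    c = np.random.binomial(two_new, p)
                    if c == two_new:
                        if gen >= burn_in:
                            fixed[klass[i]] += 1
                    elif c > 0:
                        counts[j] = c
                        klass[j] = klass[i]
                        j += 1
                m = j
                n_dip = new_n
        gens_in_epoch += 1
        two_n = 2 * n_dip

        j = 0
        for i in range(m):
            p = counts[i] / two_n
            s = s_arr[klass[i]]
            p2 = p * (1.0 + s) / (1.0 + p * s)
            c = np.random.binomial(two_n, p2)
            if c == 0:
                continue
            if c == two_n:
                if gen >= burn_in:
                    fixed[klass[i]] += 1
                continue
            counts[j] = c
            klass[j] = klass[i]
            j += 1
        m = j

        for k in range(n_class):
            lam = rates[k] * two_n
            if lam <= 0.0:
                continue
            n_new = np.random.poisson(lam)
            for _ in range(n_new):
                if m < _CAP:
                    counts[m] = 1
                    klass[m] = k
                    m += 1
                else:
                    overflow += 1

    return fixed, counts[:m].copy(), klass[:m].copy(), n_dip, overflow
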