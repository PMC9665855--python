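"""Independent reference implementations used by the test suite.

Everything here is deliberately naive — plain Python loops and exhaustive
enumeration — so it shares no code path with the package implementation it
checks.
"""

import math
from itertools import product

import numpy as np


def brute_prefix_order(X, m):
    """Stable sort of haplotypes by reversed prefix ending before site m."""
    keys = [tuple(X[h, :m][::-1]) for h in range(X.shape[0])]
    return sorted(range(X.shape[0]), key=lambda h: keys[h])


def brute_set_maximal(X, q):
    """Definition-based O(N*M^2) oracle for set-maximal matches."""
    n, m_sites = X.shape
    segs = []
    for h in range(n):
        for s in range(m_sites):
            for e in range(s + 1, m_sites + 1):
                agrees = all(q[t] < 0 or X[h, t] == q[t] for t in range(s, e))
                if not agrees:
                    continue
                left_ext = s > 0 and (q[s - 1] < 0 or X[h, s - 1] == q[s - 1])
                right_ext = e < m_sites and (q[e] < 0 or X[h, e] == q[e])
                if left_ext or right_ext:
                    continue  # extensible: not maximal for this haplotype
                segs.append((s, e, h))
    return sorted(
        (s, e, h)
        for s, e, h in segs
        if not any(
            s2 <= s and e2 >= e and (s2 < s or e2 > e) for s2, e2, _h2 in segs
        )
    )


def enumerate_diplotypes(X, g, params):
    """Exhaustive diplotype enumeration under the beam's probability model.

    Walks every het orientation vector through the conditional-copying
    model with explicit carrier sets (no PBWT) and log-space accumulation
    via math.fsum.  Returns ({orientation bits: log probability}, het
    site list).  Genotypes must not contain missing values.
    """
    n, m_sites = X.shape
    het = [m for m in range(m_sites) if g[m] == 1]
    log_restart = math.log(params.recomb_penalty) + math.log(params.mismatch_penalty)

    results = {}
    for bits in product((0, 1), repeat=len(het)):
        hap_a = np.empty(m_sites, dtype=int)
        hap_b = np.empty(m_sites, dtype=int)
        for m in range(m_sites):
            if g[m] == 1:
                b = bits[het.index(m)]
                hap_a[m], hap_b[m] = b, 1 - b
            else:
                hap_a[m] = hap_b[m] = g[m] // 2
        logs = []
        for hap in (hap_a, hap_b):
            carriers = list(range(n))
            for m in range(m_sites):
                col = X[:, m]
                if col.min() == col.max():  # monomorphic: forced, free
                    carriers = [h for h in carriers if X[h, m] == col[0]]
                    continue
                nxt = [h for h in carriers if X[h, m] == hap[m]]
                if nxt:
                    carriers = nxt
                else:  # restart from every carrier of the required allele
                    logs.append(log_restart)
                    carriers = [h for h in range(n) if X[h, m] == hap[m]]
        results[bits] = math.fsum(logs)
    return results, het
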