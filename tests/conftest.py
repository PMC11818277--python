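import numpy as np
import pytest

from qvburden.synthetic_data import PlantedSet, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    cfg = SimConfig(seed=20240901, n_samples=40, n_background_genes=40,
                    mean_variants_per_gene=6.0)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept free of the package's code paths)
# ---------------------------------------------------------------------------

def enumerate_fisher_p(a, b, c, d):
    """Two-sided Fisher p by explicit enumeration of same-margin tables."""
    import math

    r1, c1, n = a + b, a + c, a + b + c + d

    def table_prob(x):
        return (math.comb(r1, x) * math.comb(n - r1, c1 - x)
                / math.comb(n, c1))

    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    p_obs = table_prob(a)
    return sum(table_prob(x) for x in range(lo, hi + 1)
               if table_prob(x) <= p_obs * (1 + 1e-12))


def enumerate_mwu_p(x, y):
    """Two-sided exact MWU p (tail doubling) over all group labelings."""
    import itertools

    import numpy as np

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_of(idx):
        sel = np.zeros(len(pooled), bool)
        sel[list(idx)] = True
        a, bb = pooled[sel], pooled[~sel]
        return ((a[:, None] > bb[None, :]).sum()
                + 0.5 * (a[:, None] == bb[None, :]).sum())

    u_obs = u_of(range(n1))
    lo = hi = tot = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = u_of(comb)
        lo += u <= u_obs
        hi += u >= u_obs
        tot += 1
    return min(1.0, 2.0 * min(lo, hi) / tot)


def enumerate_cmh_exact_p(tables):
    """Two-sided exact CMH p by brute force over all a-cell vectors."""
    import itertools
    import math

    def hyper_pmf(x, n, r1, c1):
        return (math.comb(r1, x) * math.comb(n - r1, c1 - x)
                / math.comb(n, c1))

    supports, pmfs = [], []
    s_obs = 0
    for (a, b, c, d) in tables:
        n, r1, c1 = a + b + c + d, a + b, a + c
        lo, hi = max(0, r1 + c1 - n), min(r1, c1)
        xs = list(range(lo, hi + 1))
        supports.append(xs)
        pmfs.append({x: hyper_pmf(x, n, r1, c1) for x in xs})
        s_obs += a
    p_le = p_ge = 0.0
    for combo in itertools.product(*supports):
        prob = 1.0
        for k, x in enumerate(combo):
            prob *= pmfs[k][x]
        s = sum(combo)
        if s <= s_obs:
            p_le += prob
        if s >= s_obs:
            p_ge += prob
    return min(1.0, 2.0 * min(p_le, p_ge))
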