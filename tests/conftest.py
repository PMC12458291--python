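import numpy as np
import pytest

import divergescan as ds


def anova_wc_diploid(calls_a, calls_b):
    """Independent Weir–Cockerham oracle: nested allele-indicator ANOVA
    (mean squares within individuals, among individuals, among
    populations), a different algebraic route than the package's
    closed-form components."""
    pops = []
    for arr in (calls_a, calls_b):
        arr = np.asarray(arr)
        ok = np.all(arr >= 0, axis=1)
        pops.append(arr[ok].astype(float))
    r = 2
    n = [len(p) for p in pops]
    if min(n) == 0 or sum(n) / 2 <= 1:
        return (np.nan,) * 3
    N = sum(n)
    ind_means = [p.mean(axis=1) for p in pops]
    pop_means = [p.mean() for p in pops]
    grand = sum(p.sum() for p in pops) / (2 * N)
    ss_g = sum(((p - m[:, None]) ** 2).sum()
               for p, m in zip(pops, ind_means))
    ss_i = sum(2 * ((m - pm) ** 2).sum()
               for m, pm in zip(ind_means, pop_means))
    ss_p = sum(2 * ni * (pm - grand) ** 2
               for ni, pm in zip(n, pop_means))
    msg = ss_g / N
    msi = ss_i / (N - r)
    msp = ss_p / (r - 1)
    nc = (N - sum(ni ** 2 for ni in n) / N) / (r - 1)
    return (msp - msi) / (2 * nc), (msi - msg) / 2, msg


def brute_force_pi(calls):
    """π numerator/denominator by explicit enumeration of allele pairs."""
    alleles = [int(a) for a in np.asarray(calls).ravel() if a >= 0]
    diff = comp = 0
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            comp += 1
            diff += alleles[i] != alleles[j]
    return diff, comp


def brute_force_dxy(calls_a, calls_b):
    """dXY numerator/denominator by explicit cross-pair enumeration."""
    a = [int(x) for x in np.asarray(calls_a).ravel() if x >= 0]
    b = [int(x) for x in np.asarray(calls_b).ravel() if x >= 0]
    diff = sum(x != y for x in a for y in b)
    return diff, len(a) * len(b)


@pytest.fixture(scope="session")
def two_pop_sim():
    """20+20 diploids, F = 0.1, all-sites matrix with invariant records."""
    params = ds.SimulationParams(n_pops=2, n_diploids_per_pop=20,
                                 n_sites=4000, seq_length=400_000,
                                 divergence_F=0.1, prop_variant=0.5,
                                 seed=11)
    gm, truth = ds.simulate_split_populations(params)
    return gm, truth


@pytest.fixture(scope="session")
def three_pop_scan():
    """Focal-drift design: pop1 at F = 0.2, pop2/pop3 at F = 0.02,
    500 windows of 50 kb."""
    params = ds.SimulationParams(n_pops=3, n_diploids_per_pop=15,
                                 n_sites=25_000, seq_length=25_000_000,
                                 divergence_F=(0.2, 0.02, 0.02),
                                 prop_variant=1.0, seed=21)
    gm, truth = ds.simulate_split_populations(params)
    return gm, truth
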