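"""Individual-based Wright-Fisher simulator used to cross-validate the
deterministic engine.

``N`` diploid individuals reproduce in discrete generations: each offspring
draws two parents with probability proportional to fitness (viability
selection), receives one gamete from each parent sampled from that parent's
germline gamete distribution, and releases replace ``floor(rho * N)``
random individuals with engineered homozygotes.

Conditional on the realized population at generation ``g``, the allele
census one generation later is binomial around one deterministic step of
the genotype-frequency recursion applied to the realized genotype
distribution — the sharpest sense in which the two engines agree, and the
one :func:`conditional_step_deviations` measures. Over whole trajectories,
marginal deviations are *not* binomial: selection and homing amplify early
fluctuations multiplicatively during the spread phase. The additive
accumulation of :func:`drift_envelope` is exact only in the neutral limit
(no costs, no cutting), where the per-generation map has unit slope.
"""

from __future__ import annotations

import numpy as np

from .dynamics import GenotypeDistribution, Trajectory, next_generation
from .genetics import enumerate_haplotypes, gamete_distribution
from .scenarios import ScenarioConfig

__all__ = [
    "wright_fisher_oracle",
    "drift_envelope",
    "conditional_step_deviations",
]


def wright_fisher_oracle(
    config: ScenarioConfig,
    N: int,
    seed: int,
    generations: int | None = None,
    record_states: bool = False,
) -> Trajectory:
    """Stochastic finite-population counterpart of :func:`dynamics.simulate`.

    Only single-population configurations are supported. Returns a
    :class:`Trajectory` whose generation 0 is the post-release census,
    matching the deterministic engine's bookkeeping. Reproducible for a
    fixed ``seed``. With ``record_states`` the realized genotype
    distribution of every generation is attached as trajectory snapshots.
    """
    if config.n_populations != 1:
        raise ValueError("the individual-based oracle is single-population only")
    if N < 100:
        raise ValueError("population size must be at least 100")
    gens = config.generations if generations is None else generations
    rng = np.random.default_rng(seed)
    arch, fit, sched = config.architecture(), config.fitness(), config.schedule()
    n = arch.n
    haps = enumerate_haplotypes(n)
    M = len(haps)

    from .dynamics import fitness_tensor

    Wt = fitness_tensor(fit)
    gam_cache: dict[int, np.ndarray] = {}

    def gamete_rows(pair_codes: np.ndarray) -> dict[int, np.ndarray]:
        for code in np.unique(pair_codes):
            if code not in gam_cache:
                i, j = divmod(int(code), M)
                gam_cache[code] = gamete_distribution((haps[i], haps[j]), arch)
        return gam_cache

    # base-3 digit table for allele counting
    digits = np.array([[int(a) for a in h] for h in haps])  # (M, n)

    def census(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        out = np.empty((n, 3))
        for j in range(n):
            counts = np.bincount(digits[h1, j], minlength=3) + np.bincount(
                digits[h2, j], minlength=3
            )
            out[j] = counts / (2 * N)
        return out

    release_idx = sched.release_index(n)

    def inject(h1: np.ndarray, h2: np.ndarray, rho: float) -> None:
        k = int(np.floor(rho * N))
        if k > 0:
            who = rng.choice(N, size=k, replace=False)
            h1[who] = release_idx
            h2[who] = release_idx

    def state(h1: np.ndarray, h2: np.ndarray) -> GenotypeDistribution:
        F = np.zeros((M, M))
        np.add.at(F, (h1, h2), 1.0 / N)
        return GenotypeDistribution(n, (F + F.T) / 2.0)

    h1 = np.zeros(N, dtype=np.int64)  # all-wild haplotype has index 0
    h2 = np.zeros(N, dtype=np.int64)
    inject(h1, h2, sched.initial_fraction)

    freqs = [census(h1, h2)]
    wbar = [float(Wt[h1, h2].mean())]
    snaps = [(0, state(h1, h2))] if record_states else []
    extinct = False
    for _ in range(gens):
        w = Wt[h1, h2]
        total = w.sum()
        if total <= 0.0:
            extinct = True
            break
        p = w / total
        parents = rng.choice(N, size=2 * N, p=p)
        pair_codes = h1[parents] * M + h2[parents]
        rows = gamete_rows(pair_codes)
        gametes = np.empty(2 * N, dtype=np.int64)
        order = np.argsort(pair_codes, kind="stable")
        sorted_codes = pair_codes[order]
        start = 0
        for code, count in zip(*np.unique(sorted_codes, return_counts=True)):
            sel = order[start : start + count]
            gametes[sel] = rng.choice(M, size=count, p=rows[int(code)])
            start += count
        h1, h2 = gametes[:N].copy(), gametes[N:].copy()
        inject(h1, h2, sched.continuous_fraction)
        freqs.append(census(h1, h2))
        wbar.append(float(Wt[h1, h2].mean()))
        if record_states:
            snaps.append((len(freqs) - 1, state(h1, h2)))
    return Trajectory(
        n=n,
        allele_freqs=np.array(freqs),
        mean_fitness=np.array(wbar),
        extinct=extinct,
        snapshots=snaps,
    )


def conditional_step_deviations(
    traj: Trajectory, config: ScenarioConfig, N: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-generation deviations from the one-step deterministic prediction.

    For each recorded generation ``g`` (requires a trajectory produced with
    ``record_states=True``), applies one generation of the deterministic
    recursion to the *realized* genotype distribution and compares the next
    stochastic census to it. Conditional on generation ``g``, each of the
    ``2N`` transmitted allele copies is an independent draw from the
    predicted pool, so the deviations are binomial with standard error
    ``sqrt(p (1 - p) / (2N))``.

    Returns ``(deviations, standard_errors)``, each of shape
    ``(generations, n, 3)``; standard errors are floored at one allele copy.
    """
    if not traj.snapshots:
        raise ValueError("trajectory was not run with record_states=True")
    arch, fit, sched = config.architecture(), config.fitness(), config.schedule()
    devs, ses = [], []
    for (g, dist), (g_next, _) in zip(traj.snapshots, traj.snapshots[1:]):
        if g_next != g + 1:  # truncated by extinction
            break
        pred = next_generation(dist, arch, fit, sched).allele_frequencies()
        obs = traj.allele_freqs[g + 1]
        devs.append(obs - pred)
        ses.append(np.maximum(np.sqrt(pred * (1.0 - pred) / (2 * N)), 1.0 / (2 * N)))
    return np.array(devs), np.array(ses)


def drift_envelope(det_freqs: np.ndarray, N: int, z: float = 5.0) -> np.ndarray:
    """Neutral-drift band around a deterministic trajectory.

    Under neutral Mendelian inheritance drift accumulates additively: at
    generation ``g`` the variance of an allele frequency around its
    deterministic trajectory is the sum over generations ``t <= g`` of the
    binomial sampling variances ``p_t (1 - p_t) / (2N)``. Returns ``z``
    times the accumulated standard error per generation, with a one-copy
    floor of ``1 / (2N)`` so the band is never zero. With selection or
    homing the per-generation map can amplify fluctuations and this band
    understates the marginal variance — use
    :func:`conditional_step_deviations` there instead.

    Parameters
    ----------
    det_freqs : array
        Deterministic frequency trajectory, generation 0 first.
    N : int
        Diploid population size of the stochastic simulation.
    z : float
        Width of the band in standard errors.
    """
    p = np.asarray(det_freqs, dtype=float)
    var_step = p * (1.0 - p) / (2 * N)
    acc = np.cumsum(var_step)
    return np.maximum(z * np.sqrt(acc), 1.0 / (2 * N))
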