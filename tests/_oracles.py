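"""Independent oracles for the imputation and cross math.

These deliberately avoid the package's distribution classes and helper
functions: states are plain dict keys canonicalized with ``tuple(sorted())``
and every probability is accumulated by exhaustive enumeration of the
generative story (marker mixture -> unphased diplotype -> phasing ->
founder genotype per haplotype slot -> transmitted copy per slot), or by
literally sampling that story.
"""

from __future__ import annotations

import numpy as np


def _key(a, b):
    return tuple(sorted((a, b)))


def enumerate_genotype(
    left_probs: dict,
    right_probs: dict,
    wl: float,
    wr: float,
    founder_gts: dict,
    mode: str = "proximal",
) -> dict:
    """Exhaustive enumeration of the unphased genotype distribution.

    ``left_probs``/``right_probs``: {(h1, h2) sorted: prob} marker diplotypes.
    ``founder_gts``: {founder: {(a1, a2) sorted: prob}}.
    """
    if wl + wr == 0:
        marker_mix = [(left_probs, 1.0)]
    else:
        if mode == "proximal":
            a_left = wr / (wl + wr)
        else:
            a_left = wl / (wl + wr)
        marker_mix = [(left_probs, a_left), (right_probs, 1.0 - a_left)]

    out: dict = {}
    for dip_probs, w_m in marker_mix:
        if w_m == 0.0:
            continue
        for (h1, h2), p_dip in dip_probs.items():
            if h1 == h2:
                phasings = [((h1, h2), 1.0)]
            else:
                phasings = [((h1, h2), 0.5), ((h2, h1), 0.5)]
            for (x, y), p_phase in phasings:
                for (g1a, g1b), p_g1 in founder_gts[x].items():
                    for (g2a, g2b), p_g2 in founder_gts[y].items():
                        base = w_m * p_dip * p_phase * p_g1 * p_g2
                        if base == 0.0:
                            continue
                        for a in (g1a, g1b):
                            for b in (g2a, g2b):
                                k = _key(a, b)
                                out[k] = out.get(k, 0.0) + base * 0.25
    return out


def sample_genotype(
    left_probs: dict,
    right_probs: dict,
    wl: float,
    wr: float,
    founder_gts: dict,
    n_draws: int,
    rng: np.random.Generator,
    mode: str = "proximal",
) -> dict:
    """Forward Monte-Carlo sampler of the same generative story.

    Samples the phased diplotype (marker, state, phasing jointly), then for
    each haplotype slot independently samples a founder genotype and a
    transmitted copy.  Returns empirical frequencies.
    """
    if wl + wr == 0:
        a_left = 1.0
    elif mode == "proximal":
        a_left = wr / (wl + wr)
    else:
        a_left = wl / (wl + wr)

    phased: list[tuple[str, str]] = []
    weights: list[float] = []
    for dip_probs, w_m in ((left_probs, a_left), (right_probs, 1.0 - a_left)):
        if w_m == 0.0:
            continue
        for (h1, h2), p in dip_probs.items():
            if h1 == h2:
                phased.append((h1, h2))
                weights.append(w_m * p)
            else:
                phased.append((h1, h2))
                weights.append(w_m * p / 2.0)
                phased.append((h2, h1))
                weights.append(w_m * p / 2.0)
    weights_arr = np.asarray(weights)
    weights_arr = weights_arr / weights_arr.sum()
    counts = rng.multinomial(n_draws, weights_arr)

    tallies: dict = {}
    for (x, y), n in zip(phased, counts):
        if n == 0:
            continue
        allele_a = _sample_transmitted(founder_gts[x], n, rng)
        allele_b = _sample_transmitted(founder_gts[y], n, rng)
        for a, b in zip(allele_a, allele_b):
            k = _key(a, b)
            tallies[k] = tallies.get(k, 0.0) + 1.0
    return {k: v / n_draws for k, v in tallies.items()}


def _sample_transmitted(gt_probs: dict, n: int, rng: np.random.Generator):
    states = list(gt_probs)
    probs = np.asarray([gt_probs[s] for s in states])
    probs = probs / probs.sum()
    gt_idx = rng.choice(len(states), size=n, p=probs)
    copy = rng.integers(0, 2, size=n)
    return [states[i][c] for i, c in zip(gt_idx, copy)]


def enumerate_f1_genotype(parent1: dict, parent2: dict) -> dict:
    """Exhaustive F1 genotype oracle from two parent genotype dicts."""
    out: dict = {}
    for (p1a, p1b), q1 in parent1.items():
        for (p2a, p2b), q2 in parent2.items():
            base = q1 * q2
            for a in (p1a, p1b):
                for b in (p2a, p2b):
                    k = _key(a, b)
                    out[k] = out.get(k, 0.0) + base * 0.25
    return out


def sample_f1_genotype(
    parent1: dict, parent2: dict, n_draws: int, rng: np.random.Generator
) -> dict:
    """Gamete-sampling simulation of an F1 cross."""
    a1 = _sample_from_genotype_dist(parent1, n_draws, rng)
    a2 = _sample_from_genotype_dist(parent2, n_draws, rng)
    tallies: dict = {}
    for a, b in zip(a1, a2):
        k = _key(a, b)
        tallies[k] = tallies.get(k, 0.0) + 1.0
    return {k: v / n_draws for k, v in tallies.items()}


def _sample_from_genotype_dist(gt_probs: dict, n: int, rng: np.random.Generator):
    return _sample_transmitted(gt_probs, n, rng)


def random_instance(rng: np.random.Generator, max_founders: int = 8, max_alleles: int = 4):
    """Random small imputation instance (marker dists, weights, founder gts)."""
    n_founders = int(rng.integers(2, max_founders + 1))
    founders = [f"F{i}" for i in range(n_founders)]
    n_alleles = int(rng.integers(2, max_alleles + 1))
    alleles = ["A", "C", "G", "T", "AT", "ATT"][:n_alleles]

    def random_dip():
        pairs = [
            _key(founders[i], founders[j])
            for i in range(n_founders)
            for j in range(i, n_founders)
        ]
        n_states = int(rng.integers(1, min(6, len(pairs)) + 1))
        idx = rng.choice(len(pairs), size=n_states, replace=False)
        raw = rng.dirichlet(np.ones(n_states))
        return {pairs[int(i)]: float(p) for i, p in zip(idx, raw)}

    def random_gt():
        pairs = [
            _key(alleles[i], alleles[j])
            for i in range(n_alleles)
            for j in range(i, n_alleles)
        ]
        n_states = int(rng.integers(1, min(4, len(pairs)) + 1))
        idx = rng.choice(len(pairs), size=n_states, replace=False)
        raw = rng.dirichlet(np.ones(n_states))
        return {pairs[int(i)]: float(p) for i, p in zip(idx, raw)}

    left = random_dip()
    right = random_dip()
    wl = int(rng.integers(0, 5000))
    wr = int(rng.integers(0, 5000))
    if wl + wr == 0:
        right = dict(left)
    founder_gts = {f: random_gt() for f in founders}
    return {
        "founders": founders,
        "alleles": alleles,
        "left": left,
        "right": right,
        "wl": wl,
        "wr": wr,
        "founder_gts": founder_gts,
    }
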