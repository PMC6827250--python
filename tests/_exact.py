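"""Exact CTMC absorption oracle for small digestion problems.

Enumerates the full state space of a digesting pool and computes the
absorbing-state distribution from the embedded jump chain (branch
probabilities = rate / total rate), independently of the Gillespie sampler.
Feasible for substrates up to a few rings; used to validate the stochastic
simulator.
"""

from collections import Counter, defaultdict

from alginseq import GlycanChain, Monomer, endo_cleave, exo_step


def state_key(chains: Counter, monomers: Counter):
    return (
        tuple(sorted((str(c), n) for c, n in chains.items() if n > 0)),
        tuple(sorted((m.name, n) for m, n in monomers.items() if n > 0)),
    )


def _enumerate_events(chains, endo, exo, u1, u2):
    """(rate, kind, chain, bond) tuples; bond filter re-derived from scratch."""
    events = []
    for ch, c in sorted(chains.items()):
        if c <= 0:
            continue
        if endo is not None and u1 > 0:
            m = len(ch.residues)
            extra = 1 if ch.unsaturated else 0
            for i in range(1, m):
                up_rings = i + extra
                down_rings = m - i
                if up_rings < endo.min_nre_frag or down_rings < endo.min_re_frag:
                    continue
                k = endo.k(ch.residues[i - 1], ch.residues[i])
                if k > 0:
                    events.append((c * u1 * k, "endo", ch, i))
        if exo is not None and u2 > 0 and ch.dp >= 2:
            if not (ch.label == "2AB" and ch.dp == 2):
                r = exo.rate(ch.dp)
                if r > 0:
                    events.append((c * u2 * r, "exo", ch, None))
    return events


def exact_final_distribution(pool, *, endo=None, exo=None, endo_mU=0.0, exo_mU=0.0):
    """Map absorbing state key -> exact probability."""
    chains = Counter(pool)
    memo = {}

    def rec(chains, monomers):
        key = state_key(chains, monomers)
        if key in memo:
            return memo[key]
        events = _enumerate_events(chains, endo, exo, endo_mU, exo_mU)
        if not events:
            memo[key] = {key: 1.0}
            return memo[key]
        total = sum(r for r, *_ in events)
        out = defaultdict(float)
        for rate, kind, ch, bond in events:
            c2 = Counter(chains)
            m2 = Counter(monomers)
            c2[ch] -= 1
            if c2[ch] <= 0:
                del c2[ch]
            if kind == "endo":
                up, down = endo_cleave(ch, bond)
                c2[up] += 1
                c2[down] += 1
            else:
                released, remainder = exo_step(ch)
                m2[released] += 1
                if isinstance(remainder, Monomer):
                    m2[remainder] += 1
                else:
                    c2[remainder] += 1
            for fk, p in rec(c2, m2).items():
                out[fk] += (rate / total) * p
        memo[key] = dict(out)
        return memo[key]

    return rec(chains, Counter())
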