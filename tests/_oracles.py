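"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: the LP oracle
enumerates basic solutions combinatorially instead of calling a simplex
solver; the pathway oracle enumerates raw reaction sequences; the closure
oracle is a fixed-point loop over rule applications.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def vertex_enumeration_lp(N, lb, ub, c, tol=1e-9):
    """Maximize c'v s.t. N v = 0, lb <= v <= ub by basic-solution enumeration.

    For each choice of n-rank(N) variables pinned to a bound, solve the
    remaining square-ish system; feasible candidates are vertices.  Returns
    (best objective, best vertex) or (None, None) when infeasible.
    """
    N = np.atleast_2d(np.asarray(N, dtype=float))
    m, n = N.shape
    rank = np.linalg.matrix_rank(N) if N.size else 0
    n_fix = n - rank
    best_val, best_v = None, None
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for pattern in itertools.product(*([(lb[j], ub[j]) for j in fixed])):
            v = np.zeros(n)
            for j, val in zip(fixed, pattern):
                v[j] = val
            if free:
                A = N[:, free]
                b = -N[:, fixed] @ np.array(pattern)
                sol, residual, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            if np.max(np.abs(N @ v)) > 1e-7:
                continue
            if np.any(v < np.asarray(lb) - tol) or np.any(v > np.asarray(ub) + tol):
                continue
            val = float(np.dot(c, v))
            if best_val is None or val > best_val + tol:
                best_val, best_v = val, v.copy()
    return best_val, best_v


def brute_force_pathways(reactions, source, sinks, max_len, cofactors):
    """All simple source->sink reaction sequences by raw sequence enumeration.

    ``reactions``: mapping id -> stoich dict.  A sequence is valid when each
    reaction consumes the compound reached by its predecessor (through a
    non-cofactor species), no compound repeats, and the walk first reaches a
    sink at its last step.
    """
    ids = sorted(reactions)
    found = set()

    def products(rid):
        return sorted(s for s, c in reactions[rid].items() if c > 0 and s not in cofactors)

    def consumes(rid, compound):
        return reactions[rid].get(compound, 0) < 0

    def extend(chain, current, visited):
        if len(chain) >= max_len:
            return
        for rid in ids:
            if not consumes(rid, current):
                continue
            for nxt in products(rid):
                if nxt in visited:
                    continue
                if nxt in sinks:
                    found.add(chain + (rid,))
                else:
                    extend(chain + (rid,), nxt, visited | {nxt})

    extend(tuple(), source, {source})
    return found


def brute_force_closure(seed_smiles, rules, max_generations):
    """Fixed-point iteration over rule applications (compound set only)."""
    from xenoflux.rules import apply_rule, canonicalize_compound

    seen = {canonicalize_compound(s).id for s in seed_smiles}
    for _ in range(max_generations):
        new = set()
        for cid in sorted(seen):
            compound = canonicalize_compound(cid)
            for rule in rules:
                for rxn in apply_rule(rule, compound):
                    new.update(rxn.products())
        if new <= seen:
            break
        seen |= new
    return seen


def summation_overall(reaction_stoichs, tol=1e-9):
    """Independent overall-reaction composition: plain float summation."""
    total: dict[str, float] = {}
    for stoich in reaction_stoichs:
        for species, coeff in stoich.items():
            total[species] = total.get(species, 0.0) + coeff
    return {s: c for s, c in total.items() if not math.isclose(c, 0.0, abs_tol=tol)}
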