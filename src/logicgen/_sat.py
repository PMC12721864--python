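"""Logic-solving primitives.

Two solvers, both complete and seeded:

* :class:`TwoSat` — the generator's constraint problems are conjunctions of
  2-literal clauses (each clause forbids one pairwise allele pattern), i.e.
  pure 2-SAT.  Models are found by the classical implication-closure
  procedure: pick an unassigned literal, take the closure of its
  implications; if the closure is contradictory the negation's closure is
  forced.  For a satisfiable formula this never backtracks, and the random
  variable order / polarity under the caller's generator is what makes
  successive synthetic haplotypes diverse.

* :class:`SelectionSolver` — a DPLL search over row-selection variables for
  the reconstruction problem: arbitrary clauses (positive support clauses,
  negative blocking clauses, assumptions) plus a native exactly-M
  cardinality propagator over the selection variables.  Chronological
  backtracking is sufficient at audit scale and keeps the solver small and
  auditable.

Literals follow DIMACS convention: variable ``v`` in ``1..n`` appears as
``+v`` (true) or ``-v`` (false).
"""

from __future__ import annotations

import numpy as np

__all__ = ["TwoSat", "SelectionSolver"]


class TwoSat:
    """Complete randomized solver for 2-literal CNF."""

    def __init__(self, n_vars: int):
        self.n_vars = int(n_vars)
        # implications[lit] = list of literals implied by lit
        self._imp: dict[int, list[int]] = {}
        self.n_clauses = 0

    def add_clause(self, a: int, b: int) -> None:
        """Add clause (a OR b): records implications not-a -> b, not-b -> a."""
        self._imp.setdefault(-a, []).append(b)
        self._imp.setdefault(-b, []).append(a)
        self.n_clauses += 1

    def add_clauses(self, clauses) -> None:
        for a, b in clauses:
            self.add_clause(int(a), int(b))

    def _closure(self, lit: int, assign: np.ndarray):
        """All new literals implied by ``lit`` given ``assign``; None on conflict."""
        val = assign[abs(lit)]
        if val != 0:
            return [] if (val > 0) == (lit > 0) else None
        new: dict[int, None] = {lit: None}
        stack = [lit]
        while stack:
            cur = stack.pop()
            for nxt in self._imp.get(cur, ()):
                v = assign[abs(nxt)]
                if v != 0:
                    if (v > 0) != (nxt > 0):
                        return None
                    continue
                if -nxt in new:
                    return None
                if nxt not in new:
                    new[nxt] = None
                    stack.append(nxt)
        return list(new)

    def solve(self, rng: np.random.Generator, polarity_bias=None):
        """Return a 0/1 assignment of length ``n_vars``, or None if unsatisfiable.

        ``polarity_bias`` gives, per variable, the probability of trying the
        positive literal first (default 0.5 everywhere).  Deterministic for a
        fixed generator state; different states explore different models.
        """
        assign = np.zeros(self.n_vars + 1, dtype=np.int8)  # 0 unknown, +1/-1
        order = rng.permutation(self.n_vars) + 1
        if polarity_bias is None:
            polarity = rng.integers(0, 2, size=self.n_vars)
        else:
            bias = np.asarray(polarity_bias, dtype=np.float64)
            if bias.shape != (self.n_vars,):
                raise ValueError("polarity_bias must have one entry per variable")
            polarity = rng.random(self.n_vars) < bias[order - 1]
        for v, pol in zip(order, polarity):
            if assign[v] != 0:
                continue
            first = int(v) if pol else -int(v)
            closure = self._closure(first, assign)
            if closure is None:
                closure = self._closure(-first, assign)
                if closure is None:
                    return None
            for lit in closure:
                assign[abs(lit)] = 1 if lit > 0 else -1
        return (assign[1:] > 0).astype(np.uint8)


class SelectionSolver:
    """DPLL over ``n_vars`` Boolean variables with an exactly-``k`` side constraint.

    Clauses are lists of DIMACS literals.  ``add_clause`` may be called
    between :meth:`solve` invocations (model enumeration via blocking
    clauses); each solve restarts from scratch.
    """

    def __init__(self, n_vars: int, clauses=(), exactly: int | None = None):
        self.n_vars = int(n_vars)
        self.exactly = exactly
        self.clauses: list[tuple[int, ...]] = []
        self._occ: list[list[int]] = [[] for _ in range(2 * self.n_vars + 1)]
        for c in clauses:
            self.add_clause(c)

    def _slot(self, lit: int) -> int:
        # occurrence-list slot for a literal: +v -> v, -v -> n_vars + v
        return lit if lit > 0 else self.n_vars - lit

    def add_clause(self, lits) -> None:
        c = tuple(int(l) for l in lits)
        if not c:
            raise ValueError("empty clause")
        idx = len(self.clauses)
        self.clauses.append(c)
        for l in c:
            self._occ[self._slot(l)].append(idx)

    # -- solving -------------------------------------------------------

    def solve(self, rng: np.random.Generator, assumptions=()):
        """Return the set of true variables (1-based), or None if unsatisfiable."""
        n = self.n_vars
        k = self.exactly
        assign = [0] * (n + 1)  # 0 unknown, +1 true, -1 false
        n_true = 0
        n_false = 0
        # per-clause counters
        sat_count = [0] * len(self.clauses)
        free_count = [len(c) for c in self.clauses]
        trail: list[int] = []  # literals in assignment order

        def set_lit(lit: int) -> bool:
            """Assign literal; return False on immediate conflict."""
            nonlocal n_true, n_false
            v = abs(lit)
            val = 1 if lit > 0 else -1
            if assign[v] != 0:
                return assign[v] == val
            assign[v] = val
            trail.append(lit)
            if val > 0:
                n_true += 1
            else:
                n_false += 1
            for ci in self._occ[self._slot(lit)]:
                sat_count[ci] += 1
            for ci in self._occ[self._slot(-lit)]:
                free_count[ci] -= 1
            return True

        def unset_last() -> None:
            nonlocal n_true, n_false
            lit = trail.pop()
            v = abs(lit)
            if assign[v] > 0:
                n_true -= 1
            else:
                n_false -= 1
            assign[v] = 0
            for ci in self._occ[self._slot(lit)]:
                sat_count[ci] -= 1
            for ci in self._occ[self._slot(-lit)]:
                free_count[ci] += 1

        def propagate(queue: list[int]) -> bool:
            """Assign queued literals and all their consequences."""
            while queue:
                lit = queue.pop()
                if not set_lit(lit):
                    return False
                # clause consequences: clauses losing the literal -lit
                for ci in self._occ[self._slot(-lit)]:
                    if sat_count[ci] == 0:
                        if free_count[ci] == 0:
                            return False
                        if free_count[ci] == 1:
                            unit = next(
                                l for l in self.clauses[ci] if assign[abs(l)] == 0
                            )
                            queue.append(unit)
                # cardinality consequences
                if k is not None:
                    if n_true > k or n - n_false < k:
                        return False
                    if n_true == k or n - n_false == k:
                        forced = 1 if n - n_false == k and n_true < k else -1
                        for v in range(1, n + 1):
                            if assign[v] == 0:
                                queue.append(v * forced)
            return True

        # initial propagation: assumptions + pre-existing unit clauses
        init = [int(a) for a in assumptions]
        init += [c[0] for c in self.clauses if len(c) == 1]
        if k is not None and k == 0:
            init += [-v for v in range(1, n + 1)]
        if k is not None and k == n:
            init += [v for v in range(1, n + 1)]
        base = len(trail)
        if not propagate(init):
            return None

        # decision stack: (trail length before decision, literal, flipped?)
        decisions: list[list] = []
        while True:
            free = [v for v in range(1, n + 1) if assign[v] == 0]
            if not free:
                if k is not None and n_true != k:
                    # dead end with no free vars; treat as conflict
                    if not self._backjump(decisions, trail, unset_last, propagate):
                        return None
                    continue
                return {v for v in range(1, n + 1) if assign[v] > 0}
            v = int(free[rng.integers(len(free))])
            if k is not None:
                remaining_need = k - n_true
                p_true = remaining_need / len(free)
            else:
                p_true = 0.5
            lit = v if rng.random() < p_true else -v
            decisions.append([len(trail), lit, False])
            if not propagate([lit]):
                if not self._backjump(decisions, trail, unset_last, propagate):
                    return None
        # unreachable

    @staticmethod
    def _backjump(decisions, trail, unset_last, propagate) -> bool:
        """Undo to the deepest unflipped decision and take its negation."""
        while decisions:
            mark, lit, flipped = decisions[-1]
            while len(trail) > mark:
                unset_last()
            if flipped:
                decisions.pop()
                continue
            decisions[-1][2] = True
            if propagate([-lit]):
                return True
            # conflict again on the flip: continue unwinding
            mark = decisions[-1][0]
            while len(trail) > mark:
                unset_last()
            decisions.pop()
        return False
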