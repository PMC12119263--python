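"""Fuzzy-set QCA engine: necessity, truth tables, Boolean minimization.

Set-theoretic relations between calibrated condition memberships and an
outcome membership are summarised by two containment ratios:

* sufficiency consistency of X for Y: sum min(x, y) / sum x
* necessity consistency of X for Y:   sum min(x, y) / sum y

with coverage as the complementary ratio in each case.

Sufficiency analysis proceeds through a truth table over the 2^k corners
of the condition space.  Each case belongs to the unique corner where all
its memberships exceed 0.5; corners with enough cases are classified
sufficient (positive) when their raw consistency clears a threshold, other
observed corners are negative, and sparse corners are remainders.  Positive
corners are then reduced by Quine-McCluskey minimization to prime
implicants and a minimal cover:

* complex solution      — no remainders used as don't-cares
* parsimonious solution — all remainders used as don't-cares
* intermediate solution — only "easy counterfactual" remainders, i.e.
  corners reachable from an observed positive corner by moving conditions
  in their theoretically expected direction

A condition literal in an intermediate configuration is *core* when the
same literal occurs in a parsimonious implicant subsumed by that
configuration, and *peripheral* otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .calibration import FuzzyDataset
from .errors import ConfigError, DataError, ValidationError

NECESSITY_FLAG = 0.9  # conditions with consistency above this are flagged necessary

Expectation = Literal["present", "absent", "either"]


# ---------------------------------------------------------------------------
# necessity

@dataclass(frozen=True)
class NecessityResult:
    condition: str  # condition name, "~"-prefixed for the negated set
    consistency: float
    coverage: float
    necessary: bool  # consistency > 0.9


def necessity_analysis(fds: FuzzyDataset, flag_threshold: float = NECESSITY_FLAG) -> list[NecessityResult]:
    """Necessity consistency/coverage for every condition, both polarities."""
    if fds.n_cases == 0:
        raise DataError("necessity_analysis: empty dataset")
    y = fds.outcome
    sum_y = y.sum()
    if sum_y == 0:
        raise DataError("necessity_analysis: outcome membership sums to zero")
    results = []
    for j, name in enumerate(fds.condition_names):
        for label, x in ((name, fds.memberships[:, j]), ("~" + name, 1.0 - fds.memberships[:, j])):
            overlap = np.minimum(x, y).sum()
            sum_x = x.sum()
            cons = overlap / sum_y
            cov = overlap / sum_x if sum_x > 0 else float("nan")
            results.append(NecessityResult(label, float(cons), float(cov), bool(cons > flag_threshold)))
    return results


# ---------------------------------------------------------------------------
# truth table

def row_membership(case: np.ndarray, combo: int, k: int) -> float:
    """Fuzzy conjunction membership of a case in a truth-table corner.

    ``combo`` encodes the corner as k bits (bit j set = condition j
    present); membership is the min over conditions of m or 1-m.
    """
    case = np.asarray(case, dtype=float)
    lits = np.where([(combo >> j) & 1 for j in range(k)], case, 1.0 - case)
    return float(lits.min())


def _combo_memberships(mat: np.ndarray, combo: int) -> np.ndarray:
    k = mat.shape[1]
    bits = np.array([(combo >> j) & 1 for j in range(k)], dtype=bool)
    return np.where(bits, mat, 1.0 - mat).min(axis=1)


@dataclass(frozen=True)
class TruthTableRow:
    combo: int  # k-bit corner encoding
    n_cases: int  # cases with row membership > 0.5
    raw_consistency: float
    pri_consistency: float
    assignment: Literal["positive", "negative", "remainder"]


@dataclass
class TruthTable:
    condition_names: list[str]
    rows: list[TruthTableRow]
    freq_threshold: int
    cons_threshold: float

    @property
    def k(self) -> int:
        return len(self.condition_names)

    def assigned(self, kind: str) -> list[int]:
        return [r.combo for r in self.rows if r.assignment == kind]

    def combo_label(self, combo: int) -> str:
        return "*".join(
            (name if (combo >> j) & 1 else "~" + name)
            for j, name in enumerate(self.condition_names)
        )


def build_truth_table(
    fds: FuzzyDataset, freq_threshold: int = 1, cons_threshold: float = 0.8
) -> TruthTable:
    """Assign cases to corners and classify corners.

    A corner is positive when it holds at least ``freq_threshold`` cases
    and its raw consistency (sum min(rowmem, y) / sum rowmem over all
    cases) reaches ``cons_threshold``; an observed-but-inconsistent corner
    is negative (contradictory corners are never dropped); sparse corners
    are remainders available as counterfactuals.
    """
    if freq_threshold < 1:
        raise ConfigError("freq_threshold must be >= 1")
    if not 0 < cons_threshold <= 1:
        raise ConfigError("cons_threshold must be in (0, 1]")
    mat, y = fds.memberships, fds.outcome
    if np.any(mat == 0.5):
        raise ValidationError(
            "membership exactly 0.5 encountered; apply adjust_half before the truth table"
        )
    k = fds.n_conditions
    # each case's best-fit corner: the unique corner where all memberships > 0.5
    corner_of_case = (mat > 0.5).astype(int) @ (1 << np.arange(k))
    counts = np.bincount(corner_of_case, minlength=2**k)
    rows = []
    for combo in range(2**k):
        mem = _combo_memberships(mat, combo)
        s = mem.sum()
        overlap = np.minimum(mem, y).sum()
        raw = overlap / s if s > 0 else float("nan")
        anti = np.minimum(np.minimum(mem, y), 1.0 - y).sum()
        pri = (overlap - anti) / (s - anti) if s - anti > 0 else float("nan")
        n = int(counts[combo])
        if n < freq_threshold:
            assignment = "remainder"
        elif np.isfinite(raw) and raw >= cons_threshold:
            assignment = "positive"
        else:
            assignment = "negative"
        rows.append(TruthTableRow(combo, n, float(raw), float(pri), assignment))
    return TruthTable(list(fds.condition_names), rows, freq_threshold, cons_threshold)


# ---------------------------------------------------------------------------
# implicants and Quine-McCluskey minimization

@dataclass(frozen=True, order=True)
class Implicant:
    """A conjunction of condition literals over k conditions.

    ``mask`` bit j set means condition j is specified; ``values`` bit j
    gives its polarity (only meaningful where the mask is set).
    """

    k: int
    mask: int
    values: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", self.values & self.mask)

    def covers(self, combo: int) -> bool:
        return (combo & self.mask) == self.values

    def covered_combos(self) -> list[int]:
        free = [j for j in range(self.k) if not (self.mask >> j) & 1]
        combos = []
        for bits in itertools.product((0, 1), repeat=len(free)):
            c = self.values
            for j, b in zip(free, bits):
                c |= b << j
            combos.append(c)
        return combos

    def n_literals(self) -> int:
        return bin(self.mask).count("1")

    def subsumes(self, other: "Implicant") -> bool:
        """True when every combo covered by ``other`` is covered by self."""
        return (self.mask & other.mask) == self.mask and (other.values & self.mask) == self.values

    def literals(self) -> dict[int, bool]:
        return {j: bool((self.values >> j) & 1) for j in range(self.k) if (self.mask >> j) & 1}

    def label(self, names: Sequence[str]) -> str:
        lits = self.literals()
        if not lits:
            return "(always)"
        return "*".join((names[j] if v else "~" + names[j]) for j, v in sorted(lits.items()))

    def sort_key(self) -> tuple:
        # literal per condition: 0 present, 1 absent, 2 don't-care — gives a
        # stable lexicographic order by condition position
        return tuple(
            (0 if (self.values >> j) & 1 else 1) if (self.mask >> j) & 1 else 2
            for j in range(self.k)
        )


def prime_implicants(k: int, onset: Iterable[int], dontcares: Iterable[int] = ()) -> list[Implicant]:
    """Quine-McCluskey prime implicants of the function ON=onset, DC=dontcares.

    Minterms are iteratively merged along single differing bits; implicants
    that never merge are prime.  The empty (tautological) implicant is
    inadmissible — a configurational solution must name at least one
    condition — so single-literal implicants never merge away even when the
    whole condition space is positive or don't-care.
    """
    onset, dontcares = set(onset), set(dontcares)
    if overlap := onset & dontcares:
        raise ConfigError(f"minterms listed as both positive and don't-care: {sorted(overlap)}")
    current = {(((1 << k) - 1), m) for m in onset | dontcares}
    primes: set[tuple[int, int]] = set()
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        items = sorted(current)
        by_mask: dict[int, list[tuple[int, int]]] = {}
        for it in items:
            by_mask.setdefault(it[0], []).append(it)
        for mask, group in by_mask.items():
            seen = {v for _, v in group}
            for _, v in group:
                for j in range(k):
                    bit = 1 << j
                    if not mask & bit:
                        continue
                    if mask == bit:  # would merge to the inadmissible empty implicant
                        continue
                    if (v ^ bit) in seen:
                        merged.add((mask & ~bit, v & ~bit))
                        used.add((mask, v))
                        used.add((mask, v ^ bit))
        primes |= current - used
        current = merged
    return sorted(
        (Implicant(k, mask, values) for mask, values in primes), key=Implicant.sort_key
    )


def _essential_and_covers(
    primes: Sequence[Implicant], targets: Sequence[int]
) -> tuple[list[Implicant], list[list[Implicant]]]:
    """Prime-implicant chart: essential primes, then all minimal completions."""
    cover_of = {t: [p for p in primes if p.covers(t)] for t in targets}
    essential = []
    for t, ps in cover_of.items():
        if len(ps) == 1 and ps[0] not in essential:
            essential.append(ps[0])
    remaining = [t for t in targets if not any(p.covers(t) for p in essential)]
    if not remaining:
        return essential, [sorted(essential, key=Implicant.sort_key)]
    pool = [p for p in primes if p not in essential and any(p.covers(t) for t in remaining)]

    # branch-and-bound set cover: branch on the hardest uncovered row
    best_size = len(pool) + 1
    solutions: set[frozenset[Implicant]] = set()

    def dfs(uncovered: frozenset[int], chosen: tuple[Implicant, ...]) -> None:
        nonlocal best_size
        if not uncovered:
            if len(chosen) < best_size:
                best_size = len(chosen)
                solutions.clear()
            if len(chosen) == best_size:
                solutions.add(frozenset(chosen))
            return
        if len(chosen) + 1 > best_size:
            return
        row = min(uncovered, key=lambda t: len([p for p in pool if p.covers(t)]))
        for p in pool:
            if p.covers(row) and p not in chosen:
                dfs(uncovered - frozenset(p.covered_combos()), chosen + (p,))

    dfs(frozenset(remaining), ())
    if not solutions:  # cannot happen: every positive row is its own implicant
        raise AssertionError("prime implicants fail to cover the positive rows")
    covers = [sorted(essential + list(sol), key=Implicant.sort_key) for sol in solutions]
    covers.sort(key=lambda c: tuple(p.sort_key() for p in c))
    return essential, covers


@dataclass
class MinimizationResult:
    implicants: list[Implicant]  # canonical minimal cover
    all_covers: list[list[Implicant]]  # every minimal cover (canonical first)
    primes: list[Implicant]
    empty: bool = False


def minimize(
    table: TruthTable, mode: Literal["complex", "parsimonious"], dontcares: Iterable[int] | None = None
) -> MinimizationResult:
    """Minimal disjunction of implicants covering the positive corners.

    ``complex`` uses no counterfactuals (remainders count as negative);
    ``parsimonious`` treats all remainders as don't-cares.  An explicit
    ``dontcares`` set (a subset of the remainders) overrides the mode, which
    is how the intermediate solution is computed.  When several minimal
    covers exist, all are returned and the lexicographically smallest (by
    condition order) is canonical.
    """
    positives = table.assigned("positive")
    if not positives:
        return MinimizationResult([], [], [], empty=True)
    if dontcares is not None:
        dc = set(dontcares)
        if extra := dc - set(table.assigned("remainder")):
            raise ConfigError(f"don't-cares must be remainder rows, got {sorted(extra)}")
    elif mode == "parsimonious":
        dc = set(table.assigned("remainder"))
    elif mode == "complex":
        dc = set()
    else:
        raise ConfigError(f"unknown minimization mode {mode!r}")
    primes = prime_implicants(table.k, positives, dc)
    essential, covers = _essential_and_covers(primes, positives)
    return MinimizationResult(covers[0], covers, primes)


# ---------------------------------------------------------------------------
# intermediate solution and core/peripheral classification

def easy_counterfactuals(
    table: TruthTable, expectations: Mapping[str, Expectation]
) -> set[int]:
    """Remainder corners admissible as easy counterfactuals.

    A remainder is easy when it can be reached from some observed positive
    corner by moving conditions only toward their expected state (either
    direction when the expectation is "either"): if a combination is known
    to produce the outcome, adding an expected-helpful condition is assumed
    not to undo it.
    """
    names = table.condition_names
    for cond in expectations:
        if cond not in names:
            raise ConfigError(f"expectation for unknown condition {cond!r}")
        if expectations[cond] not in ("present", "absent", "either"):
            raise ConfigError(f"invalid expectation {expectations[cond]!r} for {cond!r}")
    positives = table.assigned("positive")
    easy = set()
    for r in table.assigned("remainder"):
        for p in positives:
            ok = True
            for j, name in enumerate(names):
                if ((r >> j) & 1) == ((p >> j) & 1):
                    continue
                exp = expectations.get(name, "either")
                r_state = "present" if (r >> j) & 1 else "absent"
                if exp != "either" and exp != r_state:
                    ok = False
                    break
            if ok:
                easy.add(r)
                break
    return easy


def intermediate_minimize(
    table: TruthTable, expectations: Mapping[str, Expectation]
) -> MinimizationResult:
    """Minimization using only easy-counterfactual remainders as don't-cares."""
    return minimize(table, "complex", dontcares=easy_counterfactuals(table, expectations))


Role = Literal["core-present", "peripheral-present", "core-absent", "peripheral-absent"]


@dataclass
class Configuration:
    """One solution pathway: literals with core/peripheral roles plus metrics."""

    implicant: Implicant
    roles: dict[str, Role]  # condition name -> role; absent key = don't-care
    consistency: float = float("nan")
    raw_coverage: float = float("nan")
    unique_coverage: float = float("nan")


@dataclass
class Solution:
    kind: Literal["complex", "parsimonious", "intermediate"]
    configurations: list[Configuration]
    solution_consistency: float = float("nan")
    solution_coverage: float = float("nan")
    all_covers: list[list[Implicant]] = field(default_factory=list)
    empty: bool = False


def classify_core_peripheral(
    intermediate: Sequence[Implicant],
    parsimonious: Sequence[Implicant],
    names: Sequence[str],
) -> list[Configuration]:
    """Mark literals core/peripheral in each intermediate configuration.

    A literal is core iff the same condition with the same polarity occurs
    in a parsimonious implicant subsuming the configuration; literals
    present only in the intermediate configuration are peripheral.
    """
    configs = []
    for imp in intermediate:
        core_lits: set[tuple[int, bool]] = set()
        for q in parsimonious:
            if q.subsumes(imp):
                core_lits |= set(q.literals().items())
        roles: dict[str, Role] = {}
        for j, v in imp.literals().items():
            grade = "core" if (j, v) in core_lits else "peripheral"
            roles[names[j]] = f"{grade}-{'present' if v else 'absent'}"  # type: ignore[assignment]
        configs.append(Configuration(imp, roles))
    return configs


# ---------------------------------------------------------------------------
# metrics

def _implicant_membership(imp: Implicant, mat: np.ndarray) -> np.ndarray:
    lits = imp.literals()
    if not lits:
        return np.ones(mat.shape[0])
    cols = [mat[:, j] if v else 1.0 - mat[:, j] for j, v in sorted(lits.items())]
    return np.min(np.column_stack(cols), axis=1)


def configuration_metrics(configs: list[Configuration], fds: FuzzyDataset) -> tuple[float, float]:
    """Fill per-configuration and solution consistency/coverage (in place).

    Per configuration: consistency = sum min(m, y)/sum m and raw coverage =
    sum min(m, y)/sum y where m is the configuration membership; unique
    coverage is the loss in union coverage when the configuration is
    removed (union = elementwise max).  Returns the solution consistency
    and coverage computed on the union membership.
    """
    if not configs:
        raise DataError("configuration_metrics: no configurations")
    y = fds.outcome
    sum_y = y.sum()
    if sum_y == 0:
        raise DataError("configuration_metrics: outcome membership sums to zero")
    mems = [_implicant_membership(c.implicant, fds.memberships) for c in configs]

    def coverage(m: np.ndarray) -> float:
        return float(np.minimum(m, y).sum() / sum_y)

    union = np.max(np.column_stack(mems), axis=1)
    for i, (c, m) in enumerate(zip(configs, mems)):
        s = m.sum()
        if s == 0:
            raise DataError(
                f"configuration {c.implicant} has zero total membership; consistency undefined"
            )
        c.consistency = float(np.minimum(m, y).sum() / s)
        c.raw_coverage = coverage(m)
        others = [mm for j, mm in enumerate(mems) if j != i]
        if others:
            union_wo = np.max(np.column_stack(others), axis=1)
            c.unique_coverage = coverage(union) - coverage(union_wo)
        else:
            c.unique_coverage = c.raw_coverage
    sol_cons = float(np.minimum(union, y).sum() / union.sum()) if union.sum() > 0 else float("nan")
    return sol_cons, coverage(union)


# ---------------------------------------------------------------------------
# full run

@dataclass
class FsqcaReport:
    outcome_name: str
    condition_names: list[str]
    freq_threshold: int
    cons_threshold: float
    expectations: dict[str, Expectation]
    necessity: list[NecessityResult]
    truth_table: TruthTable
    complex: Solution
    parsimonious: Solution
    intermediate: Solution


def _solution(kind: str, res: MinimizationResult, fds: FuzzyDataset, names: Sequence[str],
              parsimonious_imps: Sequence[Implicant] | None = None) -> Solution:
    if res.empty:
        return Solution(kind, [], empty=True)  # type: ignore[arg-type]
    ref = parsimonious_imps if parsimonious_imps is not None else res.implicants
    configs = classify_core_peripheral(res.implicants, ref, names)
    cons, cov = configuration_metrics(configs, fds)
    return Solution(kind, configs, cons, cov, res.all_covers)  # type: ignore[arg-type]


def run_fsqca(
    fds: FuzzyDataset,
    freq_threshold: int = 1,
    cons_threshold: float = 0.8,
    expectations: Mapping[str, Expectation] | None = None,
) -> FsqcaReport:
    """End-to-end analysis: necessity, truth table, three solution types."""
    expectations = dict(expectations or {})
    nec = necessity_analysis(fds)
    table = build_truth_table(fds, freq_threshold, cons_threshold)
    res_c = minimize(table, "complex")
    res_p = minimize(table, "parsimonious")
    res_i = intermediate_minimize(table, expectations)
    names = fds.condition_names
    pars_imps = res_p.implicants
    return FsqcaReport(
        outcome_name=fds.outcome_name,
        condition_names=list(names),
        freq_threshold=freq_threshold,
        cons_threshold=cons_threshold,
        expectations=expectations,
        necessity=nec,
        truth_table=table,
        complex=_solution("complex", res_c, fds, names, pars_imps),
        parsimonious=_solution("parsimonious", res_p, fds, names, pars_imps),
        intermediate=_solution("intermediate", res_i, fds, names, pars_imps),
    )


ROLE_GLYPH = {
    "core-present": "●",
    "peripheral-present": "•",
    "core-absent": "⊗",
    "peripheral-absent": "⊘",
}


def configuration_chart(solution: Solution, names: Sequence[str]) -> str:
    """Plain-text configuration chart (● core-present, • peripheral-present,
    ⊗ core-absent, ⊘ peripheral-absent, blank don't-care)."""
    if solution.empty or not solution.configurations:
        return "(empty solution)"
    width = max(len(n) for n in names) + 2
    header = " " * width + "  ".join(f"{i + 1:>3}" for i in range(len(solution.configurations)))
    lines = [header]
    for j, name in enumerate(names):
        cells = []
        for cfg in solution.configurations:
            role = cfg.roles.get(name)
            cells.append(f"{ROLE_GLYPH.get(role, ' '):>3}")
        lines.append(f"{name:<{width}}" + "  ".join(cells))
    lines.append(
        f"{'consistency':<{width}}"
        + "  ".join(f"{c.consistency:.3f}"[:5].rjust(3) for c in solution.configurations)
    )
    lines.append(
        f"{'raw coverage':<{width}}"
        + "  ".join(f"{c.raw_coverage:.3f}"[:5].rjust(3) for c in solution.configurations)
    )
    lines.append(
        f"{'unique coverage':<{width}}"
        + "  ".join(f"{c.unique_coverage:.3f}"[:5].rjust(3) for c in solution.configurations)
    )
    lines.append(f"solution consistency {solution.solution_consistency:.3f}")
    lines.append(f"solution coverage    {solution.solution_coverage:.3f}")
    return "\n".join(lines)
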