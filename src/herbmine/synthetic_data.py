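"""Synthetic prescription generators: archetype sampling and exact solving.

The survey's raw prescriptions were never released; what the paperwork of
such surveys prints is (a) summary statistics and (b) the support counts of
the top core-material combinations. This module provides two generators so
every downstream stage is testable against those printed summaries:

* :func:`sample_dataset` draws prescriptions from a *formula-archetype*
  model: each prescription starts from one classical formula core (e.g. the
  Si Wu quartet Dang Gui / Chuan Qiong / Di Huang / Bai Shao) drawn by
  weight, independently gains add-on materials, and receives per-material
  daily doses from clipped normal distributions.

* :func:`solve_exact_transactions` builds a transaction set whose support
  counts match a list of exact itemset-count constraints, by integer
  feasibility over the 2^m *composition cells* of the m constrained items
  (cell = the subset of constrained items a transaction contains; each
  constraint is a linear equality over cells, one extra equality fixes the
  total N). Greedy top-down allocation fails on instances where a
  constrained item must be painted onto existing carriers rather than added
  in fresh transactions; the cell formulation handles those exactly.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import Bounds, LinearConstraint, milp

from .errors import InfeasibleConstraintsError, ValidationError
from .io_model import Dataset, MaterialRecord, Prescription, TransactionSet, load_catalog
from .itemset_mining import brute_force_support

#: Largest number of distinct constrained items the exact solver accepts
#: (the cell formulation has 2^m integer variables).
SOLVER_ITEM_BOUND = 16


@dataclass(frozen=True)
class DoseModel:
    """Clipped-normal daily-dose model for one material (grams)."""

    mean: float
    sd: float
    min_clip: float = 0.5

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"dose sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class ArchetypeModel:
    """Mixture-of-formula-cores generative model for prescriptions."""

    archetypes: tuple[tuple[frozenset[str], float], ...]
    addon_probs: Mapping[str, float] = field(default_factory=dict)
    dose_models: Mapping[str, DoseModel] = field(default_factory=dict)
    n: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.archetypes:
            raise ValidationError("archetype list must be non-empty")
        weights = [w for _, w in self.archetypes]
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValidationError("archetype weights must be >= 0 and not all zero")
        for item, p in self.addon_probs.items():
            if not (0 <= p <= 1):
                raise ValidationError(f"addon probability for {item} outside [0, 1]")

    @property
    def items(self) -> frozenset[str]:
        out: set[str] = set()
        for a, _ in self.archetypes:
            out |= a
        out |= set(self.addon_probs)
        return frozenset(out)


@dataclass(frozen=True)
class ConstraintSet:
    """Exact support-count constraints over a transaction universe."""

    universe: tuple[str, ...]
    N: int
    constraints: tuple[tuple[frozenset[str], int], ...]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        for s, k in self.constraints:
            if not s <= uni:
                raise ValidationError(
                    f"constrained itemset {sorted(s)} outside universe"
                )
            if not (0 <= k <= self.N):
                raise ValidationError(
                    f"constraint count {k} for {sorted(s)} outside [0, N={self.N}]"
                )

    @property
    def constrained_items(self) -> tuple[str, ...]:
        out: set[str] = set()
        for s, _ in self.constraints:
            out |= s
        return tuple(sorted(out))


@dataclass(frozen=True)
class FeasibilityReport:
    feasible: bool
    violations: tuple[str, ...] = ()
    partial: bool = False  # True when the exact search was skipped (m > bound)

    def __post_init__(self) -> None:
        if self.feasible and self.violations:
            raise ValueError("feasible report cannot carry violations")


# ---------------------------------------------------------------------------
# archetype sampler

def sample_dataset(
    model: ArchetypeModel,
    catalog: Sequence[MaterialRecord] | None = None,
) -> Dataset:
    """Draw ``model.n`` prescriptions; identical seed gives identical data.

    Per prescription: one archetype is drawn by normalized weight, each
    add-on material joins independently with its probability, and every
    present material receives a dose drawn from its clipped normal model.
    """
    if catalog is None:
        catalog = fixture_table1()
    known = {m.material_id for m in catalog}
    missing_models = sorted(model.items - set(model.dose_models))
    if missing_models:
        raise ValidationError(f"no dose model for item(s): {missing_models}")
    missing_cat = sorted(model.items - known)
    if missing_cat:
        raise ValidationError(f"model items missing from catalog: {missing_cat}")

    rng = np.random.default_rng(model.seed)
    weights = np.array([w for _, w in model.archetypes], dtype=float)
    probs = weights / weights.sum()
    addon_items = sorted(model.addon_probs)
    order = {m.material_id: i for i, m in enumerate(catalog)}

    prescriptions = []
    for i in range(model.n):
        idx = rng.choice(len(model.archetypes), p=probs)
        present = set(model.archetypes[idx][0])
        for item in addon_items:
            if rng.random() < model.addon_probs[item]:
                present.add(item)
        items = []
        for item in sorted(present, key=lambda x: order.get(x, len(order))):
            dm = model.dose_models[item]
            dose = max(float(rng.normal(dm.mean, dm.sd)), dm.min_clip)
            items.append((item, dose))
        prescriptions.append(Prescription(
            prescription_id=f"S{i + 1:03d}",
            pharmacy_id=f"PH{(i % 96) + 1:03d}",
            region_code="TC",
            items=tuple(items),
        ))
    return Dataset(catalog=tuple(catalog), prescriptions=tuple(prescriptions))


def sample_doses(dm: DoseModel, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` doses from one clipped-normal dose model."""
    rng = np.random.default_rng(seed)
    return np.maximum(rng.normal(dm.mean, dm.sd, size=n), dm.min_clip)


# ---------------------------------------------------------------------------
# exact constraint solving

def _cells(items: Sequence[str]):
    m = len(items)
    for mask in range(2 ** m):
        yield frozenset(items[i] for i in range(m) if mask >> i & 1)


def _milp_arrays(cs: ConstraintSet):
    items = list(cs.constrained_items)
    cells = list(_cells(items))
    ncells = len(cells)
    rows = []
    rhs = []
    for s, k in cs.constraints:
        rows.append([1.0 if s <= c else 0.0 for c in cells])
        rhs.append(float(k))
    rows.append([1.0] * ncells)
    rhs.append(float(cs.N))
    return items, cells, np.asarray(rows), np.asarray(rhs)


def _milp_solve(cs: ConstraintSet, seed: int) -> np.ndarray | None:
    """Integer-feasible cell counts, or None when the system is infeasible."""
    items, cells, A, b = _milp_arrays(cs)
    rng = np.random.default_rng(seed)
    # random objective: any feasible vertex works; the seed picks among them
    obj = rng.uniform(0.0, 1.0, size=len(cells))
    res = milp(
        c=obj,
        constraints=LinearConstraint(A, b, b),
        integrality=np.ones(len(cells)),
        bounds=Bounds(0, cs.N),
    )
    if not res.success:
        return None
    x = np.round(res.x).astype(int)
    if not np.allclose(A @ x, b):
        return None
    return x


def check_constraints(cs: ConstraintSet) -> FeasibilityReport:
    """Diagnose a constraint system before solving.

    Runs (i) subset monotonicity among the constrained sets, (ii) an exact
    integer-feasibility search over composition cells when the number of
    constrained items is within the solver bound, and (iii) inclusion-
    exclusion union bounds against N for item groups whose full subset
    lattice is constrained. (iii) is what proves the survey's printed
    combination counts incompatible with its printed singleton citation
    counts: with all seven subsets of a triple constrained, the union size
    is determined exactly and can exceed N.
    """
    violations: list[str] = []
    by_set = {s: k for s, k in cs.constraints}

    # (i) monotonicity: S subset of T  =>  count(S) >= count(T)
    for s, t in combinations(by_set, 2):
        small, big = (s, t) if s <= t else (t, s) if t <= s else (None, None)
        if small is None:
            continue
        if by_set[small] < by_set[big]:
            violations.append(
                f"monotonicity: count({sorted(small)})={by_set[small]} < "
                f"count({sorted(big)})={by_set[big]} despite subset relation"
            )

    # (iii) inclusion-exclusion union bound on fully-constrained groups
    items = cs.constrained_items
    for size in (2, 3):
        for group in combinations(items, size):
            subsets = [frozenset(c)
                       for r in range(1, size + 1)
                       for c in combinations(group, r)]
            if not all(sub in by_set for sub in subsets):
                continue
            union = sum(
                (-1) ** (len(sub) + 1) * by_set[sub] for sub in subsets
            )
            if union > cs.N:
                violations.append(
                    f"union bound: |union of {list(group)}| = {union} > N = {cs.N} "
                    "by inclusion-exclusion over the constrained subsets"
                )

    # (ii) exact integer feasibility over composition cells
    partial = False
    m = len(items)
    if m > SOLVER_ITEM_BOUND:
        partial = True
    elif not violations:
        if _milp_solve(cs, seed=0) is None:
            violations.append(
                "exact search: no integer assignment of composition cells "
                "satisfies all counts and the transaction total"
            )

    return FeasibilityReport(
        feasible=not violations, violations=tuple(violations), partial=partial
    )


def solve_exact_transactions(cs: ConstraintSet, seed: int = 0) -> TransactionSet:
    """Build N transactions matching every exact itemset-count constraint.

    The returned set is verified internally against the brute-force support
    oracle before being returned — solver soundness is asserted inside the
    operation, not only in tests. Deterministic for a given seed and input
    ordering. Raises :class:`InfeasibleConstraintsError` when no transaction
    set exists.
    """
    items = list(cs.constrained_items)
    if len(items) > SOLVER_ITEM_BOUND:
        raise ValidationError(
            f"{len(items)} constrained items exceed the solver bound "
            f"({SOLVER_ITEM_BOUND})"
        )
    x = _milp_solve(cs, seed)
    if x is None:
        report = check_constraints(cs)
        raise InfeasibleConstraintsError(
            "constraints admit no transaction set: "
            + ("; ".join(report.violations) or "integer search infeasible"),
            violations=list(report.violations),
        )
    cells = list(_cells(items))
    transactions: list[frozenset[str]] = []
    for cell, count in zip(cells, x):
        transactions.extend([cell] * int(count))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(transactions))
    transactions = [transactions[i] for i in order]
    ts = TransactionSet(universe=tuple(cs.universe), transactions=tuple(transactions))

    for s, k in cs.constraints:  # soundness check against the oracle
        got = brute_force_support(ts, s)
        if got != k:
            raise AssertionError(
                f"solver produced count {got} for {sorted(s)}, expected {k}"
            )
    if ts.N != cs.N:
        raise AssertionError(f"solver produced N={ts.N}, expected {cs.N}")
    return ts


# ---------------------------------------------------------------------------
# constraint-set file I/O

_TOTAL_TOKEN = "_total_"


def write_constraints(cs: ConstraintSet, path: str | Path) -> Path:
    """Two-column delimited file; the reserved ``_total_`` row carries N."""
    path = Path(path)
    lines = ["itemset,count", f"{_TOTAL_TOKEN},{cs.N}"]
    lines += [f"{'+'.join(sorted(s))},{k}" for s, k in cs.constraints]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_constraints(path: str | Path, universe: Sequence[str] | None = None) -> ConstraintSet:
    df = pd.read_csv(path, dtype={"itemset": str, "count": int})
    n = None
    constraints = []
    for _, row in df.iterrows():
        if row["itemset"] == _TOTAL_TOKEN:
            n = int(row["count"])
            continue
        constraints.append((frozenset(row["itemset"].split("+")), int(row["count"])))
    if n is None:
        raise ValidationError(f"constraint file {path} lacks a {_TOTAL_TOKEN} row")
    if universe is None:
        universe = sorted({i for s, _ in constraints for i in s})
    return ConstraintSet(universe=tuple(universe), N=n, constraints=tuple(constraints))


# ---------------------------------------------------------------------------
# packaged fixtures

#: Seven core materials of the dysmenorrhea survey, in printed FC order.
CORE7 = ("AS", "LiC", "RG", "PL", "HP", "LyC", "CCT")

#: The ten printed core-combination support counts (N = 99 prescriptions).
CORE7_COUNTS: tuple[tuple[frozenset[str], int], ...] = (
    (frozenset({"LiC", "AS"}), 92),
    (frozenset({"AS", "RG"}), 75),
    (frozenset({"LiC", "RG"}), 73),
    (frozenset({"LiC", "AS", "RG"}), 73),
    (frozenset({"LiC", "PL", "AS"}), 69),
    (frozenset({"PL", "AS", "RG"}), 67),
    (frozenset({"LiC", "PL", "AS", "RG"}), 66),
    (frozenset({"LiC", "LyC", "AS", "RG"}), 60),
    (frozenset({"LiC", "AS", "RG", "HP"}), 56),
    (frozenset({"LiC", "PL", "LyC", "AS", "RG"}), 55),
)


def fixture_table1() -> tuple[MaterialRecord, ...]:
    """The 22-material frequent-material catalog packaged with the code."""
    ref = importlib.resources.files("herbmine.data") / "table1.csv"
    with importlib.resources.as_file(ref) as path:
        return load_catalog(path, strict=True)


def fixture_core7() -> ConstraintSet:
    """The ten printed core-combination counts as exact constraints, N=99.

    Singleton citation counts are deliberately omitted: jointly with the
    combination counts they are provably infeasible at N=99 (the
    inclusion-exclusion union of the top three materials would exceed 99),
    and the combination counts are the quantities the solver must honor.
    """
    return ConstraintSet(universe=CORE7, N=99, constraints=CORE7_COUNTS)


def fixture_archetypes() -> ArchetypeModel:
    """Demonstration archetype model emulating the survey's structure.

    Archetype weights follow an explicit feasible witness of the printed
    combination counts (55 prescriptions carry the full five-material core,
    a further 19 just the Dang Gui / Chuan Qiong pair, and so on); add-on
    probabilities approximate printed citation fractions. Dose means/SDs use
    the three printed values (HP 15.12 +/- 7.24 g, ZJH 25.18 +/- 8.48 g,
    OI 3.09 +/- 2.04 g); other materials get a midpoint-of-pharmacopeia-range
    mean with SD a quarter of the range.
    """

    def _range_model(lo: float, hi: float) -> DoseModel:
        return DoseModel(mean=(lo + hi) / 2, sd=(hi - lo) / 4)

    return ArchetypeModel(
        archetypes=(
            (frozenset({"LiC", "PL", "LyC", "AS", "RG"}), 55.0),
            (frozenset({"LiC", "PL", "AS", "RG"}), 11.0),
            (frozenset({"LiC", "LyC", "AS", "RG"}), 5.0),
            (frozenset({"LiC", "AS", "RG"}), 2.0),
            (frozenset({"AS", "RG"}), 2.0),
            (frozenset({"LiC", "AS"}), 19.0),
            (frozenset({"CaT", "CY"}), 5.0),
        ),
        addon_probs={
            "HP": 0.57, "CCT": 0.59, "GU": 0.45, "ZJH": 0.30, "OI": 0.31,
        },
        dose_models={
            "AS": _range_model(5, 15),
            "LiC": _range_model(3, 10),
            "RG": _range_model(9, 30),
            "PL": _range_model(6, 15),
            "LyC": _range_model(6, 15),
            "CCT": _range_model(3, 10),
            "GU": _range_model(2, 11.5),
            "CaT": _range_model(3, 10),
            "CY": _range_model(3, 12),
            "HP": DoseModel(mean=15.12, sd=7.24),
            "ZJH": DoseModel(mean=25.18, sd=8.48),
            "OI": DoseModel(mean=3.09, sd=2.04),
        },
        n=99,
        seed=0,
    )


def fixtures() -> dict[str, object]:
    """All packaged fixtures: the catalog, the constraint set, the sampler."""
    return {
        "table1": fixture_table1(),
        "core7": fixture_core7(),
        "archetypes": fixture_archetypes(),
    }
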