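"""Selection method S1: random sparse allocations and their bookkeeping.

The base design partitions the full RIL panel into ``n_env`` disjoint
training sets (each RIL phenotyped in exactly one environment); every
environment's prediction set is frozen as the complement of its base
training set. Derived compositions then (a) reduce the per-environment
training size by cumulative masking in seeded groups and (b) redistribute
masked RILs as overlapping RILs (O-RILs) observed in every environment.

Terminology: an NO-RIL is observed in exactly one environment, an O-RIL in
all of them. A composition "185-10" means 185 NO-RILs plus 10 O-RILs per
environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DesignError(ValueError):
    """Invalid design request."""


@dataclass(frozen=True)
class DesignSpec:
    """One cell of the size x composition grid."""

    n_per_env: int
    n_overlap: int
    n_env: int
    replicate_seed: int = 0
    group_size: int = 10

    def __post_init__(self) -> None:
        if self.n_env < 1:
            raise DesignError("n_env must be >= 1")
        if self.n_overlap < 0 or self.n_per_env < 1:
            raise DesignError("sizes must be nonnegative (n_per_env >= 1)")
        if self.n_overlap >= self.n_per_env:
            raise DesignError("n_overlap must be smaller than n_per_env")
        if self.group_size < 1:
            raise DesignError("group_size must be >= 1")
        if self.n_overlap % self.group_size:
            raise DesignError(
                f"n_overlap={self.n_overlap} is not a multiple of the "
                f"masking group size {self.group_size}"
            )

    @property
    def n_no(self) -> int:
        return self.n_per_env - self.n_overlap

    @property
    def label(self) -> str:
        return f"{self.n_no}-{self.n_overlap}"


@dataclass
class Allocation:
    """Per-environment training sets plus frozen prediction sets."""

    no_rils: dict[int, tuple[str, ...]]       # env -> NO-RILs of that env
    o_rils: tuple[str, ...]                   # observed in every environment
    prediction: dict[int, tuple[str, ...]]    # frozen at the base allocation
    never_observed: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    @property
    def n_env(self) -> int:
        return len(self.no_rils)

    @property
    def envs(self) -> list[int]:
        return sorted(self.no_rils)

    def training(self, env: int) -> tuple[str, ...]:
        return self.no_rils[env] + self.o_rils

    def observed_pairs(self) -> set[tuple[str, int]]:
        return {(r, j) for j in self.envs for r in self.training(j)}

    def evaluated_prediction(self, env: int) -> tuple[str, ...]:
        """Frozen prediction set minus RILs currently observed in ``env``.

        O-RILs are observed everywhere, so they are never evaluated; a
        RIL's own training environment never contained it in the frozen
        prediction set to begin with.
        """
        observed_here = set(self.training(env))
        return tuple(r for r in self.prediction[env] if r not in observed_here)

    def unique_observed(self) -> set[str]:
        out: set[str] = set(self.o_rils)
        for rils in self.no_rils.values():
            out.update(rils)
        return out

    def validate(self) -> None:
        all_no: list[str] = []
        for rils in self.no_rils.values():
            all_no.extend(rils)
        if len(all_no) != len(set(all_no)):
            raise DesignError("NO-RIL sets overlap across environments")
        if set(all_no) & set(self.o_rils):
            raise DesignError("a RIL is both NO and O")
        sizes = {len(self.training(j)) for j in self.envs}
        if len(sizes) > 1:
            raise DesignError("training sizes differ across environments")
        for j in self.envs:
            if set(self.training(j)) & set(self.prediction[j]) - set(self.o_rils):
                raise DesignError(
                    f"environment {j}: training RIL inside frozen prediction set"
                )


@dataclass(frozen=True)
class DesignAccounting:
    """Exact integer bookkeeping of one allocation."""

    n_per_env: int
    n_env: int
    unique_across: int
    no_across: int
    plots: int
    cells_total: int
    missing_cells: int
    coverage_fraction: float


def allocate_base(
    ril_ids: Sequence[str], n_env: int, seed: int
) -> Allocation:
    """Seeded random partition of the panel into disjoint training sets.

    Every environment receives ``len(ril_ids) / n_env`` NO-RILs; its frozen
    prediction set is all RILs not assigned to it.
    """
    ril_ids = list(ril_ids)
    n = len(ril_ids)
    if n_env < 1:
        raise DesignError("n_env must be >= 1")
    if n % n_env:
        raise DesignError(
            f"{n} RILs cannot be split evenly into {n_env} environments "
            f"(remainder {n % n_env})"
        )
    per = n // n_env
    rng = np.random.default_rng(seed)
    perm = [ril_ids[i] for i in rng.permutation(n)]
    no_rils = {j: tuple(perm[j * per : (j + 1) * per]) for j in range(n_env)}
    prediction = {}
    for j in range(n_env):
        own = set(no_rils[j])
        prediction[j] = tuple(r for r in ril_ids if r not in own)
    alloc = Allocation(
        no_rils=no_rils,
        o_rils=(),
        prediction=prediction,
        meta={"kind": "base", "seed": int(seed), "n_per_env": per},
    )
    alloc.validate()
    return alloc


def derive_composition(base: Allocation, spec: DesignSpec) -> Allocation:
    """Reduce and recompose a base allocation per one grid cell.

    Size reduction keeps a seeded per-environment prefix so size-s designs
    nest inside size-(s + group) designs; each composition step masks one
    group per environment and promotes ``group_size`` of the pooled masked
    RILs to O-RILs. Leftover masked RILs become never-observed.
    """
    if base.o_rils:
        raise DesignError("derive_composition expects a base (O-free) allocation")
    if spec.n_env != base.n_env:
        raise DesignError("spec.n_env does not match the base allocation")
    base_per = len(next(iter(base.no_rils.values())))
    if spec.n_per_env > base_per:
        raise DesignError(
            f"n_per_env={spec.n_per_env} exceeds base size {base_per}"
        )
    g = spec.group_size
    n_steps = spec.n_overlap // g
    if spec.n_no < n_steps * 0:  # pragma: no cover - guarded by DesignSpec
        raise DesignError("negative NO count")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.replicate_seed), 0x5005])
    )
    # Seeded per-environment order; the same draws happen for every spec with
    # the same replicate_seed, which is what makes designs nested.
    order = {
        j: [base.no_rils[j][i] for i in rng.permutation(base_per)]
        for j in base.envs
    }
    active = {j: order[j][: spec.n_per_env] for j in base.envs}
    reduction_masked = [r for j in base.envs for r in order[j][spec.n_per_env :]]

    o_rils: list[str] = []
    leftover: list[str] = []
    for step in range(1, n_steps + 1):
        pool = [
            r
            for j in base.envs
            for r in active[j][spec.n_per_env - g * step : spec.n_per_env - g * (step - 1)]
        ]
        if g > len(pool):
            raise DesignError("masked pool smaller than requested O-RIL draw")
        pick = rng.choice(len(pool), size=g, replace=False)
        chosen = {pool[i] for i in pick}
        o_rils.extend(pool[i] for i in sorted(pick))
        leftover.extend(r for r in pool if r not in chosen)

    n_no = spec.n_per_env - g * n_steps
    no_rils = {j: tuple(active[j][:n_no]) for j in base.envs}
    alloc = Allocation(
        no_rils=no_rils,
        o_rils=tuple(o_rils),
        prediction=dict(base.prediction),
        never_observed=tuple(reduction_masked) + tuple(leftover),
        meta={
            "kind": "composition",
            "base": base.meta,
            "n_per_env": spec.n_per_env,
            "n_overlap": spec.n_overlap,
            "replicate_seed": int(spec.replicate_seed),
            "group_size": g,
        },
    )
    alloc.validate()
    return alloc


def composition_grid(
    sizes: Sequence[int] | None = None,
    overlap_step: int = 10,
    min_no: int = 5,
    n_env: int = 9,
    replicate_seed: int = 0,
) -> list[DesignSpec]:
    """The full size x composition grid (full panel scale by default).

    Row ``s`` runs from composition ``s-0`` down to ``min_no`` NO-RILs in
    steps of ``overlap_step`` O-RILs: 20 cells for size 195, 10 for size 95,
    165 cells in total at the defaults.
    """
    if sizes is None:
        sizes = range(195, 94, -10)
    specs: list[DesignSpec] = []
    for s in sizes:
        if s < 1:
            raise DesignError("training sizes must be positive")
        t = 0
        while s - t * overlap_step >= min_no:
            specs.append(
                DesignSpec(
                    n_per_env=s,
                    n_overlap=t * overlap_step,
                    n_env=n_env,
                    replicate_seed=replicate_seed,
                    group_size=overlap_step,
                )
            )
            t += 1
    return specs


def accounting(alloc: Allocation, total_rils: int, n_env: int | None = None) -> DesignAccounting:
    """Exact counts: plots, unique RILs, coverage and missing cells."""
    alloc.validate()
    J = alloc.n_env if n_env is None else n_env
    n_per_env = len(alloc.training(alloc.envs[0])) if alloc.envs else 0
    plots = sum(len(alloc.training(j)) for j in alloc.envs)
    unique = len(alloc.unique_observed())
    no_across = sum(len(alloc.no_rils[j]) for j in alloc.envs)
    cells_total = int(total_rils) * J
    missing = cells_total - plots
    return DesignAccounting(
        n_per_env=n_per_env,
        n_env=J,
        unique_across=unique,
        no_across=no_across,
        plots=plots,
        cells_total=cells_total,
        missing_cells=missing,
        coverage_fraction=plots / cells_total if cells_total else float("nan"),
    )


def cost_model(acc: DesignAccounting, cost_per_plot: float = 15.0) -> dict[str, float]:
    """Phenotyping cost of a sparse design vs the full factorial."""
    if cost_per_plot < 0:
        raise DesignError("cost_per_plot must be >= 0")
    total = acc.plots * cost_per_plot
    full = acc.cells_total * cost_per_plot
    return {
        "total_cost": total,
        "full_design_cost": full,
        "savings": full - total,
        "cost_per_plot": cost_per_plot,
    }
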