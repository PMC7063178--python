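"""Qualitative contrast table and synthetic densitometry-style replicates.

The wet-lab side of the study is represented by strict orderings between
condition means (stress markers higher under DIO, insulin markers higher
under NCD).  ``generate_synthetic_blots`` emulates the replicate structure
of those measurements (n = 4 per condition, positive values, multiplicative
lognormal noise); ``check_qualitative_patterns`` scores simulation output
against the same table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .simulate import SimulationResult, steady_value

__all__ = [
    "PatternConstraint",
    "PatternTable",
    "SyntheticBlot",
    "PatternCheckReport",
    "generate_synthetic_blots",
    "check_qualitative_patterns",
]


@dataclass(frozen=True)
class PatternConstraint:
    """One strict ordering between two conditions of one readout."""

    id: str
    readout: str
    condition_a: str
    condition_b: str
    relation: str  # "greater" or "less": readout[a] <relation> readout[b]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.relation not in ("greater", "less"):
            raise ValueError(f"constraint {self.id!r}: bad relation {self.relation!r}")
        if self.condition_a == self.condition_b:
            raise ValueError(f"constraint {self.id!r}: conditions must differ")

    def holds(self, value_a: float, value_b: float) -> bool:
        # strict inequality: ties fail, mirroring categorical higher/lower calls
        if self.relation == "greater":
            return value_a > value_b
        return value_a < value_b


@dataclass
class PatternTable:
    constraints: list[PatternConstraint] = field(default_factory=list)

    def __iter__(self):
        return iter(self.constraints)

    def __len__(self):
        return len(self.constraints)

    def readouts(self) -> set[str]:
        return {c.readout for c in self.constraints}

    def conditions(self) -> set[str]:
        out: set[str] = set()
        for c in self.constraints:
            out.update((c.condition_a, c.condition_b))
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "PatternTable":
        rows = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rows.append(
                    PatternConstraint(
                        id=row["id"],
                        readout=row["readout"],
                        condition_a=row["condition_a"],
                        condition_b=row["condition_b"],
                        relation=row["relation"],
                        provenance=row.get("provenance", ""),
                    )
                )
        return cls(rows)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["id", "readout", "condition_a", "condition_b", "relation", "provenance"]
            )
            for c in self.constraints:
                writer.writerow(
                    [c.id, c.readout, c.condition_a, c.condition_b, c.relation, c.provenance]
                )


@dataclass
class SyntheticBlot:
    """Replicate densitometry-like observations for one readout/condition."""

    readout: str
    condition: str
    values: np.ndarray
    sigma: float
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("blot replicate values must be positive")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def generate_synthetic_blots(
    patterns: PatternTable,
    effect_size: float = 2.0,
    sigma: float = 0.2,
    n: int = 4,
    seed: int = 0,
    base_level: float = 1.0,
) -> list[SyntheticBlot]:
    """Seeded lognormal replicates whose condition means obey the table.

    For each readout, conditions on the "high" side of its constraints get
    mean ``base_level * effect_size`` and the others ``base_level``.  A
    readout constrained in both directions against the same condition pair
    is contradictory and raises ``ValueError``.
    """
    if effect_size <= 1.0:
        raise ValueError("effect_size must exceed 1")
    if n < 2:
        raise ValueError("need at least 2 replicates")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")

    # orientation per (readout, condition): +1 high side, -1 low side
    orientation: dict[tuple[str, str], int] = {}
    for c in patterns:
        high, low = (
            (c.condition_a, c.condition_b)
            if c.relation == "greater"
            else (c.condition_b, c.condition_a)
        )
        for cond, sign in ((high, +1), (low, -1)):
            key = (c.readout, cond)
            if orientation.get(key, sign) != sign:
                raise ValueError(
                    f"contradictory constraints for readout {c.readout!r} on "
                    f"condition {cond!r}"
                )
            orientation[key] = sign

    rng = np.random.default_rng(seed)
    blots = []
    for (readout, condition), sign in sorted(orientation.items()):
        mean = base_level * (effect_size if sign > 0 else 1.0)
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
        blots.append(
            SyntheticBlot(
                readout=readout,
                condition=condition,
                values=mean * noise,
                sigma=sigma,
                seed=seed,
            )
        )
    return blots


@dataclass
class PatternCheckReport:
    verdicts: dict[str, bool]
    values: dict[str, tuple[float, float]]

    @property
    def score(self) -> float:
        """Fraction of constraints satisfied (1.0 for an empty table)."""
        if not self.verdicts:
            return 1.0
        return sum(self.verdicts.values()) / len(self.verdicts)

    @property
    def all_pass(self) -> bool:
        return all(self.verdicts.values())

    def failed(self) -> list[str]:
        return [cid for cid, ok in self.verdicts.items() if not ok]


def check_qualitative_patterns(
    results: Mapping[str, SimulationResult | Mapping[str, float]],
    patterns: PatternTable,
    tail_fraction: float = 0.1,
) -> PatternCheckReport:
    """Strict pass/fail per constraint on steady readout values.

    ``results`` maps condition name either to a finished simulation (steady
    values are taken from the trajectory tail) or directly to a mapping of
    readout name to scalar (e.g. synthetic replicate means).
    """
    verdicts: dict[str, bool] = {}
    values: dict[str, tuple[float, float]] = {}
    for c in patterns:
        pair = []
        for condition in (c.condition_a, c.condition_b):
            try:
                source = results[condition]
            except KeyError:
                raise KeyError(f"constraint {c.id!r}: missing condition {condition!r}")
            if isinstance(source, SimulationResult):
                try:
                    traj = source.readouts[c.readout]
                except KeyError:
                    raise KeyError(
                        f"constraint {c.id!r}: readout {c.readout!r} absent from "
                        f"condition {condition!r}"
                    ) from None
                pair.append(steady_value(traj, tail_fraction).value)
            else:
                try:
                    pair.append(float(source[c.readout]))
                except KeyError:
                    raise KeyError(
                        f"constraint {c.id!r}: readout {c.readout!r} absent from "
                        f"condition {condition!r}"
                    ) from None
        verdicts[c.id] = c.holds(pair[0], pair[1])
        values[c.id] = (pair[0], pair[1])
    return PatternCheckReport(verdicts=verdicts, values=values)


def blots_to_condition_means(
    blots: Iterable[SyntheticBlot],
) -> dict[str, dict[str, float]]:
    """Arrange replicate means as {condition: {readout: mean}}."""
    out: dict[str, dict[str, float]] = {}
    for blot in blots:
        out.setdefault(blot.condition, {})[blot.readout] = blot.mean
    return out
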