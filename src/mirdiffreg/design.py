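"""Experimental design: replicate pools arranged as lines x conditions.

The default layout mirrors a two-line (high-autotomy ``HA`` vs low-autotomy
``LA``), two-condition (``sham`` vs ``SNL`` nerve injury) experiment with
three biological replicate pools per group, i.e. 12 pools such as
``HA_SNL1`` or ``LA_sham3``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

LINES = ("HA", "LA")
CONDITIONS = ("sham", "SNL")


@dataclass(frozen=True)
class PoolDesign:
    """Layout of biological replicate pools.

    Parameters
    ----------
    lines:
        Genetic line labels (default ``("HA", "LA")``).
    conditions:
        Treatment labels (default ``("sham", "SNL")``).
    replicates:
        Number of replicate pools per line x condition group.
    """

    lines: tuple[str, ...] = LINES
    conditions: tuple[str, ...] = CONDITIONS
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("line labels must be unique")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if not self.lines or not self.conditions:
            raise ValueError("design needs at least one line and one condition")

    def pool_id(self, line: str, condition: str, replicate: int) -> str:
        return f"{line}_{condition}{replicate}"

    @property
    def pools(self) -> list[str]:
        """All pool ids, grouped by line then condition, replicates last."""
        return [
            self.pool_id(line, cond, r)
            for line in self.lines
            for cond in self.conditions
            for r in range(1, self.replicates + 1)
        ]

    def group(self, line: str, condition: str) -> list[str]:
        if line not in self.lines:
            raise KeyError(f"unknown line {line!r}")
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}")
        return [self.pool_id(line, condition, r) for r in range(1, self.replicates + 1)]

    @property
    def groups(self) -> dict[tuple[str, str], list[str]]:
        return {
            (line, cond): self.group(line, cond)
            for line in self.lines
            for cond in self.conditions
        }

    def group_of(self, pool: str) -> tuple[str, str]:
        for (line, cond), members in self.groups.items():
            if pool in members:
                return line, cond
        raise KeyError(f"pool {pool!r} is not part of this design")

    def present(
        self,
        columns: Iterable[str],
        line: str,
        condition: str,
        exclude: Sequence[str] = (),
    ) -> list[str]:
        """Group members that are present in ``columns`` and not excluded."""
        cols = set(columns)
        return [p for p in self.group(line, condition) if p in cols and p not in exclude]
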