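"""Age-specific background (other-cause) mortality.

A :class:`LifeTable` maps integer age to the annual probability of death from
any cause, q(x).  In the disease model this supplies the competing
"death from other causes" transition out of the post-treatment and
local-recurrence states.  The bundled default covers ages 59-63, the span of
the five-year horizon starting at age 59, with 2008 US total-population
values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["LifeTable", "load_life_table", "save_life_table", "bundled_life_table"]

_FIXTURE_NAME = "us_life_2008_59_63.csv"


class LifeTableError(ValueError):
    """Malformed life-table input."""


@dataclass(frozen=True)
class LifeTable:
    """Ordered mapping from integer age to annual death probability q(age).

    Ages must be contiguous.  Lookups above the last tabulated age clamp to
    the final entry (the horizon here is short); lookups below the first
    tabulated age are an error.
    """

    ages: tuple[int, ...]
    qx: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ages) == 0:
            raise LifeTableError("life table is empty")
        if len(self.ages) != len(self.qx):
            raise LifeTableError("ages and qx differ in length")
        if list(self.ages) != list(range(self.ages[0], self.ages[0] + len(self.ages))):
            raise LifeTableError("ages must be contiguous and increasing")
        for a, q in zip(self.ages, self.qx):
            if not 0.0 <= q <= 1.0:
                raise LifeTableError(f"q({a}) = {q} outside [0, 1]")

    def annual_death_probability(self, age: int) -> float:
        """q(age), clamping to the last entry beyond the table's end."""
        if age < self.ages[0]:
            raise LifeTableError(
                f"age {age} below first tabulated age {self.ages[0]}"
            )
        if age > self.ages[-1]:
            return self.qx[-1]
        return self.qx[age - self.ages[0]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "qx": self.qx})


def load_life_table(path) -> LifeTable:
    """Read a two-column (age, qx) CSV into a validated :class:`LifeTable`.

    A header row is optional; ``#`` lines are comments.  Duplicate or
    non-contiguous ages and probabilities outside [0, 1] raise
    :class:`LifeTableError` naming the offending content.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise LifeTableError(f"{path}: empty life-table file") from None
    if df.empty:
        raise LifeTableError(f"{path}: no data rows")
    # headerless files: first row was consumed as header; detect numeric names
    cols = list(df.columns)
    if _is_number(cols[0]):
        df.loc[-1] = cols
        df = df.sort_index().reset_index(drop=True)
        df.columns = ["age", "qx"][: len(cols)]
    if len(df.columns) < 2:
        raise LifeTableError(f"{path}: need two columns (age, qx)")
    df = df.rename(columns={df.columns[0]: "age", df.columns[1]: "qx"})
    try:
        ages = [int(a) for a in df["age"]]
        qx = [float(q) for q in df["qx"]]
    except (TypeError, ValueError) as exc:
        raise LifeTableError(f"{path}: non-numeric row ({exc})") from None
    if len(set(ages)) != len(ages):
        dup = sorted({a for a in ages if ages.count(a) > 1})
        raise LifeTableError(f"{path}: duplicate age(s) {dup}")
    order = sorted(range(len(ages)), key=lambda i: ages[i])
    try:
        return LifeTable(
            tuple(ages[i] for i in order), tuple(qx[i] for i in order)
        )
    except LifeTableError as exc:
        raise LifeTableError(f"{path}: {exc}") from None


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def save_life_table(table: LifeTable, path) -> None:
    """Write a life table as an (age, qx) CSV; inverse of load_life_table."""
    table.to_frame().to_csv(path, index=False)


def bundled_life_table() -> LifeTable:
    """The packaged 2008 US total-population table for ages 59-63."""
    with resources.as_file(resources.files("uvealcea.data") / _FIXTURE_NAME) as p:
        return load_life_table(p)
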