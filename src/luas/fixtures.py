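"""Packaged count tables from the LUAS cohort description.

Each fixture is a small labeled table of nonnegative integer counts with a
``provenance`` string describing where the numbers come from. Counts that are
not literally printed in the cohort description but back-computed from a
printed percentage and total are flagged ``derived_count=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources


@dataclass(frozen=True)
class Fixture:
    """A named table of counts with provenance."""

    name: str
    table: dict[str, int]
    provenance: str
    derived_count: bool = False

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("fixture provenance must be nonempty")
        for key, value in self.table.items():
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"fixture count {key!r} must be a nonnegative integer")


def _registry() -> dict[str, dict]:
    with resources.files("luas.data").joinpath("fixtures.json").open() as fh:
        return json.load(fh)


def available_fixtures() -> list[str]:
    """Names of all packaged fixtures."""
    return sorted(_registry())


def load_fixture(name: str) -> Fixture:
    """Look up a packaged count table by name.

    Raises
    ------
    KeyError
        If ``name`` is not in the registry; the message lists what is.
    """
    reg = _registry()
    if name not in reg:
        raise KeyError(
            f"unknown fixture {name!r}; available fixtures: {', '.join(sorted(reg))}"
        )
    entry = reg[name]
    return Fixture(
        name=name,
        table=dict(entry["table"]),
        provenance=entry["provenance"],
        derived_count=bool(entry.get("derived_count", False)),
    )
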