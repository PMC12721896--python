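"""Peptide elemental compositions and exchangeable-site counting.

A peptide's composition is the sum of its in-chain residue compositions plus
one water.  The number of body-water-exchangeable C-H positions ``n`` is the
sum of per-residue effective site counts; the default table ships with the
package and can be replaced by any two-column text file, since the effective
values are an explicit modelling input.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .constants import ELEMENTS

WATER = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}


@dataclass(frozen=True)
class ElementalComposition:
    """Counts of C, H, N, O, S atoms in a neutral molecule."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative {el} count in composition")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{el: getattr(self, el) + getattr(other, el) for el in ELEMENTS}
        )

    def as_dict(self) -> dict[str, int]:
        return {el: getattr(self, el) for el in ELEMENTS}

    def formula(self) -> str:
        parts = []
        for el in ELEMENTS:
            k = getattr(self, el)
            if k == 1:
                parts.append(el)
            elif k > 1:
                parts.append(f"{el}{k}")
        return "".join(parts)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("midaflux").joinpath("data", name)))


def _read_table(path: str | Path, value_cols: int) -> dict[str, tuple[float, ...]]:
    out: dict[str, tuple[float, ...]] = {}
    header_seen = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # first non-comment line is the header
            continue
        fields = line.split("\t")
        if len(fields) != value_cols + 1:
            raise ValueError(f"malformed line in {path}: {line!r}")
        out[fields[0]] = tuple(float(v) for v in fields[1:])
    return out


def load_residue_compositions(path: str | Path | None = None) -> dict[str, ElementalComposition]:
    """Load per-residue elemental compositions (in-chain, minus water)."""
    path = path or _data_path("residue_compositions.tsv")
    raw = _read_table(path, value_cols=5)
    return {
        res: ElementalComposition(**{el: int(v) for el, v in zip(("C", "H", "N", "O", "S"), vals)})
        for res, vals in raw.items()
    }


def load_site_table(path: str | Path | None = None) -> dict[str, float]:
    """Load the per-residue exchangeable C-H site table (real-valued, >= 0)."""
    path = path or _data_path("exchangeable_sites.tsv")
    table = {res: vals[0] for res, vals in _read_table(path, value_cols=1).items()}
    bad = [r for r, n in table.items() if n < 0]
    if bad:
        raise ValueError(f"negative site counts for residues {bad}")
    return table


_DEFAULT_COMPOSITIONS = load_residue_compositions()
DEFAULT_SITE_TABLE = load_site_table()


def composition_from_sequence(
    sequence: str,
    residue_compositions: dict[str, ElementalComposition] | None = None,
) -> ElementalComposition:
    """Elemental composition of a peptide: sum of residues plus one water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    table = residue_compositions or _DEFAULT_COMPOSITIONS
    total = ElementalComposition(**WATER)
    for i, res in enumerate(sequence):
        if res not in table:
            raise ValueError(f"unknown residue {res!r} at position {i + 1} in {sequence!r}")
        total = total + table[res]
    return total


def exchangeable_site_count(sequence: str, site_table: dict[str, float] | None = None) -> float:
    """Total effective number of 2H-incorporating C-H sites for a peptide."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    table = site_table if site_table is not None else DEFAULT_SITE_TABLE
    n = 0.0
    for i, res in enumerate(sequence):
        if res not in table:
            raise ValueError(f"residue {res!r} at position {i + 1} missing from site table")
        n += table[res]
    return n
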