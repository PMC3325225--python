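"""Discrete character coding for depth and habitat.

Maximum occurrence depth (metres) is discretised into 13 ordered depth
intervals; habitat is a 4-category character (Seeps, Vents, Seeps and
Vents, Coastal).  Character matrices are read and written as TSV and as a
restricted NEXUS CHARACTERS dialect for interoperability with classic
character-tracing software.
"""

from __future__ import annotations

import re
from bisect import bisect_right
from dataclasses import dataclass, field

import pandas as pd

from .tree import PhyloTree

__all__ = [
    "DepthBinning",
    "DEFAULT_DEPTH_EDGES",
    "HABITAT_CATEGORIES",
    "bin_depth",
    "encode_habitat",
    "Character",
    "CharacterMatrix",
    "load_character_table",
    "validate_against_tree",
    "ValidationReport",
]

# Interval edges in metres: shelf break at 200 m then bathyal/abyssal
# slices; 12 edges delimit 13 intervals.  Configurable everywhere.
DEFAULT_DEPTH_EDGES: tuple[float, ...] = (
    200, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5000, 6000,
)

HABITAT_CATEGORIES: tuple[str, ...] = (
    "Seeps", "Vents", "Seeps and Vents", "Coastal",
)

_HABITAT_SYNONYMS = {
    "seep": "seeps",
    "vent": "vents",
    "seeps & vents": "seeps and vents",
    "seeps+vents": "seeps and vents",
    "seep and vent": "seeps and vents",
    "vents and seeps": "seeps and vents",
}


@dataclass(frozen=True)
class DepthBinning:
    """Ascending metre boundaries delimiting ``len(edges) + 1`` depth
    intervals; the deepest interval is open above."""

    edges: tuple[float, ...] = DEFAULT_DEPTH_EDGES
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("depth edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)
        if not self.labels:
            labs = [f"0-{edges[0]:g}m"]
            labs += [
                f"{a:g}-{b:g}m" for a, b in zip(edges, edges[1:])
            ]
            labs.append(f">{edges[-1]:g}m")
            object.__setattr__(self, "labels", tuple(labs))
        if len(self.labels) != len(edges) + 1:
            raise ValueError("need len(edges)+1 interval labels")

    @property
    def n_states(self) -> int:
        return len(self.edges) + 1


def bin_depth(depth: float, binning: DepthBinning | None = None) -> int:
    """Index of the half-open interval [lower, upper) containing ``depth``.

    A depth exactly on a boundary belongs to the upper (deeper) interval.
    """
    if binning is None:
        binning = DepthBinning()
    if depth < 0:
        raise ValueError(f"negative depth: {depth}")
    return bisect_right(binning.edges, depth)


def encode_habitat(label: str) -> int:
    """Stable state index 0-3 for a habitat category, case-insensitive with
    a small synonym map.  Unknown labels raise (no silent coercion)."""
    key = " ".join(label.strip().casefold().split())
    key = _HABITAT_SYNONYMS.get(key, key)
    lowered = [h.casefold() for h in HABITAT_CATEGORIES]
    if key not in lowered:
        raise ValueError(
            f"unknown habitat label {label!r}; expected one of "
            f"{', '.join(HABITAT_CATEGORIES)}"
        )
    return lowered.index(key)


@dataclass
class Character:
    """One discrete character: an ordered state alphabet and a per-taxon
    state index (``None`` = missing)."""

    name: str
    states: tuple[str, ...]
    ordered: bool
    data: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self):
        for taxon, s in self.data.items():
            if s is not None and not (0 <= s < len(self.states)):
                raise ValueError(
                    f"state index {s} for {taxon!r} outside alphabet of "
                    f"size {len(self.states)}"
                )

    def scored_taxa(self) -> list[str]:
        return [t for t, s in self.data.items() if s is not None]


class CharacterMatrix:
    """Taxa x characters table of discrete state assignments."""

    def __init__(self, taxa: list[str], characters: list[Character]):
        if len(set(taxa)) != len(taxa):
            dup = sorted({t for t in taxa if taxa.count(t) > 1})
            raise ValueError(f"duplicate taxa: {', '.join(dup)}")
        self.taxa = list(taxa)
        self.characters = {c.name: c for c in characters}

    def __getitem__(self, name: str) -> Character:
        return self.characters[name]

    def states_for(
        self, name: str, taxa: list[str] | None = None
    ) -> dict[str, int]:
        """Non-missing state assignments for one character, optionally
        restricted to ``taxa``."""
        char = self.characters[name]
        pool = self.taxa if taxa is None else taxa
        return {
            t: char.data[t]
            for t in pool
            if char.data.get(t) is not None
        }

    # -- TSV ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        rows = {"taxon": self.taxa}
        for name, char in self.characters.items():
            rows[name] = [
                "" if char.data.get(t) is None else char.data[t]
                for t in self.taxa
            ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path, alphabets: dict[str, tuple[tuple[str, ...], bool]]
    ) -> "CharacterMatrix":
        """Read a state-index TSV written by :meth:`to_tsv`.  ``alphabets``
        maps character name to (state labels, ordered flag)."""
        df = pd.read_csv(path, sep="\t", dtype={"taxon": str})
        taxa = df["taxon"].tolist()
        chars = []
        for name, (states, ordered) in alphabets.items():
            data = {}
            for t, v in zip(taxa, df[name]):
                data[t] = None if pd.isna(v) else int(v)
            chars.append(Character(name, states, ordered, data))
        return cls(taxa, chars)

    # -- NEXUS -------------------------------------------------------------

    _SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"

    def to_nexus(self, path) -> None:
        """Write a NEXUS CHARACTERS block (SYMBOLS line, MISSING=?)."""
        names = list(self.characters)
        nchar = len(names)
        max_states = max(len(c.states) for c in self.characters.values())
        symbols = self._SYMBOLS[:max_states]
        lines = [
            "#NEXUS",
            "BEGIN TAXA;",
            f"    DIMENSIONS NTAX={len(self.taxa)};",
            "    TAXLABELS " + " ".join(_nexus_token(t) for t in self.taxa)
            + ";",
            "END;",
            "BEGIN CHARACTERS;",
            f"    DIMENSIONS NCHAR={nchar};",
            '    FORMAT DATATYPE=STANDARD SYMBOLS="'
            + " ".join(symbols) + '" MISSING=?;',
            "    CHARSTATELABELS",
            "        "
            + ", ".join(
                f"{i + 1} {_nexus_token(n)}" for i, n in enumerate(names)
            )
            + ";",
            "    MATRIX",
        ]
        for t in self.taxa:
            row = "".join(
                "?"
                if self.characters[n].data.get(t) is None
                else self._SYMBOLS[self.characters[n].data[t]]
                for n in names
            )
            lines.append(f"        {_nexus_token(t)} {row}")
        lines += ["    ;", "END;", ""]
        with open(path, "w") as fh:
            fh.write("\n".join(lines))

    @classmethod
    def from_nexus(
        cls, path, alphabets: dict[str, tuple[tuple[str, ...], bool]]
    ) -> "CharacterMatrix":
        """Read the restricted NEXUS dialect written by :meth:`to_nexus`."""
        with open(path) as fh:
            text = fh.read()
        m = re.search(r"MATRIX(.*?);", text, re.S | re.I)
        if not m:
            raise ValueError("no MATRIX block found")
        names = list(alphabets)
        taxa: list[str] = []
        rows: list[str] = []
        for line in m.group(1).strip().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("'"):
                end = line.index("'", 1)
                taxon, row = line[1:end], line[end + 1:].strip()
            else:
                taxon, row = line.split(None, 1)
            taxa.append(taxon.replace("_", " ") if "_" in taxon else taxon)
            rows.append(row.strip())
        chars = []
        for j, name in enumerate(names):
            states, ordered = alphabets[name]
            data: dict[str, int | None] = {}
            for t, row in zip(taxa, rows):
                sym = row[j]
                data[t] = None if sym == "?" else cls._SYMBOLS.index(sym)
            chars.append(Character(name, states, ordered, data))
        return cls(taxa, chars)


def _nexus_token(s: str) -> str:
    if re.fullmatch(r"[\w.]+", s):
        return s
    if re.fullmatch(r"[\w. ]+", s):
        return s.replace(" ", "_")
    return "'" + s.replace("'", "''") + "'"


def load_character_table(
    path, binning: DepthBinning | None = None
) -> CharacterMatrix:
    """Build a CharacterMatrix from a TSV with columns ``taxon``,
    ``max_depth_m`` and ``habitat``.

    Depth is discretised with :func:`bin_depth` into an (orderable)
    13-state character; habitat becomes the 4-state character.  Empty cells
    become missing; duplicate taxa, unparseable depths and unknown habitat
    labels raise.
    """
    if binning is None:
        binning = DepthBinning()
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"taxon", "max_depth_m", "habitat"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(
            f"missing required columns: {', '.join(sorted(missing_cols))}"
        )
    taxa = df["taxon"].tolist()
    seen = set()
    for t in taxa:
        if t in seen:
            raise ValueError(f"duplicate taxon: {t!r}")
        seen.add(t)
    depth_data: dict[str, int | None] = {}
    habitat_data: dict[str, int | None] = {}
    for _, row in df.iterrows():
        t = row["taxon"]
        d = row["max_depth_m"]
        if pd.isna(d) or str(d).strip() == "":
            depth_data[t] = None
        else:
            try:
                val = float(d)
            except ValueError:
                raise ValueError(
                    f"unparseable depth {d!r} for taxon {t!r}"
                ) from None
            depth_data[t] = bin_depth(val, binning)
        h = row["habitat"]
        if pd.isna(h) or str(h).strip() == "":
            habitat_data[t] = None
        else:
            habitat_data[t] = encode_habitat(str(h))
    depth = Character("depth", binning.labels, ordered=True, data=depth_data)
    habitat = Character(
        "habitat", HABITAT_CATEGORIES, ordered=False, data=habitat_data
    )
    return CharacterMatrix(taxa, [depth, habitat])


@dataclass
class ValidationReport:
    """Discrepancies between a tree's tips and a matrix's taxa."""

    tree_only: frozenset[str]
    matrix_only: frozenset[str]
    intersection: frozenset[str]

    @property
    def clean(self) -> bool:
        return not self.tree_only and not self.matrix_only


def validate_against_tree(
    matrix: CharacterMatrix, tree: PhyloTree
) -> ValidationReport:
    """Compare taxon sets; downstream analyses use the intersection."""
    tree_tips = tree.tip_labels
    mat_taxa = set(matrix.taxa)
    inter = tree_tips & mat_taxa
    if not inter:
        raise ValueError("tree and character matrix share no taxa")
    return ValidationReport(
        frozenset(tree_tips - mat_taxa),
        frozenset(mat_taxa - tree_tips),
        frozenset(inter),
    )
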